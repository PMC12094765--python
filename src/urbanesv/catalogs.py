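"""Canonical catalogs of ecosystem services and land-use/land-cover types.

The valuation system prices eleven ecosystem services on nine land-cover
classes. The service set follows the expert-scored equivalent-factor
tradition (food production on arable land is the numeraire); the land-cover
set extends the classical natural classes with two artificial ones —
man-made wetland (reservoirs, ponds, aquaculture, ditches) and built-up
area — which dominate urban land systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Ecosystem service codes, in canonical column order.
SERVICES: tuple[str, ...] = (
    "AP", "RM", "WS", "GR", "CR", "EP", "HR", "SR", "NC", "BC", "AL",
)

SERVICE_NAMES: dict[str, str] = {
    "AP": "agricultural production",
    "RM": "raw material",
    "WS": "water resources",
    "GR": "gas regulation",
    "CR": "climate regulation",
    "EP": "environmental purification",
    "HR": "hydrology regulation",
    "SR": "soil retention",
    "NC": "nutrient cycling",
    "BC": "biodiversity conservation",
    "AL": "aesthetic landscape",
}

#: The four service categories partition the eleven services.
SERVICE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "Provision": ("AP", "RM", "WS"),
    "Regulation": ("GR", "CR", "EP", "HR"),
    "Supporting": ("SR", "NC", "BC"),
    "Culture": ("AL",),
}

#: Land-use/land-cover codes, in canonical row order.
LULC_TYPES: tuple[str, ...] = (
    "dry_land", "paddy_field", "woodland", "grassland", "river_lake",
    "natural_wetland", "manmade_wetland", "builtup", "unused",
)

LULC_DEFINITIONS: dict[str, str] = {
    "dry_land": "arable land where crops are grown: dry land, irrigated land, garden area",
    "paddy_field": "arable land used as paddy field",
    "woodland": "land where trees and shrubs grow",
    "grassland": "natural grassland, artificial grassland and meadow",
    "river_lake": "rivers and lakes",
    "natural_wetland": "natural water bodies: mudflat, marsh, reed land",
    "manmade_wetland": "artificial water bodies: reservoir, pond, aquaculture area, ditch",
    "builtup": "industrial, residential, commercial and transportation land",
    "unused": "sandy land, bare land, saline-alkali soil",
}

#: Types whose equivalent-factor rows are adopted from the expert-scored
#: reference tables (the two artificial classes are derived by meta-analysis).
ADOPTED_TYPES: tuple[str, ...] = (
    "dry_land", "paddy_field", "woodland", "grassland", "river_lake",
    "natural_wetland", "unused",
)
DERIVED_TYPES: tuple[str, ...] = ("manmade_wetland", "builtup")


@dataclass(frozen=True)
class ServiceCatalog:
    """Ordered ecosystem-service codes and their category partition."""

    services: tuple[str, ...] = SERVICES
    categories: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(SERVICE_CATEGORIES)
    )

    def __post_init__(self) -> None:
        if len(self.services) != 11 or len(set(self.services)) != 11:
            raise ValueError("service catalog must hold exactly 11 unique codes")
        members = [s for group in self.categories.values() for s in group]
        if sorted(members) != sorted(self.services):
            raise ValueError("categories must partition the service set")

    def category_of(self, service: str) -> str:
        for cat, members in self.categories.items():
            if service in members:
                return cat
        raise KeyError(service)


@dataclass(frozen=True)
class LULCCatalog:
    """Ordered land-cover codes with free-text definitions."""

    types: tuple[str, ...] = LULC_TYPES
    definitions: dict[str, str] = field(default_factory=lambda: dict(LULC_DEFINITIONS))

    def __post_init__(self) -> None:
        if len(self.types) != 9 or len(set(self.types)) != 9:
            raise ValueError("LULC catalog must hold exactly 9 unique codes")


DEFAULT_SERVICES = ServiceCatalog()
DEFAULT_LULC = LULCCatalog()
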