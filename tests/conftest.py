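import pytest

import urbanesv as u


@pytest.fixture(scope="session")
def wuhan():
    return u.load_wuhan()


@pytest.fixture(scope="session")
def citywide_cube(wuhan):
    """Citywide cube from printed areas with S defaulting to 1."""
    adj = u.AdjustmentSet(nr=wuhan.nr, se=wuhan.se_series)
    return u.compute_esv_cube(wuhan.areas, wuhan.ef_matrix, wuhan.d, adj)


@pytest.fixture(scope="session")
def citywide_summary(wuhan, citywide_cube):
    return u.summarize(citywide_cube, 1996, 2018, wuhan.t)
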