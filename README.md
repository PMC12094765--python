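# urbanesv

Ecosystem-service valuation for urban land systems by an extended
unit-value (benefit-transfer) method.

Classical equivalent-factor valuation prices the services of *natural*
land covers only: each cover k and service i carries a dimensionless
equivalent factor EF<sub>ki</sub> relative to the food-production value of
one hectare of arable land, and the monetary value follows by
multiplication with the land area. Cities, however, are dominated by
artificial covers — built-up land and man-made wetlands (reservoirs,
ponds, aquaculture, ditches) — that those tables ignore. `urbanesv`
implements the extended scheme: it derives equivalent-factor rows for the
two artificial covers by meta-analysis of published case studies, adjusts
the baseline value for natural productivity, ability to pay and
within-city heterogeneity, and evaluates

```
ESV(r,t,k,i) = A_rtk · D · EF_ki · NR · SE_t · S_rt
```

where A is area (hm²), D the baseline unit value (yuan/hm², transferred
from the national reference by the local/national crop-yield ratio), NR
the city/national NPP ratio, SE<sub>t</sub> the yearly local/national
per-capita income ratio, and S<sub>rt</sub> a district-year factor from
food yields normalized to mean 1. Around the valuation core the package
provides land-change metrics (change rate and the annualized dynamic
index K), equivalent-factor sensitivity analysis (the elasticity
SEF = |ΔESV/ESV| / |ΔEF/EF|, which under the linear model equals a
cover's absolute share of the total), and a driving-force stage
(pairwise Pearson screening at |r| ≥ 0.75, VIF diagnostics against 5,
and OLS fits with significance stars).

The package ships the published citywide tables for Wuhan 1996–2018 as
fixtures, so the full pipeline is reproducible without any download. It
is aimed at landscape ecologists and planners who need transparent,
auditable ESV accounting at city or district scale.

## Worked example

```python
import urbanesv as u

fx = u.load_wuhan()                                   # packaged tables
d = u.compute_baseline_unit_value(3406.50, 5577.87, 4891.84)
print("D =", d)                                       # D = 3884.09 yuan/hm2

adj = u.AdjustmentSet(nr=fx.nr, se=fx.se_series)      # NR=1.01, SE per year
cube = u.compute_esv_cube(fx.areas, fx.ef_matrix, d, adj)
summary = u.summarize(cube, 1996, 2018, fx.t)
print(u.to_billions(summary.totals))
```

```
D = 3884.09
year
1996    82.20
2000    82.22
2005    87.13
2010    93.95
2015    95.74
2018    97.89
```

The totals are in 10⁹ yuan/yr: the city's ecosystem services were worth
about 82 billion yuan in 1996, rising as woodland and man-made wetland
expanded even while built-up land (a net disservice, its factor row is
mostly negative) grew by 64%. Two companion statistics:

```python
print(u.dynamic_index_k(fx.areas, "builtup", 1996, 2018))   # 2.89 %/yr
from urbanesv.sensitivity import sef
print(sef(fx.esv_decomposition(1996), "builtup", delta=-0.5,
          total=fx.esv_total(1996)))                        # 0.0598
```

The dynamic index says built-up area grew 2.89 % of its 1996 extent per
year; the sensitivity index says halving every built-up equivalent factor
moves the 1996 total by only 0.0598 × 50 % ≈ 3 % — the valuation is
inelastic to that row.

A `urbanesv` command-line tool mirrors the library
(`fixtures`, `derive-ef`, `compute`, `landchange`, `sensitivity`,
`drivers`, `synth`); run `urbanesv --help`.

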