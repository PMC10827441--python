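# caninecancer

Multi-stage carcinogenesis modelling of lifetime cancer mortality across
dog breeds.

## The problem

Dog breeds span a 35-fold range of adult body weight, and their lifetime
cancer mortality varies from a few percent to over half of all deaths.
The multi-stage model of carcinogenesis predicts that the prevalence of
a cancer requiring *M* driver mutations scales as

```
p = C (u k T)^M
```

where *C* is the number of at-risk cells, *u* the somatic driver
mutation rate per division, *k* the cell division rate, and *T* the
lifespan. Within a species, cell number is proportional to weight *W*,
and in dogs lifespan itself declines with weight (*T* = *a* − *bW*), so
breed-level lifetime cancer mortality should follow

```
p̄_k = Σ_m  A_m · W_k · T_k^m ,   m ∈ {2, …, 6},  A_m > 0,
```

with no intercept (a weightless breed has no cells at risk). This
package fits that model to per-breed mortality tables by constrained
stepwise AIC selection, flags breeds with unusual residual risk
(prediction bands and an iterative Grubbs test), tests whether residual
cancer risk or residual longevity is associated with breed inbreeding or
breed clades, and calibrates the somatic product *u·k* by comparing
species at their evolutionary cancer-risk equilibrium. A synthetic-data
generator reproduces the statistical structure of breed registry
datasets (binomial death sampling, shared breed cores across registries,
clade effects, planted outliers, inbreeding–lifespan coupling) so the
whole pipeline is testable end to end without any downloads.

It is written for comparative oncologists, veterinary epidemiologists
and evolutionary biologists working on body-size/cancer scaling (Peto's
paradox) who need a reproducible baseline of expected breed risk against
which excesses for specific breeds or cancers can be measured.

## Worked example

```python
from caninecancer.lifespan import DEFAULT_LIFESPAN
from caninecancer.multistage import stepwise_select
from caninecancer.residuals import excess_table, flag_bands, grubbs_iterative
from caninecancer.synthetic_data import SyntheticConfig, OutlierSpec, generate_panel

cfg = SyntheticConfig(seed=42, outliers=[OutlierSpec(index=10, risk_multiplier=1.8)])
table, truth = generate_panel(cfg)          # 85 breeds, true A4 = 7.84e-7
report = stepwise_select(table, DEFAULT_LIFESPAN)
print("best powers:", report.best.powers)
c = report.best.coefficients[4]
print(f"A4 = {c.estimate:.3e} (se {c.se:.2e}, p = {c.p:.1e})")
```

prints

```
best powers: (4,)
A4 = 8.089e-07 (se 1.08e-08, p = 9.6e-79)
```

i.e. stepwise selection recovers the generating single-power model
(*M* = 4, four driver mutations) and its coefficient within sampling
error. The full candidate table (`report.to_frame()`) shows each
competing power set with its AIC difference from the *W·T*⁴ reference:

```
        model  delta_aic  equivalent_to_best
        W.T^2     125.46               False
W.T^2 & W.T^3       5.89               False
        W.T^3      47.30               False
W.T^3 & W.T^4       1.88               False
        W.T^4       0.00                True
W.T^4 & W.T^5       1.96               False
        W.T^5      45.52               False
W.T^5 & W.T^6       5.35               False
        W.T^6     106.25               False
```

(pair rows sit near ΔAIC ≈ 2 because the extra term is uninformative;
they are excluded from the equivalent set when a coefficient is negative
or non-significant). Continuing with residual diagnostics:

```python
records = flag_bands(excess_table(table, report.best, DEFAULT_LIFESPAN),
                     report.best, DEFAULT_LIFESPAN)
for o in grubbs_iterative([r.raw_residual for r in records]):
    r = records[o.index]
    print(f"outlier: {r.breed_name} (excess {r.excess_cancer_pct:+.0f}%, "
          f"G = {o.G:.2f}, p < {o.p_bound:.3f})")
```

```
outlier: synth-010 (excess +64%, G = 3.49, p < 0.025)
```

correctly singles out the planted high-risk breed: its mortality is 64%
above the fitted expectation and the iterative Grubbs test rejects it at
p < 0.025.

The same steps are available from a shell:

```
caninecancer simulate --seed 42 --out-dir out
caninecancer fit out/table_synthetic-42.csv
caninecancer outliers out/table_synthetic-42.csv
caninecancer calibrate            # u*k = 1.6e-5 /yr, k = 16, one division per 23 days
caninecancer run --seed 42        # full pipeline + run manifest
```

## Layout

- `caninecancer.io_datasets` — breed-table I/O, consensus weights,
  trauma exclusion, breed-form merging, shared-breed normalisation.
- `caninecancer.lifespan` — weight–lifespan regressions, pooling,
  excess longevity.
- `caninecancer.multistage` — design, constrained stepwise AIC fit,
  cross-species calibration.
- `caninecancer.residuals` — excess mortality, prediction bands,
  iterative Grubbs outliers.
- `caninecancer.association` — inbreeding correlations, clade
  ANOVA/Fisher LSD, sign tests.
- `caninecancer.synthetic_data` — generator with ground-truth sidecar.
- `caninecancer.cli` — `simulate | fit | bands | outliers | correlate |
  clades | calibrate | run`.

See `docs/methods.md` for the modelling assumptions, parameter choices
and known limitations.
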