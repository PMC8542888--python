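# sorbfate

Batch sorption screening, multi-model isotherm fitting, sorption-profile
clustering and sorption-retarded breakthrough modelling for biochar-amended
water filters.

## What problem this addresses

Biochar made from agricultural waste (coconut husk, rice straw, corncob…)
is a cheap sorbent for removing pharmaceutical and pesticide
micropollutants — tetracyclines, fluoroquinolones, triazines, phenylureas
— from surface water, e.g. for water exchange in coastal aquaculture.
Evaluating a biochar goes through a standard computational chain:

1. **Batch screening** — from vial mass balances, single-point linear
   partition coefficients `K_bc = q/Ce` (L/kg) per compound × sorbent, at a
   stated sorbent loading, with removal percentages, censored
   complete-removal handling and ionic-strength (salinity) trend
   classification.
2. **Isotherm fitting** — linear, Freundlich, Langmuir and aqueous BET
   models, `q = K_F·Ce^(1/n)` etc., fitted by nonlinear least squares with
   an eligibility rule (≥5 points spanning ≥5× in Ce) and a multilayer
   sorption flag (Freundlich 1/n > 1, or a good BET fit).
3. **Similarity clustering** — hierarchical clustering of the K_bc matrix
   by sorbent or by compound (log10 + z-score, average linkage).
4. **Filter transport** — 1-D advection–dispersion through the layered
   sand/biochar filter with linear equilibrium retardation
   `R = 1 + (ρ_b/θ)(f_s·K_s + f_bc·K_bc)` or one-site kinetic sorption
   `∂S/∂t = k(K_d·C − S)`, simulated with a conservative finite-volume
   scheme, verified against the closed-form
   `C/C_in = ½[erfc((RL−vt)/(2√(DRt))) + e^{vL/D}·erfc((RL+vt)/(2√(DRt)))]`,
   and inverted to estimate `K_s`/`K_bc`/`k` from observed breakthrough
   curves.
5. **Batch-vs-field comparison** — per-pair ratios of batch to
   field-fitted `K_bc` with explicit censored-value bounds; on the packaged
   reference table the finite ratios span roughly 10–500.

Because no raw measurements are deposited with the study this package
emulates, a first-class synthetic-data module generates batch series,
salinity series, planted K_bc matrices and breakthrough curves with known
ground truth under the published experimental designs, so every stage is
testable end to end.

The two estimation cores follow the statsmodels convention: a model object
built from data whose `fit()` returns a results object with parameters,
standard errors, goodness of fit and a `summary()`:

```python
Isotherm(ce, q, kind="freundlich").fit()        # -> IsothermResults
ColumnTransportModel(curve, column, ...).fit()  # -> ColumnFitResults
```

## Worked example

```python
import numpy as np
from sorbfate import (
    ColumnTruth, SoluteTransportParams, field_filter, fit_column_params,
    generate_breakthrough, load_reference_pairs, ratio_table,
)

# batch-vs-field comparison on the packaged reference coefficients
pairs, _ = load_reference_pairs()
table, summary = ratio_table(pairs)
print(f"finite batch/field ratios: {summary['ratio_min']:.1f} - {summary['ratio_max']:.1f}")
print(f"censored: {summary['censored_ratios']}")

# two-stage inverse fit: K_bc from a noisy synthetic pilot-filter run,
# with the sand coefficient fixed from the control filter
truth = ColumnTruth(params=SoluteTransportParams(ks=1.4, kbc=12.2), noise_cv=0.05, seed=3)
observed = generate_breakthrough(truth)
result = fit_column_params(observed, field_filter(), free=("kbc",), fixed={"ks": 1.4})
print(result.summary())
```

prints

```
finite batch/field ratios: 11.9 - 509.4
censored: ['atrazine/CHCHI > 2790']
Column transport fit
==============================================
mode: equilibrium   n points: 24   RSS: 0.022247
free parameters: kbc   converged: True
  ks   (fixed) = 1.4
  kbc  (free ) = 11.96 +/- 2.41
  k    (fixed) = 0
```

The ratio range says field-derived biochar partition coefficients are
roughly 12–509 times lower than batch-screening values (the censored
atrazine/CHCHI pair is reported as a bound, not a number).  The fit
recovers the true `K_bc = 12.2 L/kg` as 11.96 ± 2.41 from 24 noisy 1 L
composite samples: with the 15-minute conditioning phase, early effluent
litres exit at ≈ C_in/R of the layer they occupied, which is what makes
the biochar coefficient identifiable within a 24 L trial.

A CLI mirrors the library (`sorbfate batch-kbc`, `fit-isotherm`,
`cluster`, `simulate-column`, `fit-column`, `compare`,
`synth batch|salinity|column`); see `sorbfate --help`.

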