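# Methods

This note documents the models implemented in `sorbfate`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Batch sorption screening

A batch observation is a vial with solution volume *V* (L), sorbent mass
*m* (kg), initial aqueous concentration *C₀* and equilibrium concentration
*Cₑ* (mg/L).  The sorbed-phase concentration, single-point partition
coefficient and removal follow from the mass balance:

    q = (C₀ − Cₑ) V / m          [mg/kg]
    K_bc = q / Cₑ                [L/kg]
    removal = 100 (C₀ − Cₑ) / C₀ [%]

Internal units (mg/L, L, kg) are chosen so K comes out in L/kg with no
conversion factors.  Mass conservation C₀V = CₑV + qm holds by
construction and is asserted on every computed point.

Numerical choices:

* Records with Cₑ up to 5% above C₀ are accepted (triplicate analytical
  scatter near zero removal) but clipped to Cₑ = C₀, so removal stays in
  [0, 100].  Larger violations are rejected at read time with the row index.
* Complete removal (Cₑ = 0) yields no finite K_bc.  Such points are
  censored lower bounds K_bc ≥ q/LOQ with a configurable limit of
  quantification (default 0.01 mg/L, i.e. 1% of the screening
  concentration — a typical UV detection floor), never infinities.
* Matrix cells are arithmetic means of replicate K_bc values; the spread
  is kept as the sample SD.  Cells whose replicates all show complete
  removal are flagged censored and carry the mean bound.
* The screening matrix is assembled at a stated sorbent loading
  (mass/volume, mg/L) with a 2% relative matching tolerance.

Salinity series are classified from successive K_bc ratios with a 5%
relative dead-band: `decrease` / `increase` when every step moves beyond
the band in the same direction, `flat` when every step stays inside it,
otherwise `non-monotone`.  The dead-band reflects that directions in
ionic-strength experiments are read qualitatively from replicate means.

Contact time is carried on records (default 24 h) but not modelled
kinetically: equilibration differences between 24 h and 7 d contact are at
the percent level for these systems.

## Isotherms

Four equilibrium models are supported (q in mg/kg, Cₑ in mg/L):

| model      | form                                                  |
|------------|-------------------------------------------------------|
| linear     | q = K Cₑ                                              |
| Freundlich | q = K_F Cₑ^(1/n)                                      |
| Langmuir   | q = q_max b Cₑ / (1 + b Cₑ)                           |
| BET        | q = q_m K_B Cₑ / ((C_s − Cₑ)(1 + (K_B − 1) Cₑ/C_s))  |

The BET form is the aqueous-phase adaptation with the saturation
concentration C_s replacing vapour pressure — the only BET variant
applicable to solution sorption.  C_s may be fitted (default, bounded
above the largest observed Cₑ) or fixed from solubility.

Eligibility: a series is fitted only when at least five points with
Cₑ > 0 are available spanning at least a factor of five in Cₑ;
complete-removal points are excluded before the check and noted in the
reason string.  The rule can be overridden explicitly, in which case the
result is marked ineligible.

Fitting is nonlinear least squares in natural (untransformed)
coordinates: linearised regressions distort the error structure, so the
log-log Freundlich regression is used only to seed starting values.
Determinism comes from a fixed multiplicative start grid (factors 0.3, 1,
3 on each seeded parameter); the best converged start wins by RSS.
Standard errors come from the Jacobian at the optimum
(cov = (JᵀJ)⁻¹ RSS/(n−p)).  r² is 1 − RSS/TSS on q; model ranking uses
small-sample AIC (AICc), and models within 2 AICc units of the best are
reported as a tie set rather than a single winner.

Multilayer sorption is flagged when a Freundlich fit gives 1/n > 1, or
when a BET fit is acceptable (r² ≥ 0.9; the threshold is a package
choice — "acceptable fit" has no universal definition).

## Hierarchical clustering of sorption profiles

Sorbents (or compounds) are clustered on their mean-K_bc profiles.
Because K_bc spans more than an order of magnitude, profiles are log10
transformed and z-scored per feature, then merged by average linkage on
Euclidean distances.  All four choices (transform, standardisation,
linkage, metric) are switchable and recorded in the dendrogram's
preprocessing descriptor, since the original screening study does not
report its clustering settings — exact leaf-order reproduction is
explicitly not a goal.  Censored cells exclude the affected sorbent by
default (logged); imputation at the censoring bound is available by flag.
Dendrograms serialise to Newick (branch lengths are merge-height
differences) plus a JSON merge table.

## Column transport

The pilot filter is a layered 1-D porous medium: by default a 50 L bucket
(inner diameter 0.34 m) packed, top to bottom, with 2 kg gravel, 11 kg of
10:1 w/w sand:biochar (or plain sand in the control), 4 kg sand and 7 kg
gravel, run at 1 L/min after 15 min of zero-flow conditioning.
Unmeasured properties use declared defaults, reported with every fit and
config-overridable: bulk density 1.5 kg/L (gravel) and 1.6 kg/L (sand
layers), porosity 0.4, longitudinal dispersivity 1% of layer depth,
molecular diffusion 10⁻⁹ m²/s.  Biodegradation is set to zero (short
trial duration, high filtration rate).

Per layer, the composite distribution coefficient and retardation are

    K_d = f_s K_s + f_bc K_bc        [L/kg]
    R = 1 + (ρ_b/θ) K_d

with sand/biochar mass fractions f_s, f_bc (the gravel remainder is
non-sorbing).  Two closures are implemented:

* **equilibrium** — instantaneous local sorption equilibrium,
  θR ∂C/∂t = ∂x(θD ∂x C) − q ∂x C;
* **kinetic** — one-site first-order mass transfer toward local
  equilibrium, θ ∂C/∂t + ρ_b ∂S/∂t = ∂x(θD ∂x C) − q ∂x C with
  ∂S/∂t = k (K_d C − S).

The kinetic closure is the simplest model producing the fronting and
tailing seen in field breakthrough curves; two-region and
intraparticle-diffusion variants are out of scope.

### Numerics

Conservative finite volumes with operator splitting per step: explicit
upwind advection (flux form), implicit central dispersion (tridiagonal
solve), and an exact exponential solution of the linear sorption-exchange
substep (total mass θC + ρ_b S is conserved exactly; the deviation from
equilibrium decays at rate kR).  Choices that matter:

* **Anti-diffusion correction.** Upwind advection carries numerical
  diffusion u·dx·(1 − Cr)/2.  It is subtracted from the physical
  dispersion coefficient (clipped at zero) so sharp fronts are not
  artificially smeared; the correction is exact to leading order and
  switchable.
* **Time step.** dt satisfies the *unretarded* Courant bound
  q·dt/(θ·dx) ≤ courant (default 0.9).  Using R = 1 here keeps dt
  independent of the sorption parameters, which keeps inverse-fit
  objective surfaces smooth in K_s/K_bc.
* **Grid.** A target cell count (default 200 over the total depth) with
  per-layer refinement so the grid Peclet number u·dx/D stays ≤ 2, capped
  at 20 000 cells.
* **Boundaries.** Third-type (flux) inlet by default — standard for
  column experiments; a first-type (concentration) inlet is available for
  verification against the closed form.  Outlet: zero dispersive
  gradient.  Dispersive inlet flux is included in the mass audit.
* **Conditioning.** The zero-flow conditioning phase starts from pore
  water at C_in with a clean sorbed phase; equilibrium mode equilibrates
  instantly (C → C_in/R per layer), kinetic mode relaxes for the
  conditioning duration at rate k.  This initialisation is what makes the
  first effluent litres informative: resident water exits at ≈ C_in/R of
  the layer it occupied, so the early curve encodes the layer
  retardations.  Cumulative volume starts at the onset of flow.
* **Mass audit.** Every simulation reports influent + initial storage vs
  effluent + final storage.  The scheme is conservative, so the relative
  error is at rounding level (≪ 0.5%).

Verification uses the closed-form solution for a first-type inlet into an
initially clean semi-infinite homogeneous medium,

    C/C_in = ½[erfc((RL − vt)/(2√(DRt))) + e^{vL/D} erfc((RL + vt)/(2√(DRt)))],

evaluated with scaled `erfcx` to avoid overflow (the exponent
vL/D − z₂² is ≤ 0 by AM–GM).  Because the closed form assumes a
semi-infinite medium, solver-vs-oracle comparisons observe the resident
concentration at an interior depth of a column padded to twice that
depth; comparing at the outlet instead measures the (physical) finite-
column outlet effect, not solver error.

### Inverse fitting

`ColumnTransportModel.fit()` minimises Σ(C/C_in simulated − observed)²
over a chosen free-parameter subset of {K_s, K_bc, k} with bounded
least squares from a deterministic geometric start grid.  Predictions are
interval means over each observed sampling interval, mimicking composite
1 L grab samples.  The default protocol is two-stage: K_s from the sand
control first, then fixed while K_bc (and k in kinetic mode) are fitted
per biochar filter.  Guard rails: a sand-only column rejects a free K_bc;
equilibrium mode rejects a free k; an all-zero observed curve returns a
lower-bound-only result instead of a spurious estimate.

## Batch-vs-field comparison

Per compound–sorbent pair the ratio K_bc(batch)/K_bc(field) is computed
exactly.  Left-censored field values ("<0.1") propagate to right-censored
ratio bounds ("> batch/0.1") that are excluded from the min/max summary
but itemised — nothing is silently dropped.  On the packaged reference
table the finite ratios run from ≈11.9 (atrazine/CH) to ≈509
(diuron/CHCHI); the batch column of that table is taken to correspond to
the 200 mg/L screening loading (an assumption, recorded here).

## Synthetic data

Generators are pure functions of (truth, seed):

* **Batch**: for each sorbent mass the exact equilibrium Cₑ solves the
  implicit mass balance C₀V = CₑV + q(Cₑ)m by bracketed root finding (the
  residual is strictly increasing; for BET the bracket stays below C_s).
  Defaults mirror the screening design: C₀ = 1 mg/L, V = 50 mL, masses
  5–250 mg, triplicate.
* **Salinity**: K_bc changes by a fixed factor per decade of NaCl
  molarity; 0 M is the reference and each stated level (0, 0.01, 0.1,
  1 M) is one decade step.
* **Planted K_bc matrix**: 7 compounds × 10 sorbents, two sorbent blocks
  (means 2000 vs 200 L/kg), a fixed geometric compound spread, 10%
  lognormal noise.
* **Breakthrough**: the forward solver's fine output averaged over 1 L
  sampling intervals (24 samples at 1 L/min).

Noise is multiplicative lognormal on concentrations, mean-preserving,
default CV 5%, truncated at physical bounds — concentration
quantification error scales roughly with signal.  The 5% default is a
plausible placeholder, not an estimate of any laboratory's precision.
Parameter-recovery studies use the same solver for generation and fitting
(an "inverse crime"), so they demonstrate correctness of the estimation
machinery, not robustness to model misspecification.  The generators also
deliberately omit the mechanisms believed to cause the large batch-field
gap (matrix effects, fouling, preferential flow), so passing recovery
tests says nothing about those.

## Problem sizes used in the shipped checks

Solver verification uses a 0.2 m observation depth in a 0.4 m padded
column at 400 target cells; kinetic-limit checks use 300 cells at
Courant 0.5.  Recovery studies use 50 seeded noisy replicates for the
column fit (24-point curves) and 50 for the noisy Langmuir study
(triplicate 8-point grids); clustering recovery uses 20 seeded matrices.

## Known limitations

* One-site first-order kinetics only; no two-region, intraparticle
  diffusion, fouling or preferential-flow models.
* Constant influent concentration; saturated flow; 1-D.
* Single-solute transport and single-solute isotherms (the screening
  mixture's competitive effects are not modelled).
* No pH-dependent speciation; pH is carried as metadata only.
* Censored-value handling is bound propagation, not maximum-likelihood
  censored regression.
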