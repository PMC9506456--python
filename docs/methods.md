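# Methods

## Scope and model

`cumrisk` implements a chronic cumulative dietary exposure assessment for
two hepatotoxic fungicides, metalaxyl-M and azoxystrobin, by the relative
potency factor (RPF) method. The chain is:

1. supervised residue trials → STMR/HR per analyte × pre-harvest interval;
2. toxicological reference data → RPFs relative to an index compound;
3. per-food-category residues → index-compound-equivalent concentrations
   `C_index,j = Σ_i C_i,j · RPF_i`;
4. a nested Monte Carlo simulation of exposure
   `E = Σ_j CONS_j · C_index,j / bw` and risk
   `R(%) = 100 · E / (NOAEL_index / UF)`;
5. contribution decomposition of mean exposure by compound and category.

Azoxystrobin is the index compound although metalaxyl-M is the more potent
of the two (NOAELs 18.2 vs 8 mg/kg bw/day for liver toxicity): it has far
more residue data and higher residues across crops, which reduces the
uncertainty introduced by the equivalence conversion. The RPF convention is
`RPF_i = NOAEL_index / NOAEL_i`, giving metalaxyl-M 18.2/8 = 2.275 and the
index compound exactly 1. The total uncertainty factor is 10 (interspecies)
× 10 (intraspecies) = 100, so the reference dose is 0.182 mg/kg bw/day and a
risk quotient of 100% marks the acceptability threshold.

## Residue summarization

STMR is the plain sample median (even n: mean of the two central order
statistics), HR the maximum. Replicate measurements at a site count as
independent observations — the four-site, two-replicate bundled trial set
therefore has n = 8 per analyte × interval, which is the reading that
reproduces its published summary values. Below-LOQ records are substituted
at the full LOQ (0.001 mg/kg) by default; LOQ/2 and zero are selectable.
Full-LOQ substitution is the conservative, risk-maximizing choice, and the
bundled trial medians are insensitive to it because the censored values are
the extreme low order statistics. No distributional censoring model
(Kaplan–Meier/MLE) is attempted. MRL screening uses the strict inequality
HR < MRL; an analyte with no limit on record yields an explicit
missing-standard entry, never a silent pass.

## Dissipation kinetics

The default fit is ordinary least squares of ln C on t — the standard
approach in dissipation studies — with k = −slope and C₀ = exp(intercept),
R² reported on the log scale. A nonlinear least-squares refinement on the
concentration scale (initialized from the log-linear fit) is available; the
two coincide exactly on noiseless data. Fits need ≥3 points; a fitted k ≤ 0
is returned flagged non-decaying with the half-life undefined rather than
raised, since flat series are legitimate field outcomes. Fitting is
per-site, matching how site-specific half-lives are conventionally reported.
Published site half-lives (1.15, 1.06, 2.28, 3.89 days) are carried as
reference metadata in `datasets.REPORTED_HALF_LIVES`; the underlying full
time-series is not bundled, so they are not recomputation targets.

A known limitation: when a decaying series falls below the LOQ, substitution
at the LOQ flattens the tail and biases k low. Parameter-recovery
experiments therefore use a negligible LOQ so they measure noise-driven
estimator error only; with real data, late sub-LOQ points should be excluded
from the fit rather than substituted.

## Exposure engine

The simulation is two-dimensional in the EFSA sense: variability and
uncertainty are propagated separately.

- **Inner loop** (default 2000 iterations): draws body weight, per-category
  consumption, and per-category residue concentration per simulated
  individual, applies the exposure equation, and summarizes the resulting
  risk distribution at P50/P97.5/P99.9 (empirical quantiles with linear
  interpolation).
- **Outer loop** (default 500 replicates): re-draws the input *parameters*
  and repeats the inner loop. The point estimate of each percentile is its
  median across outer replicates; the 95% confidence band is the outer
  2.5th/97.5th percentiles (two-sided, default) or 5th/95th (one-sided
  option) — both conventions exist because published practice reports an
  "upper 95% confidence limit" without stating sidedness.

Distribution choices (configurable; the source workflow fitted its inputs in
proprietary software without naming families): body weight and consumption
default to lognormal — positive, right-skewed, standard for both quantities —
parameterized by mean and CV and drawn as `mean·exp(σZ − σ²/2)` with
`σ² = ln(1+cv²)`, so draws are monotone in the mean under common random
numbers (which makes the engine's monotonicity properties exact, not just
statistical). A truncated-normal option redraws non-positive values and
reports the redraw count. Residues are either fixed per category
(`FixedResidue`, reproducing the deterministic C_index table) or an
empirical bootstrap over a per-category pool (`BootstrapResidue`). Outer
uncertainty defaults to nonparametric re-sampling: residue pools are
bootstrap-resampled and consumption parameters re-fitted from a pseudo-sample
(default size 100) of the variability distribution; a "sampling-only" mode
isolates pure Monte Carlo noise.

Seeding: the master seed plus a SHA-256 hash of the group id plus the outer
replicate index feed a `SeedSequence`, so every (group, replicate) pair gets
an independent substream. Results are bit-reproducible and invariant to
group ordering or parallel scheduling. Units: consumption in g/day
(converted to kg internally), exposure in mg/kg bw/day, risk in percent.

## Contribution analysis

Contributions are ratios of mean component exposure to mean total exposure
across inner-loop samples — a stable, well-defined population quantity;
a per-percentile variant exists for sensitivity checks. Each category's
exposure is attributed to compounds in proportion to its `C_i,j · RPF_i`
terms, the only split consistent with the cumulation's linearity. Both
decompositions sum to 100% whenever total exposure is positive; an all-zero
exposure set is reported as explicitly undefined.

## Synthetic population

The consumption survey underlying published population risks is not public.
`generate_population` emulates its *structure*: 2 regions × 2 sexes × 10 age
classes = 40 groups, body-weight means on a monotone age schedule from 14 kg
(2–3 y) to 65 kg (adult male; females ×0.88, rural ×0.95), body-weight CV
0.15, and per-category consumption CV 0.5 around adult reference intakes
(e.g. rice 220 g/day, light vegetables 150 g/day, soy sauce 10 g/day).
Consumption scales with age as `0.45 + 0.55·bw/bw_adult` — more weakly than
body weight — so per-kg intake, and hence risk, is highest in toddlers,
reproducing qualitatively the roughly three-fold child/adult risk gradient
that body-weight differences produce. A 3% CV lognormal jitter (seeded)
differentiates groups beyond the fixed multipliers. This is a plausible
emulation, not survey data: passing tests demonstrate the engine's
arithmetic, distributional and scaling behaviour, not demographic realism,
and the published headline population risk percentages are consequently not
reproduction targets.

## Numerical and design notes

- All internal computation is at full floating precision; rounding to the
  3–4 significant figures of published tables happens only at presentation.
- One category's cumulation recomputes slightly above its commonly quoted
  value (dark vegetables: 0.920 + 0.034×2.275 = 0.99735 vs 0.996), most
  likely pre-rounded inputs upstream; the recomputed value is reported.
- Percentile estimation uses linear interpolation between order statistics
  throughout (numpy default).
- Default problem sizes in the test suite use a reduced outer ladder
  (e.g. 2000×50) chosen so the full 40-group assessment completes in seconds
  while leaving Monte Carlo error well inside the asserted tolerances; the
  full 2000×500 default remains the production configuration.
- The acceptance targets (RPF and four category cumulations) are exact
  arithmetic on bundled tables and independent of any seed.

## Known limitations

- Chronic exposure only; no acute (single-day) assessment.
- Substitution-based censoring only.
- Single-compartment first-order kinetics only (no bi-exponential/DFOP).
- The compound attribution assumes residue co-occurrence is independent
  across categories; correlations between compounds within a draw are not
  modelled beyond the shared category concentration.
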