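# cumrisk

Cumulative dietary risk assessment of co-occurring pesticide residues, built
around a supervised residue study of the co-formulated fungicides
**metalaxyl-M** and **azoxystrobin** on scallion. Both compounds target the
mammalian liver, so consumers exposed to both through multiple foods face a
dose-additive cumulative risk that single-compound assessments miss. The
package is aimed at regulatory and food-safety scientists who need a
reproducible, scriptable alternative to spreadsheet/@risk-style workflows.

## What it computes

- **Residue-trial summaries** — supervised trial median residue (STMR) and
  highest residue (HR) per analyte × pre-harvest interval, with below-LOQ
  substitution and MRL compliance screening (strict `HR < MRL`).
- **Dissipation kinetics** — first-order decay fits
  `C(t) = C₀·e^(−kt)`, `t₁/₂ = ln2/k`, by log-linear OLS (default) or
  nonlinear least squares, with degradation percentages.
- **Method-validation statistics** — matrix effect
  `ME(%) = 100·(slope_matrix − slope_solvent)/slope_solvent` and recovery
  mean/RSD.
- **RPF cumulation** — relative potency factors
  `RPF_i = NOAEL_index / NOAEL_i` collapse multi-compound residues per food
  category into index-compound equivalents
  `C_index,j = Σ_i C_i,j · RPF_i` (azoxystrobin is the index compound;
  metalaxyl-M has RPF 2.275).
- **Two-dimensional Monte Carlo exposure** — nested simulation of
  `E = Σ_j CONS_j · C_index,j / bw` (mg/kg bw/day) and the risk quotient
  `R(%) = 100·E/(NOAEL_index/UF)` with UF = 10×10 = 100: the inner loop
  (default 2000 iterations) samples individual variability, the outer loop
  (default 500 replicates) re-draws input parameters to put confidence bands
  on each risk percentile (P50/P97.5/P99.9).
- **Contribution analysis** — percent of total exposure by compound and by
  food category.

The national consumption survey behind published population results is not
public, so `cumrisk.synthetic` generates a stratified stand-in population
(2 regions × 2 sexes × 10 age classes = 40 groups) with known ground truth;
the bundled study tables (residues, NOAELs, category residues, MRLs,
calibration slopes) ship in `cumrisk.datasets`.

## Worked example

```python
import cumrisk as cr
from cumrisk import datasets

obs = datasets.load_scallion_residues()
for s in cr.summarize_trials(obs):
    print(f"{s.analyte:12s} {s.interval_days:2d} d  STMR={s.stmr:.4f}  HR={s.hr:.3f}  (n={s.n})")

tox = datasets.load_tox_profiles()
print("RPF:", cr.rpf_table(tox))

cats = cr.cumulate_categories(datasets.load_category_residues(), tox, basis="stmr")
print(f"Soy sauce C_index = {cats['Soy sauce'].c_index:.4f} mg/kg")

groups = cr.generate_population(cr.SyntheticPopulationSpec(seed=1))
model = {c: ic.c_index for c, ic in cats.items()}
summaries = cr.run_two_dimensional(
    groups, model, tox, cr.EngineConfig(n_inner=2000, n_outer=50, seed=1))
child = next(s for s in summaries if s.group_id == "rural/female/2-3 y")
adult = next(s for s in summaries if s.group_id == "urban/male/30-44 y")
for s in (child, adult):
    point, lo, hi = s.percentiles["P97.5"]
    print(f"{s.group_id:22s} P97.5 risk = {point:.2f}%  (95% band {lo:.2f}-{hi:.2f}%)")
```

prints

```
azoxystrobin  7 d  STMR=0.8615  HR=4.687  (n=8)
azoxystrobin 10 d  STMR=0.3635  HR=4.368  (n=8)
metalaxyl-M   7 d  STMR=0.0025  HR=0.088  (n=8)
metalaxyl-M  10 d  STMR=0.0035  HR=0.049  (n=8)
RPF: {'metalaxyl-M': 2.275, 'azoxystrobin': 1.0}
Soy sauce C_index = 0.8667 mg/kg
rural/female/2-3 y     P97.5 risk = 13.95%  (95% band 12.71-14.87%)
urban/male/30-44 y     P97.5 risk = 4.45%  (95% band 4.11-4.80%)
```

The STMR/HR lines are the study's published trial summaries recomputed from
the raw measurements. The risk lines are on the **synthetic** population:
toddlers carry roughly three times the adult risk quotient because intake
scales with age far more weakly than body weight does; a risk quotient below
100% means exposure stays under the health-based reference dose
(NOAEL_index/UF = 0.182 mg/kg bw/day).

## Command line

```sh
cumrisk summarize residues.csv --mrl-csv mrls.csv --out report/
cumrisk assess --seed 1 --basis stmr --out assessment/
cumrisk simulate --seed 1 --out synthetic/
```

Each run writes a `manifest.json` (seed, version, config hash) sufficient to
reproduce its outputs exactly.

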