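# sulfarisk

Small-data QSPR modeling of the thermal hazard of 5-membered cyclic
sulfamidates.

Cyclic sulfamidates are electrophilic alkylating building blocks whose
ring-opening reaction with strong bases releases SO₃ and substantial heat.
For safe scale-up, each compound's reaction enthalpy ΔᵣH (J/g) must be known
— but measuring it calorimetrically is slow, and typical data sets are tiny
(tens of compounds).  `sulfarisk` implements a modeling pipeline that predicts
ΔᵣH from quantum-chemistry-derived descriptors and classifies each compound
into the Stoessel thermal criticality classes: negligible (< 100 J/g), medium
(100–400 J/g), critical (400–800 J/g), catastrophic (≥ 800 J/g).

It is written for process-safety and cheminformatics scientists who have a
small table of compounds × descriptors and need reproducible small-data
regression with honest validation.

## What is inside

* **Descriptor schema** — a fixed registry of 71 conformer-averaged
  quantum-chemical descriptors (atom-level partial charges, Fukui indices and
  frontier-orbital variants at 8 ring sites; two C–H bond dissociation
  energies; ring C–O bond order; molecule/degradant dipoles, HOMO–LUMO gaps
  and surface areas; reaction free-energy differences; summed DSC event
  enthalpy), plus the published three-model descriptor-selection table with
  overlap analytics.
* **Steric descriptor** — the "visible sky" fraction: the part of the full
  solid angle around an atom's center not obstructed by other atoms' van der
  Waals spheres, computed with deterministic Fibonacci-sphere ray casting;
  Boltzmann conformer weighting w_i ∝ exp(−ΔE_i/RT) and ensemble averaging;
  multi-frame XYZ I/O.
* **Models** — three regression routes sharing leakage-free preprocessing
  (training-mean imputation of the undefined BDE cells, autoscaling, per-fold
  refits inside cross-validation, predictions floored at 0 J/g):
  1. **PLS-GA** — from-scratch NIPALS PLS1 keeping the fewest latent
     components that explain ≥ 85% of descriptor variance, wrapped in a
     genetic algorithm (crossover 70%, mutation 4%, purge 20%, elitism;
     population 50·p, generations 20·p at full scale) minimizing the
     leave-one-out SEV;
  2. **LASSO** — (1/2n)‖y − β₀ − Xβ‖² + λ‖β‖₁ with λ chosen by
     leave-one-out MSE on a 100-point log grid;
  3. **GPR** — Gaussian-process regression with a constant + dot-product +
     white-noise kernel on the **per-mol** enthalpy scale (so the model need
     not learn molecular weight), with correlation-guided reproducible
     feature selection and native 95% uncertainty intervals.
* **Evaluation** — SEV/SEP (RMSE over cross-validation / prediction
  residuals), R², a DSC-only univariate baseline, criticality
  classification reports, and equal-weight ensembling over all 2ᵏ−1 model
  subsets.
* **Synthetic study generator** — emulates the measured data set's structure
  (29 compounds, 20/9 enthalpy-stratified split, correlated descriptor
  blocks, dense per-mol linear effects, ~6% multiplicative noise, two missing
  BDE cells, per-gram enthalpies within 0–800 J/g) with full ground truth,
  so the entire pipeline is testable without any quantum-chemistry input.

## Worked example

```bash
sulfarisk simulate --seed 7 --out run/
sulfarisk fit lasso        --features run/features.csv --out run/ --seed 3
sulfarisk fit gpr          --features run/features.csv --out run/ --seed 3
sulfarisk fit dsc-baseline --features run/features.csv --out run/ --seed 3
sulfarisk report --dir run/
```

which prints, step by step:

```
seed=7 config_hash=48cb851f503af781
wrote 29 compounds x 71 descriptors to run/features.csv
lasso: SEV 144.4 J/g, wrote artifacts to run
gpr: SEV 169.5 J/g, wrote artifacts to run
dsc-baseline: SEV 207.5 J/g, wrote artifacts to run
report over 3 model(s), 7 combination rows -> run
```

`run/metrics.csv` then holds one row per model with its prediction-set SEP
(J/g), R² and misclassification count on the 9 held-out compounds;
`run/criticality.csv` compares measured and predicted Stoessel classes per
compound; `run/combinations.csv` lists all 7 model-subset ensembles with
their SEP.  The SEV figures above are leave-one-out cross-validation errors
on the 20 training compounds of the synthetic study: the quantum-descriptor
models beat the DSC-only baseline, mirroring the intended use of the
pipeline as an early go/no-go screen.  `sulfarisk fit pls-ga` runs the
genetic-algorithm route (reduced desk-scale profile by default; use
`--profile paper-scale` for the full 3550-chromosome, 1420-generation
search, which takes hours).

The same functionality is available as a library:

```python
import sulfarisk as sr

table, truth = sr.generate_study(sr.SimConfig(seed=7))
fit = sr.select_lambda_loo(table)            # LASSO with LOO-chosen lambda
pred = sr.predict_lasso(fit, table.predict)  # clipped at 0 J/g
print(sr.rmse(table.predict.y_per_gram, pred))
```

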