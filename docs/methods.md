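# Methods

## Problem and scope

`sulfarisk` models the reaction enthalpy ΔᵣH of 5-membered cyclic
sulfamidates toward strong bases from quantum-chemistry-derived molecular
descriptors, and maps predictions to Stoessel thermal-criticality classes.
The package implements the statistical pipeline only: descriptor *values*
(charges, Fukui indices, bond energies, orbital gaps, free energies) are
inputs, supplied by file or by the synthetic generator — no electronic-
structure calculation is performed.  The one geometric descriptor computed
here is the steric "visible sky" fraction, which needs only 3-D coordinates
and van der Waals radii.

## Descriptor registry

The registry fixes 71 named descriptor columns and their order.  Seven
atom-level property families (xtb Fukui +/0/−, xtb Mulliken charge, two
frontier-orbital Fukui variants, visible sky) each contribute one value per
ring site — the five heavy atoms N, S, O, C(O), C(N) and the three hydrogen
sites NH, C(N)H, C(O)H (averaged when several H are bonded) — giving 56
columns.  Added to these are the C(O)–H and C(N)–H bond dissociation
energies, the ring C–O bond order, molecule-level dipole / HOMO–LUMO gap /
Labute accessible surface area, the same three properties for each of two
degradants, two reaction free-energy differences, and the summed DSC event
enthalpy (20–400 °C window, recorded in kcal/mol).  Only the two BDE columns
and H-site atom columns may be missing (absent hydrogen ⇒ undefined value).
The exact itemization beyond the 25 descriptors in the published selection
table is an interpretation; it is pinned in the packaged manifest so the
count (71) and the 8-sites-per-family block structure are stable, testable
facts.

## Visible sky and conformer averaging

For atom *i*, the visible-sky value is the fraction of the full solid angle,
seen from the nuclear center, whose ray does not intersect any other atom's
vdW sphere.  Design choices: Bondi radii by default (overridable per
conformer); the central atom's own sphere is ignored (the viewpoint is the
nucleus); a ray is blocked iff its half-line intersects an occluding sphere;
a viewpoint lying inside another atom's sphere yields 0.  Directions come
from a deterministic Fibonacci sphere, so results are reproducible without a
seed; n_rays defaults to 100 000, giving agreement with the spherical-cap
closed form to ~1e-5 and with a Monte-Carlo direction set within sampling
error.  Conformer-ensemble averages use Boltzmann weights
w_i ∝ exp(−(E_i − E_min)/RT) with R = 0.0083145 kJ/(mol K) and a default
temperature of 298.15 K (ambient; the averaging temperature is not otherwise
constrained).

## Preprocessing

Missing BDE cells are filled with the mean of the *observed training*
values; artificially large fill values are deliberately not supported — in a
linear model they give the missing feature a large influence, the opposite
of the intended "ignore this feature for this compound".  All descriptor
columns are then centered and scaled by training statistics (sample n−1
standard deviation; zero-variance columns pass through centered).  Inside
leave-one-out cross-validation both states are refitted on every fold's
19-compound training subset, so the held-out compound never contributes to
imputation or scaling.  Whether the original workflow refit scaling per fold
is unknowable from the outside; per-fold refitting is the leakage-free
choice and is what the package tests.

## PLS with genetic-algorithm descriptor selection

PLS1 is implemented as NIPALS with deflation.  The number of latent
components is the smallest k whose cumulative explained descriptor-variance
fraction reaches the threshold (default 0.85), capped by min(n−1, p);
extraction also stops early when the response residual is numerically
exhausted, so an exactly-recoverable response terminates at the minimal k.
The 0.85 rule is applied to the *selected* submatrix inside every GA fitness
evaluation — each candidate model is self-contained.  Predicted enthalpies
below 0 J/g are floored at 0, inside cross-validation folds as well as on
the prediction set.

The GA encodes descriptor subsets as binary chromosomes and minimizes the
leave-one-out SEV.  Operator rates: crossover 0.70, per-bit mutation 0.04,
purge 0.20.  Unstated details are fixed as follows: rank-proportional
roulette parent selection (robust to the SEV scale), crossover as a single
random contiguous-span swap, purge replaces the worst fraction with fresh
random chromosomes, and the single best chromosome is retained unchanged
(elitism), which makes the best-fitness trace monotone.  All-zero
chromosomes are re-randomized before evaluation.  Sizing follows
population = 50·p and generations = 20·p (3550 and 1420 at p = 71); because
a full-scale run takes hours, the default desk profile is population 200 /
50 generations, and fitness values are memoized (identical chromosomes are
never re-evaluated).  Per-fold imputation/scaling matrices are precomputed
once per GA run — column-wise preprocessing is subset-independent, so this
is exactly the per-fold protocol, just cached.

## LASSO

The l1 path minimizes (1/2n)Σ(y − β₀ − xβ)² + λΣ|β| (unpenalized
intercept), solved by coordinate descent via scikit-learn's `Lasso` with
warm starts down a 100-point log grid from λ_max = max_j |x_jᵀ(y−ȳ)|/n to
1e-4·λ_max.  λ is selected by leave-one-out mean squared error with
per-fold preprocessing refits; ties break toward the larger (sparser) λ.
The active set can never exceed the number of training rows, which the
tests assert on the 20-compound training set.

## Gaussian-process regression

The GP kernel is constant + inhomogeneous dot product + white noise.  A
dot-product kernel makes the GP exactly a Bayesian linear model (Gaussian
prior on weights), which the tests exploit: with fixed hyperparameters the
posterior mean and variance equal the weight-space closed form to 1e-6.
Hyperparameters maximize the log marginal likelihood with 10 random
restarts (seeded) and log-bounds [−6, 6].  Targets are per-mol enthalpies
(J/g × molecular weight): the descriptor → enthalpy mapping then does not
need to encode molecular weight.  Predictions are converted back to J/g;
means and 95% bounds (mean ± 1.96 sd) are floored at 0.

Manual, chemistry-guided feature selection is encoded as a reproducible
procedure: rank descriptors by |Pearson r| against the per-mol enthalpy on
the training set (zero-variance ⇒ r = 0), drop any candidate with pairwise
|r| > 0.9 against an already-kept one, guarantee at least one steric
(visible-sky / surface-area) descriptor, and choose the subset size from a
small ladder (default 4, 6, 8) by leave-one-out SEV.

## Evaluation, baseline and ensembles

SEV and SEP are RMSEs over the LOO and prediction residuals; R² is
1 − SS_res/SS_tot about the measured mean of the evaluated set (for
prediction sets, the prediction-set mean — a documented choice among
alternatives).  Stoessel class boundaries at 100/400/800 J/g are left-closed
upward: an exact boundary value is assigned the more severe class, the
conservative reading for safety.  The DSC-only baseline regresses the
per-gram enthalpy on the summed DSC event enthalpy column as-is (its
kcal/mol units make the slope a unit conversion; the ambiguity is recorded,
not resolved).  Ensembles average member predictions with equal weights; all
2ᵏ−1 non-empty subsets are enumerated into a combination table ordered by
decreasing ensemble size.

## Synthetic study generator

The generator emulates the *structure* of the measured data, not its
chemistry.  Descriptor columns are unit normals with within-family
correlation ρ (default 0.6 — the real collinearity is unquantified, so this
is an exposed guess) via a shared family factor.  The per-mol enthalpy is
intercept + Xβ with dense small effects (sd 1 500 J/mol) on every
descriptor plus a few large planted effects (±25 000 J/mol), matching the
observation that descriptor effects are dense rather than sparse.  Dividing
by a per-compound molecular weight (uniform 150–400 g/mol) gives the
per-gram value; multiplicative noise (relative sd 0.06, consistent with
triplicate measurement scatter of ~5–10%) is applied on the per-mol scale.
Rows whose noise-free per-gram enthalpy falls outside the physical
0–800 J/g window are redrawn rather than clipped, which keeps the linear
law exact (noise-free tables support coefficient recovery to machine
precision); only the noise-perturbed realized values are clipped.  The
20/9 split is enthalpy-stratified: rows are ranked by enthalpy, one
prediction compound is drawn per quantile stratum.  Two missing BDE cells
default to the study pattern — C(O)–H in the lowest-enthalpy training
compound, C(N)–H in the lowest-enthalpy prediction compound.

What the generator does *not* reproduce: real descriptor distributions and
their physical couplings, heteroscedastic calorimetry error, and any
relation between molecular weight and descriptor values.  Because per-gram
values are per-mol values divided by a variable weight, a per-gram model
faces irreducible 1/mw variation that no descriptor explains; recovery
simulations for the per-gram models (GA-PLS, LASSO) therefore fix the
molecular weight at 275 g/mol so "response linear in the planted
descriptors" actually holds on the modeled scale.  Passing recovery tests
show the selectors retrieve planted linear signal under realistic noise —
they do not certify performance on real sulfamidate chemistry.

## Problem sizes and numerical choices

Test and acceptance runs use the desk-scale GA profile (population 200, 50
generations; about 8 000 distinct fitness evaluations) and 10-seed recovery
batches; the full sizing rule is exercised arithmetically.  Coordinate
descent converges at tolerance 1e-10; NIPALS stops components at weight
norms below 1e-12; GP numerical jitter is handled by scikit-learn's Cholesky
with the white-noise term keeping the Gram matrix well-conditioned.  LOO SEV
accumulates residuals into a vector and takes a single RMSE so the value is
bit-identical to a naive fold loop.

## Known limitations

* The registry's 46 non-published descriptor identities are an
  interpretation pinned by the manifest.
* The visible-sky occlusion model (vdW spheres, Bondi radii, nuclear
  viewpoint) is one reasonable reading of "solid angle obstructed by other
  atoms"; alternatives (scaled spheres, other radius sets) are supported by
  passing explicit radii.
* GA parent-selection and crossover granularity are fixed choices among
  several defensible readings; results at desk scale depend mildly on them.
* The GPR kernel composition beyond the dot-product term, and whether
  published errors used clipped or raw per-gram means, are interpretations;
  clipped means are used throughout for consistency.
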