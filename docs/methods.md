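# Methods

## Model

The endpoint is the zeta potential ζ (mV) of a polymeric nanoparticle in
a biological medium.  Each particle is described by a row of descriptors
partitioned into three blocks: continuous core properties, small-integer
coating counts, and binary protein-corona fingerprint bits (1 = the
protein is found in the particle's corona).  The model is a linear
structure–property relationship fitted by partial least squares with a
single response (PLS1):

    X  (n × p, autoscaled)  →  T = X·R  (n × A latent scores)
    ŷ = ȳ_train + X_scaled · b,   b = W (PᵀW)⁻¹ q

NIPALS computes each component deterministically — for one response the
weight vector of component *a* is exactly `X_aᵀy_a / ‖X_aᵀy_a‖`, so no
iteration, convergence tolerance or random initialization is involved.
Both X and y are deflated per component; y-deflation does not change
PLS1 predictions but feeds the per-component variance accounting.

Explained variance per LV is reported as
`100·‖t_a p_aᵀ‖²_F / ‖X‖²_F` for the descriptor block (Frobenius norm of
the scaled training matrix as denominator) and as the per-component drop
in residual sum of squares over the total centered sum of squares for
the endpoint.  The cumulative endpoint share equals 100·R² of the
training fit (asserted as a test identity).

## Preprocessing

Descriptors are autoscaled — centered and divided by their standard
deviation — with parameters computed on the **training rows only** and
applied unchanged to every partition.  The standard-deviation
denominator is the population convention (n) by default; the choice does
not affect predictions or any error statistic (it rescales all columns
by one common factor), only the scale of the standardized coefficients,
and the population convention is what makes the package's coefficients
match the reference values the fixture ships with.  The sample (n−1)
convention is available via `ddof=1`.

The endpoint is mean-centered but never variance-scaled, so every error
statistic stays in mV and a standardized coefficient reads as "mV of ζ
per SD of the descriptor".

Descriptors with zero variance over the (fold-)training rows are dropped
with a warning rather than rejected.  This rule is load-bearing for
leave-one-out validation on small tables: a corona bit present in
exactly one training particle becomes constant when that particle is
held out, and the fold must remain fittable.  It is precisely these
folds that dominate RMSECV on the packaged table (structures 5 and 7
carry the only kininogen-1 and complement-C1r bits), which is why an
honest RMSECV (≈25 mV) is three times the external RMSEP (≈7 mV): the
cross-validation is answering "what if I had never seen a particle with
this protein?", not "how noisy is the fit?".  The validation report
names these folds explicitly.

## Validation statistics

Standard QSAR definitions: R² and RMSEC on the training fit; LOO with
full per-fold refit of both scaler and model (component count reduced,
and logged, if a fold's rank drops below A); Q²cv with the full-training
mean as reference (fold-mean selectable); external Q²ext as Q²F1,
i.e. `1 − Σ_V(y−ŷ)² / Σ_V(y−ȳ_train)²` — the training-mean reference is
the only convention under which the published (Q²ext, RMSEP) pair is
arithmetically consistent with the table's endpoints, and the identity
`Q²ext = 1 − n_V·RMSEP²/Σ_V(y−ȳ_train)²` is asserted exactly in tests.

## Applicability domain

Leverage is the hat-matrix diagonal `h_i = x_iᵀ(XᵀX)⁻¹x_i` with X the
autoscaled training matrix (uncentered after autoscaling, which is
equivalent to centered).  The warning threshold is `h* = 3p/n` with
p = number of model descriptors by default (5 descriptors, 14 training
rows → h* ≈ 1.07); the textbook "descriptors + 1" convention is exposed
as `convention="p+1"`.  Standardized residuals divide by the RMSE of the
sample's own partition (RMSEC for training, RMSEP for validation;
pooled RMSE selectable); |r| > 3 flags a response outlier.

Two leverage spaces are provided.  The default descriptor space uses all
p autoscaled descriptors; under it one fixture validation particle
(structure 18, the only sample with three sp² coating carbons — outside
the training range of that count) exceeds h*.  The score space
(`leverage_space="scores"`) measures distance only along the A latent
directions the model actually uses, as most PLS software does; under it
all 20 fixture samples fall inside the domain, matching the reference
analysis.  The discrepancy is a real property of the data, not a bug:
structure 18 is an extrapolation in raw descriptor space but not along
the fitted latent directions.

## Descriptor selection

The GA encodes a descriptor subset as a bit mask.  Fitness is the LOO
RMSECV of the subset (R² selectable), with the LV count chosen per
chromosome as the best among `lv_candidates` (default {1, 2, 3}).
Defaults — population 50, 100 generations, crossover 0.8, per-bit
mutation 2/pool, elitism 2, tournament size 3 — are conventional GA-PLS
settings; nothing in the search is hidden from the config, and a single
integer seed makes runs bit-reproducible.  A repair step flips random
bits until the subset-size constraint holds.  The reported best fitness
is always a fresh re-evaluation, never a cached value.  For pools small
enough to enumerate, `exhaustive_search` provides the exact optimum; the
test suite checks the GA against it on a 30-descriptor pool with three
planted effects.

## Synthetic data

The generator emulates the full descriptor pool the real study drew
from: 33 correlated-Gaussian core descriptors (the first on an
average-molecular-weight-like scale, mean 6.5, sd 0.8), 34 Poisson
coating counts (rate 1.5), and 80 Bernoulli corona bits (prevalence 0.3,
independent by default; an optional latent adsorption-propensity factor
induces co-occurrence).  The endpoint is a planted sparse linear
combination plus Gaussian noise (default sd 7 mV, comparable to the
reference model's RMSEP), and `fixture_like_spec()` mirrors the real
setting: 20 samples, five effective descriptors with the reference sign
pattern (+core, −coating, +two corona bits), endpoint typically spanning
≳80 mV.

What the generator does **not** emulate: real corona fingerprints are
driven by shared adsorption physics and are strongly structured;
descriptor blocks here are mutually independent; coating counts are not
tied to actual functional-group chemistry.  Passing recovery tests on
synthetic pools therefore demonstrates correctness of the selection and
validation machinery, not predictive validity on new laboratory data.

## Numerical choices and scope

* Component count is validated against `rank(X_scaled)`; requesting more
  components raises, and LOO folds degrade gracefully (reduce A, log).
* Singular `XᵀX` in the leverage computation falls back to the
  pseudo-inverse with a warning (condition number guard at 1e12).
* CSV round-trips preserve values as shortest round-trippable decimal
  text; model serialization (JSON) round-trips all arrays exactly.
* The every-third splitter sorts by endpoint with a deterministic
  user-suppliable tie-break; the packaged table keeps its published
  train/validation labels because endpoint ties (−10, +5, +10 mV) make
  the rule's outcome order-dependent.
* Problem sizes in the test suite (pools of 12–30 descriptors, 48–60
  samples, exhaustive enumeration up to C(30,3)) are chosen so the whole
  battery, including the GA-vs-enumeration check, completes in a few
  minutes on one CPU.

## Known limitations

* The 2-LV variance decomposition of the descriptor block on the
  packaged five-descriptor table accounts for ≈38% of ‖X‖²; the two
  singleton corona bits are nearly orthogonal to everything and cap how
  much structural variance two components can carry.  Published
  summaries of the reference analysis report a larger share, which is
  not reproducible from the five published descriptor columns under any
  standard accounting the authors are aware of (Frobenius, score-share,
  PCA eigenvalue, covariance-share — all checked); the package reports
  the Frobenius convention and leaves the discrepancy visible in the
  `reproduce` command's comparison table rather than adopting an ad hoc
  normalization.
* The packaged table's per-sample published predictions are reference
  metadata only; they are internally inconsistent (two identical
  descriptor rows carry different published predictions), so no
  deterministic model can reproduce them cell-for-cell.  The
  `reproduce` command reports the refit model's predictions next to
  them with differences.
* Q²cv on the packaged table (≈0.43) is much lower than Q²ext (≈0.89);
  both are reported, and the mechanism (singleton-bit folds) is stated
  in the validation report rather than averaged away.
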