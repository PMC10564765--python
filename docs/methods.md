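# Methods

## Problem

Given a training set X of n cases described by m numeric features and a
binary diagnosis label, wrapper feature selection searches for the subset
S ⊆ V = {v_1, …, v_m} that maximizes

    f(S) = β · Rat(S) + (1 − β) · (1 − |S|/m)

where Rat(S) is the *resubstitution rate*: the fraction of training cases
correctly classified by a model fit on X restricted to S.  β ∈ [0, 1]
(default 0.99) trades classifying capacity against parsimony.  By
convention f(∅) = 0 exactly; Rat is never evaluated on an empty subset.
Rat is deliberately a training-set quantity — there is no inner validation
split — which makes it optimistic; held-out quality is measured separately
by the evaluation protocol below.

## Search

The optimizer combines greedy randomized construction with tabu search
inside a multistart loop.

**Construction.** From S = ∅ (f = 0, so every feature is initially a
candidate), repeatedly evaluate g(j) = f(S ∪ {v_j}) for all j ∉ S, keep the
improving candidates L′ = {j : g(j) ≥ f(S)}, restrict them to the candidate
list L = {j ∈ L′ : g(j) ≥ gmin + α(gmax − gmin)} (gmin/gmax over L′), and
add a uniform-random member of L.  Stop when L′ = ∅.  α = 1 is pure greedy
(deterministic on tie-free gains); α = 0 samples uniformly over all
improving candidates.  The spanned-L′-only reading at α = 0 is required for
the stated termination condition to be meaningful.

**Tabu search.** Steepest descent/ascent over the full neighborhood N(S)
of add, remove and swap moves, accepting the best considered neighbor even
when it worsens f.  Reversals of recent moves are forbidden: re-entry of a
feature j is tabu while iter ≤ VectorOut(j) + tenure, removal while
iter ≤ VectorIn(j) + tenure; a swap is tabu if either end is.  A tabu move
is still considered when its f strictly exceeds the best f* found in the
current run (aspiration).  Stamps are initialized to −(tenure + 1) so
nothing is tabu at iteration 1, and memory is reset at the start of every
tabu run.  Ties among best considered neighbors break uniformly at random
from the run RNG.  The run stops after `max_iter_ts` consecutive
iterations without improving f*, or early (with a warning) if no neighbor
is considered at all.

**Multistart.** Construct, improve, keep the best (S_best, f_best); stop
after `max_iter_ms` consecutive starts without improving f_best.  All
randomness flows from a single seeded generator, so a (seed, params,
dataset) triple reproduces the exact move sequence with the DA classifier.

### Parameters

| name          | meaning                                   | default      |
|---------------|-------------------------------------------|--------------|
| β             | accuracy weight in f                      | 0.99         |
| α             | RCL greediness                            | 0.99         |
| tenure        | tabu duration (iterations)                | ⌈m/2⌉        |
| max_iter_ts   | tabu no-improvement cap                   | 10·m         |
| max_iter_ms   | multistart no-improvement cap             | 10           |

The tenure and tabu-cap defaults are scaled by the feature count m, not the
case count: a tenure larger than m would freeze the entire neighborhood.
Both remain directly configurable.

## Classifiers

Three classifiers stand behind one fit/predict contract; the wrapper never
inspects solver internals.

- **DA** — linear discriminant analysis with pooled within-class covariance
  and empirical class priors.  It is implemented closed-form in NumPy from
  per-dataset sufficient statistics (class means and the pooled scatter
  matrix), so fitting a subset costs only a |S|×|S| submatrix solve: the
  search performs 10⁵–10⁶ fits per run and per-fit overhead is the entire
  runtime budget.  Exactly singular covariances fall back to a
  diagonal-regularized estimate (ridge 1e-6) with a warning.  Prediction
  agreement with scikit-learn's `LinearDiscriminantAnalysis` is asserted in
  the test suite, and neighborhoods are evaluated in vectorized batches
  (stacked solves) that are checked against the scalar path.
- **LR** — scikit-learn `LogisticRegression` (L2, C = 1, tol = 1e-4,
  max_iter = 1000), threshold at posterior 0.5.
- **SVM** — scikit-learn `LinearSVC` (dual coordinate descent, C = 1,
  tol = 1e-4, max_iter = 1000), sign of the decision value.

The LR/SVM regularization constants are declared defaults, not tuned
values.  Evaluations are memoized in an exact, order-independent cache
(optional size cap), since the search revisits subsets heavily.

## Evaluation protocol

Stratified k-fold cross-validation (default k = 10), seeded.  Per fold:
z-score normalization fit on the training fold only (min–max available as
an alternative; constant features map to zero), selection on the training
fold, a final model on the selected subset, and test-fold metrics from the
confusion table:

    ACC = (TP+TN)/total      AUC = (1 + TPR − FPR)/2
    Gmean = √(TPR·TNR)       F1 = 2TP/(2TP+FP+FN)

AUC here is the balanced-accuracy form computed from thresholded
predictions — *not* a ROC integral — and is kept that way deliberately so
that reported numbers are comparable with the wrapper-selection literature
that uses this definition.  A test fold with a single class yields NaN for
the affected metrics (with a warning) and is excluded from t-test pairing.
Method comparisons use the classical paired two-tailed t test on per-fold
scores (default level 0.05; zero-variance differences are reported as
degenerate, with "=" when all differences are zero).

## Synthetic data and the oracle

The generator draws n cases (default 400), m features (30), class balance
`pos_fraction` (0.35 — representative of the imbalance range of public
diagnosis benchmarks), with r informative features (4) shifted by `delta`
(2.0) noise standard deviations between classes and the rest pure noise.
Class-conditional Gaussians make DA Bayes-optimal, so "informative subset
= good subset" holds by construction.  What the generator does **not**
emulate: correlated or heavy-tailed features, feature interactions,
label noise, missing-data mechanisms.  Passing tests therefore demonstrate
algorithmic correctness on well-specified landscapes, not clinical
performance.

The exhaustive oracle evaluates f on every nonempty subset (guarded to
m ≤ 15), with ties resolved toward smaller, lexicographically earlier
subsets — mirroring the objective's parsimony pressure and keeping the
oracle deterministic.

## Numerical choices

- z-score uses the population standard deviation; constant features map to
  all-zeros in every split.
- Missing-value column drops break ties toward the lower column index.
- Subset cache keys are bitmasks, order-independent by construction.
- Neighbor ties compare f by exact float equality; with the closed-form DA
  this is reproducible bit-for-bit for a fixed seed.
- Derived per-fold seeds stay below 2³¹.

## Known limitations

- With β = 0.99 the per-feature parsimony penalty is (1 − β)/m.  On a
  training set of n cases, any feature whose inclusion flips even one
  training case contributes β/n to f, so whenever β/n > (1 − β)/m — e.g.
  n = 400, m = 30 — the f-optimum provably contains label-independent
  noise features that only absorb resubstitution headroom.  A stronger
  optimizer therefore selects *more* noise features, not fewer; this is a
  property of the resubstitution objective itself, visible in the
  exhaustive oracle's optima as well, and is why the package reports
  held-out metrics separately.
- Runtime grows with the no-improvement caps; the defaults were kept at
  the tuned values (α = 0.99, tenure = ⌈m/2⌉, 10·m, 10).
- LR/SVM searches are substantially slower than DA and determinism is only
  up to solver tolerance.
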