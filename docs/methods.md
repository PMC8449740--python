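# Methods

## Data model and conventions

A `Dataset` is an n×d feature table with a declared schema (numeric,
nominal or binary columns) and binary labels in which **1 is the minority =
positive class** (e.g. "died within one year").  All asymmetric metrics
(precision, recall, F1, G-mean) use this convention; it is what makes the
G-mean = 0 pathology of majority-only classifiers visible.  Missing values
are rejected at read time — imputation is out of scope.

CSV carries no type metadata, so column kinds come from a YAML sidecar or
are inferred (numeric if all values parse, else nominal; two categories →
binary).  Dense ARFF headers are read via `scipy.io.arff`; sparse and
relational attributes are rejected as unsupported.  When reading labeled
files, the minority category of the class column becomes the positive
class (overridable).

For SVM distances and SMOTE interpolation, features are encoded into the
unit cube: nominal columns one-hot, binary columns {0,1}, numeric columns
min-max scaled (constant columns map to 0).  Min-max was chosen over
standardization so RBF distances and SMOTE segments stay in a bounded
cube.  Encoders fit on training data clip transformed numerics into
[0, 1] and raise on unseen categories.  How a study encodes nominal
attributes for kernel methods is genuinely open; one-hot + min-max is this
package's documented choice.

## Synthetic generator

`generate_imbalanced` draws two spherical unit-variance Gaussian clusters
whose means are `separation` apart (majority at the origin), with exact
class counts; optional equal-frequency discretization of leading
coordinates produces nominal columns.  `inject_label_noise` flips exactly
`round(rate·n)` uniformly chosen labels and returns the flipped index set,
giving ground truth for filter-recovery experiments.  Default study
conditions mirror the clinical motivation: 400 majority / 70 minority
(imbalance ratio 5.71), d = 2, separation 4 (clusters that overlap in the
tails but are clearly learnable), 10% label noise.

What the generator does *not* emulate: correlated or heterogeneous
features, class-dependent covariance, subconcepts/small disjuncts, and
boundary-concentrated (non-uniform) label noise.  Passing tests therefore
show the machinery is correct under clean geometric conditions, not that
the method wins on any particular clinical table.

## Gain-ratio trees and the committees filter

Trees split greedily by the gain ratio (information gain over split
information, base-2), with numeric candidates at midpoints of consecutive
distinct sorted values and nominal attributes split multiway.  Candidates
must produce ≥ 2 nonempty subsets and positive information gain — the
positive-gain restriction guards the ratio's small-SplitInfo pathology.
One escape hatch: if a node is impure but no candidate has positive gain
(an XOR-style configuration, where the signal appears only one level
deeper), the first valid zero-gain split (lowest column index, lowest
threshold) is taken.  Ties in gain ratio break by lower column index, then
lower threshold, so trees are deterministic.  Leaves predict their
majority class; ties go to the positive class.  Prediction routes unseen
nominal categories to the child with the largest training support.  No
pruning, windowing or fractional missing-value handling.

The filter (CVCF) trains one tree per stratified fold on the fold's
complement and has **every** tree vote on **every** sample; a sample is
removed when all (`consensus`) or more than half (`majority`, the default)
of the votes contradict its label.  Defaults: 10 folds; majority voting,
being strictly more aggressive, always removes a superset of consensus.

Because committee members vote on samples they were trained on, the base
learner must generalize rather than memorize: a fully grown tree echoes
its own training labels and the filter goes blind (flip recall collapses
to the share of held-out votes).  Classical C4.5 avoids this via pruning,
which is out of scope here; the replacement capacity control is a
committee-tree leaf floor of `min_leaf = 10` — large enough that an
isolated mislabeled sample cannot earn its own pure leaf, small enough to
track a curved class boundary.  `fit_tree` itself keeps `min_leaf = 2`.

## SMOTE

Neighbourhoods are computed among minority samples only (Euclidean
distance in the encoded cube, ties by lower index, self excluded by index
so duplicated points remain mutual neighbours).  Parents are visited
round-robin over a seeded shuffle, so per-parent synthetic counts differ
by at most one and the balanced-count postcondition is exact; the
neighbour is drawn uniformly from the k nearest and δ ~ U(0, 1).  k
defaults to 5, the canonical setting.  Originals are kept first,
synthetics appended; an optional provenance table records (parent,
neighbour, δ) per synthetic row for auditability.

## Fuzzy self-tuning swarm

Minimization convention: callers maximizing accuracy pass 1 − accuracy
(the "Better" membership attaches to negative fitness increments).

* Swarm size: `floor(10 + 2·√M)` — 12 particles for the two-dimensional
  (C, γ) problem.
* Inputs: δ = distance to the global best, fuzzified Same/Near/Far with
  breakpoints at 0.2/0.4/0.6 of the box diagonal δ_max; φ = step-scaled,
  worst-fitness-normalized fitness increment in [−1, 1], fuzzified
  Better/Same/Worse.  Both membership triples are partitions of unity.
  f_wor is the largest fitness observed over all evaluations so far; if it
  is 0, φ := 0.  On the first iteration (no previous move) φ := 0.
* Outputs: w ∈ {0.3, 0.5, 1.0}, c_soc ∈ {1, 2, 3}, c_cog ∈ {0.1, 1.5, 3},
  λ ∈ {0, 0.001, 0.01}, η ∈ {0.1, 0.15, 0.2} (Low/Medium/High), combined
  by zero-order Sugeno inference (activation-weighted mean; all-zero
  activation falls back to Medium).
* Rule base: shipped as editable YAML data (`rulebase.yaml`), not code.
  The qualitative design: an improving particle keeps momentum (high w)
  and trusts its own memory (high c_cog); a worsening or distant particle
  is pulled toward the global best (high c_soc) with larger velocity caps;
  a particle near the best takes small careful steps.  All swarm tests are
  rule-base-agnostic (partition of unity, Sugeno boundedness, convergence),
  so refining the table cannot silently break the optimizer.
* Update: v′ = w·v + c_soc·r₁∘(g − x) + c_cog·r₂∘(b − x); |v′| is clamped
  per dimension into [λ·range, η·range] preserving sign (exact-zero
  components stay zero — there is no sign to give the floor); walls are
  absorbing (position clamped, offending velocity component zeroed).  The
  attraction form (g − x), (b − x) is used; the repulsive (x − g), (x − b)
  variant is available behind `repel=True` for comparison but diverges
  from every best-seeking convergence property.

## SVM tuning

The soft-margin QP is delegated to scikit-learn's SVC; the package tests
the kernel contract, the dual box constraint |βᵢyᵢ| ≤ C and the zero-sum
equality, rather than re-deriving an SMO solver.  Fitness is mean
stratified 5-fold cross-validated accuracy on the training partition with
folds fixed by seed, so every (C, γ) is scored on identical folds;
tuning never sees the test set.  The search box defaults to [0, 30]² with
both parameters floored at 10⁻⁶ before evaluation, since an RBF-SVM is
degenerate at 0; 30 iterations by default.

## Pipeline

`mode="paper"` (default) runs filter → SMOTE → split → tune → test in
that order, faithful to the method's published flow: the whole dataset is
cleaned and balanced before the train/test split.  Synthetic neighbours of
eventual test points are then visible in training, so test metrics are
optimistically biased; the pipeline logs a loud warning.  `mode=
"leak_safe"` splits first and fits the filter, encoder and SMOTE on the
training partition only — the honest variant for generalization claims.
Default test fraction 0.2 (configurable).  Every stage writes counts,
seeds and chosen hyperparameters into a JSON manifest; the filter audit
and tuning trace are exported as CSV.

The repeated-run harness derives per-repeat seeds from a master seed
(`numpy.random.SeedSequence`, kept below 2³¹), reports per-repeat metrics
and their means (10 repeats by default), and the paired t-test (two-tailed,
df = n−1) compares metric sequences pairwise by repeat index.  Degenerate
t-tests are handled explicitly: all-zero differences → (t=0, p=1);
nonzero zero-variance differences → p=0, flagged.

## Numerical choices and problem sizes

Entropies use base-2 logs with an 10⁻¹² guard; AUC is the rank-based
Mann–Whitney statistic with average ranks (ties count ½), identical to
trapezoidal ROC area.  Test and acceptance runs use deliberately small
problem sizes chosen to exercise each property at full fidelity: filter
recovery on n = 250 (200/50, separation 6, 10% flips, 5 folds, 10 seeds);
grid-oracle comparison on n = 100 with a 50×50 logarithmic grid over the
same box; the end-to-end contrast on 400/70 with 5 committee folds and 15
swarm iterations per run over 10 master seeds.

## Known limitations

* The stage order of `mode="paper"` inflates test metrics by construction;
  headline numbers from that mode measure fit to the balanced, cleaned
  distribution, not generalization to raw imbalanced data.
* The filter assumes noise is label-flipping on an otherwise learnable
  concept; under heavy class overlap it removes genuine boundary minority
  samples, and the committee's leaf floor trades boundary resolution for
  noise robustness.
* SMOTE interpolates in the one-hot cube, so synthetic "nominal" values
  are fractional; the SVM is indifferent, but the synthetics are not valid
  rows of the original categorical domain.
* The swarm's rule table is a qualitative reconstruction of the
  self-tuning design; its convergence properties are tested, its exact
  coefficients are editable data.
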