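# Methods

## Problem setting

`rehabselect` targets a binary prognosis task from shoulder-replacement
rehabilitation: each patient (case) is described by 16 numeric predictors —
age and five passive range-of-motion (ROM) angles measured before surgery
and at 3 and 6 months after — plus the total rehabilitation time in months.
Rehabilitation time is binarized at a threshold (4.5 months by default) into
class 0 (fast recovery) and class 1 (slow recovery). The scientific question
the package operationalizes is not only "can the outcome be classified?" but
"how few training cases suffice to classify the rest perfectly?" — an
instance-selection (training-set minimization) problem over the
2^N − 2 possible non-degenerate train/test splits of an N-case table.

## Base learners (Phase I)

- **KNN.** Majority vote among the K nearest training cases under Euclidean
  distance, K odd in {3, 5, 7, 11, 13} by convention (default 3). Neighbors
  are ranked by (distance, training order) so ties at the K-th distance are
  deterministic; an even-K tied vote resolves to class 0. Features enter raw
  (no standardization) to match the procedure the package models; a z-score
  flag exists for sensitivity checks.
- **2-means.** Lloyd's algorithm with K = 2 on the training features:
  centroids initialize from two distinct seeded sample points; an emptied
  cluster is re-seeded with the point farthest from its current centroid;
  iteration stops at an assignment fixed-point, a centroid shift below
  `tol = 1e-6`, or 100 sweeps. Each cluster is then mapped to the majority
  class of its training members (empty cluster or tie → the cluster's own
  index — the mapping is this package's documented choice; the procedure it
  models never states one), and test cases take the class of their nearest
  centroid (distance tie → lower cluster index). `init_indices` allows
  deterministic restarts, which the exactness tests use to reach the global
  optimum on tiny instances.
- **Accuracy.** All evaluation is plain accuracy
  `(tp + tn) / (tp + tn + fp + fn)` on the test side of a split.

## GA clustering (GAClust)

A binary genome of length S (the training-set size) assigns each training
case to cluster 0 or 1. The two cluster centroids — mean feature vectors —
classify the test set by nearest centroid, with the cluster index taken
directly as the predicted class (the outcome classes are themselves defined
as clusters 0/1, so no relabeling search is performed). Fitness is the
test-set accuracy; the GA maximizes it. Empty-cluster genomes are legal:
classification degenerates to the single available class, which avoids
penalizing early generations. An exactly equidistant test case goes to
class 0.

Two properties of this design are worth flagging. First, fitness is measured
on the test set itself, exactly as in the procedure the package models; the
resulting accuracy is therefore optimistically biased as an estimate of
out-of-sample performance and should be read as "a split and clustering
achieving this accuracy exists", not "this accuracy generalizes". Second,
complementing the genome swaps the two predicted classes, so
fitness(complement) = 1 − fitness(genome) whenever both clusters are
nonempty and no test point is exactly equidistant.

## Hybrid instance selection (GAKNN, GAKmeans, GA2Clust)

An outer GA evolves a membership genome of length N: gene 1 places the case
in the training set, gene 0 in the test set. Fitness is the scalarized
two-objective function

    f = acc − alpha · S / N

with `acc` the test-side accuracy of the wrapped evaluator, `S` the number
of selected cases, and `alpha ≥ 0` the size-penalty weight (defaults 0.28
for GAKNN with K = 3, 0.5 for GAKmeans, 0.625 for GA2Clust — the settings
the modeled experiments report). Degenerate genomes (S = 0 or S = N) and
subsets the evaluator cannot use (S < K for KNN, S < 2 for 2-means) receive
accuracy 0, keeping fitness total so the GA can move through them. Because
an S = 0 genome then scores fitness 0, it can formally outrank every legal
subset when alpha is extreme; a `SubsetResult` therefore always reports the
best *non-degenerate* genome encountered during the run — a selection must
be a usable partition — while the GA's internal fitness keeps the total
definition.

GA2Clust nests a full GAClust run inside each outer evaluation: the inner
GA clusters the selected training cases and its best test accuracy supplies
`acc`. Inner runs are seeded deterministically from the outer seed and a
CRC-32 hash of the genome (kept below 2^31), and evaluations are memoized by
exact bit string, so cached and fresh values agree and the nested search
stays affordable. The same genome-derived seeding fixes the 2-means
initialization inside GAKmeans, making every hybrid fitness a deterministic
function of (genome, outer seed).

## GA engine

Generational GA on fixed-length bit vectors: fitness-proportional
(roulette-wheel) selection, uniform crossover (probability 0.8; fair coin
per locus), per-bit flip mutation (probability 0.01), and elitism cloning
the two fittest individuals (ties by lower population index), so the
per-generation best fitness is non-decreasing. Because the subset fitness
can be negative, roulette weights use the shift policy
`w_i = f_i − min(f) + 1e-9`, which preserves ordering and degrades to
uniform selection when all fitnesses are equal. Parents are drawn with
replacement; pairs produce two offspring until the population is refilled,
discarding the odd remainder. One master seed spawns independent named
streams (init, selection, crossover, mutation) via `numpy` `SeedSequence`,
so runs are reproducible bit-for-bit and operators replayable in isolation.

The per-bit mutation rate 0.01 is calibrated for genomes of length ~120
(about 1.2 flips per offspring). On the short genomes used in the
exhaustive-oracle tests (L ≤ 16) that rate explores far too slowly, so
those tests run with mutation 1/L; this is a test-scale configuration
choice, not a change to the modeled settings.

## Synthetic cohort generator

The generator emulates the *statistical shape* of the modeled 120-patient
cohort, not its clinical distributions (which are private): 16 truncated-
Gaussian features around plausible ROM baselines (flexion/abduction up to
180°, rotations up to 90°, hyperextension up to 60°, age ~72 y), with
post-operative means improving over pre-operative; isotropic within-class
noise (SD 10 units); and rehabilitation times drawn uniformly from
per-class ranges (4.0–4.4 and 4.5–6.0 months) straddling the 4.5-month
threshold, so binarization recovers the generating class exactly unless an
optional label-noise rate decouples them.

Class structure is controlled by `separation`: the Euclidean distance
between the class mean vectors in within-class-SD units, applied along the
unit diagonal of feature space. Defining separation as *total* distance
(rather than per-feature shift) keeps the difficulty meaningful in 16
dimensions — a per-feature shift of even 1 SD would make the classes
trivially separable. The default, separation 3.0, gives strong but
imperfect structure: typical random-split KNN accuracy ~0.88–0.95, while
perfect splits exist for well-chosen subsets. That is precisely the regime
in which instance selection is non-trivial — the GA must place the
boundary-region cases in the training set — and it is what makes the
random-subset baseline comparison meaningful (on perfectly separated blobs
every random subset would also score 1.0). `generate_separable_toy`
provides that perfectly separated case (two Gaussian blobs with a large
margin) for exactness tests.

What passing tests on synthetic data do and do not show: they validate the
algorithms — that the GA finds minimal perfect training subsets when they
exist and matches exhaustive search at small N — not any clinical claim
about real shoulder-rehabilitation cohorts, whose feature distributions,
correlations and class overlap the generator does not attempt to match.

## Experiment harness and problem sizes

The Phase-I sweep draws seeded random partitions at training fractions 10%
to 90% (step 10%; size round-half-up, so fractions of 120 give exactly
12…108), evaluates the base learner on each test side, and reports mean,
standard deviation, minimum, maximum and the count of perfect replicates
per fraction. The replicate count is a parameter: the package's standard
desk-scale setting is 200 per fraction, chosen to estimate means and
extremes stably while keeping a full sweep in seconds; the modeled
experiment design used 100,000 replicates, which the same harness supports.

Likewise the nested GA2Clust defaults to a desk-scale budget (outer
population 30 × 80 generations over a memoized fitness, inner population
20 × 30 generations), which reaches perfect accuracy with ~15% of cases in
training on the default cohort in about two minutes; the paper-scale outer
budget (population 500, 5000 generations) is reachable through the same
configuration objects. GAKNN uses population 100 × 100 generations and
GAKmeans 100 × 500, matching the modeled settings directly since they are
cheap.

Subset-count combinatorics (`count_subsets`, `total_search_space`) use exact
big-integer arithmetic; the count of ways to pick 84 of 120 cases is
≈ 5.43 × 10^30 and the full genome space 2^120 ≈ 1.33 × 10^36.

## Numerical and degenerate-input policy

- Partitions must leave both sides nonempty; violations raise
  `DegeneratePartitionError` at the data layer and score accuracy 0 inside
  GA fitness (see above).
- CSV I/O is comma-separated, dot-decimal, UTF-8, header required, with
  `%.10g` floats — lossless round-trips for the generator's values.
- All classifier and GA tie-breaks are documented above and deterministic;
  there is no hidden RNG consumption outside the named streams.
- Case indexing is 1-based everywhere user-visible, matching the packaged
  training-set listings.

## Known limitations

- Test-set-coupled fitness (both GAClust and the hybrids) means reported
  accuracies certify the existence of a perfect split, not generalization;
  a held-out-validation variant would change the question being asked.
- Only Euclidean distance is implemented; Manhattan/Mahalanobis tags raise.
- No Pareto-front machinery: the two objectives are scalarized by alpha,
  and different alphas must be run separately.
- The 2-means evaluator inherits Lloyd's local-optimum sensitivity; inside
  the hybrids this is absorbed into the (deterministic, genome-seeded)
  fitness definition rather than eliminated.
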