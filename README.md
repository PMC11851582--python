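# rehabselect

Genetic-algorithm instance selection and GA clustering for binary
rehabilitation-prognosis classification.

## The problem

After reverse total shoulder arthroplasty (RTSA), patients follow a months-long
rehabilitation program. Given a case table of N patients × 16 numeric
predictors — age plus passive range-of-motion angles for five shoulder
movements measured pre-operatively and at 3 and 6 months post-operatively —
and the total rehabilitation time `Trt` (months), the outcome is binarized at
a threshold (4.5 months by default):

    y = 0  if Trt < 4.5      (fast recovery)
    y = 1  if Trt ≥ 4.5      (slow recovery)

Beyond plain classification, the package answers a data-economy question:
**what is the smallest training subset that still classifies every remaining
case correctly?** With N cases there are 2^N − 2 non-degenerate train/test
splits (≈ 10^36 for N = 120), so the search is delegated to a genetic
algorithm (GA).

## Algorithms

**Phase I — base learners over random splits**

- `knn`: K-nearest neighbors (Euclidean, K ∈ {3, 5, 7, 11, 13}), accuracy
  `acc = (tp + tn)/(tp + tn + fp + fn)` on the test side.
- `kmeans`: Lloyd 2-means on the training features, clusters mapped to
  classes by training-label majority, test cases classified by nearest
  centroid.
- `GAClust`: a GA evolves a binary genome of length S (one bit per training
  case = its cluster); the two cluster centroids classify the test set and
  fitness f1 = acc is maximized.

**Phase II — GA training-set minimization (instance selection)**

An outer GA evolves a membership genome of length N (bit 1 = case is in the
training set) under the two-objective scalarized fitness

    f2 = acc − α · S / N

where S is the training-set size and α weights size against accuracy.
The accuracy term comes from KNN (`GAKNN`, α = 0.28, K = 3), 2-means
(`GAKmeans`, α = 0.5), or a nested inner GAClust run (`GA2Clust`,
α = 0.625). GA operators throughout: roulette-wheel selection, uniform
crossover (0.8), bit-flip mutation (0.01), elitism of 2.

The package also ships, as packaged fixtures, the four published optimal
training-set case listings for these algorithms on the original (private)
120-patient cohort — sizes 64 (53.33%), 42 (35%), 50 (41.67%) and
43 (35.83%) — and a synthetic cohort generator so everything is runnable
and testable without the private data.

## Worked example

Generate a 120-case synthetic cohort and run GAKNN instance selection:

```
$ rehabselect generate --n-cases 120 --seed 0 --out cohort.csv
wrote cohort.csv and cohort_truth.csv

$ rehabselect select --dataset cohort.csv --algorithm gaknn \
      --k 3 --alpha 0.28 --seed 1 --out-dir out/
gaknn: accuracy 1.0000, S=31/120 (25.83%), fitness 0.9277
wrote out/gaknn_trace.csv
wrote out/gaknn_training_cases.txt
```

Reading the output: the GA found a training subset of 31 of the 120 cases
(25.83%) whose 3-NN classifier labels all 89 remaining cases correctly
(accuracy 1.0000); the fitness 0.9277 is 1.0 − 0.28·31/120. The selected
case ids are in `gaknn_training_cases.txt`, and `gaknn_trace.csv` holds the
per-generation best/mean fitness and best subset size behind the run's
convergence curve. `rehabselect sweep` produces the Phase-I
accuracy-versus-training-fraction statistics (mean/std/min/max and
perfect-split counts per fraction), and `rehabselect gaclust` runs the
Phase-I GA clustering on one split. Every output directory contains a
`*_config.json` with the fully resolved settings for bit-for-bit
reproduction.

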