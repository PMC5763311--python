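# Methods

## Model and score

The package operationalizes prediction-based causality for pairs of
scalar series observed from one dynamical system. Both series are
delay-embedded (dimension E, lag τ); by Takens-type embedding theorems
the two point clouds reconstruct topologically equivalent attractors.
The score asks how nearly the two clouds are *exactly similar figures*:
with `d` the distance matrix of the predictor cloud and `D` that of the
predicted cloud, the scale γ = d₁₂/D₁₂ is estimated from the first two
points in temporal order, every remaining pair (i ≥ 3, j < i) contributes
a relative error ε_ij = |d_ij − γD_ij|/(γD_ij), and the errors are
aggregated through exp(−ε_ij), averaged per row and then across rows
with the factor 1/(n−1).

Properties that follow directly and are enforced by tests:

* **Bounds.** 0 < ε ≤ (n−2)/(n−1), with equality iff all ε_ij = 0. The
  outer normalization is deliberately kept as 1/(n−1) although the outer
  sum has n−2 terms, so a perfect pair at n = 3 scores 0.5 and at
  n = 10 scores 8/9 — the aggregation is implemented exactly as its
  defining formula states rather than silently "corrected" to
  1/(n−2).
* **Affine invariance.** Rescaling or shifting either series leaves the
  score unchanged (distances scale uniformly; γ absorbs the ratio), so
  an affine copy of a series attains the maximum score exactly.
* **Asymmetry.** Swapping predictor and predicted changes the error
  denominators, so the two directions of a pair generally score
  differently; the direction convention reads a high score for
  (predictor X, predicted Y) as "Y causes X".
* **Determinism.** Scoring contains no randomness.

A leave-one-out variant (`loo_scores`) deletes one embedded point at a
time from both clouds and rescores; the named scheme is not defined
precisely anywhere, so delete-one-point rescoring was chosen as the
plainest reading, and the full-data score remains the headline
statistic.

### Numerical choices and degenerate inputs

* Reference pair for γ: the first two points in temporal order
  (`reference_pair="first"`); `"farthest"` (the pair with maximal D) is
  available as a robustness option.
* d₁₂ = 0 or D₁₂ = 0 raises a degenerate-reference-pair error; a
  coincident pair of target points (D_ij = 0 in an evaluated term)
  raises by default so data problems surface, or — with
  `skip_degenerate_pairs` — drops that term and renormalizes the inner
  mean over the remaining terms.
* Missing values are rejected at construction; with ~10 samples any
  imputation would dominate the result.
* In the all-pairs driver a degenerate pair is logged and left NaN
  instead of failing the whole matrix.
* n in the aggregation counts *embedded* points, which is fewer than
  raw time points when E > 1.

### Embedding defaults

E = 2, τ = 1, standardization off. Short series are the design target
and n = T − (E−1)τ must stay ≥ 3, so the default embedding maximizes
the point count while still unfolding the one-step dynamics; there is
deliberately no automatic E/τ selection (false-nearest-neighbour-style
estimators are unreliable at ten samples). Standardization is a no-op
for the score itself (affine invariance) but is exposed for
completeness and for users exporting embedded coordinates.

## Synthetic data

Three generators provide ground-truthed benchmarks.

**Coupled logistic maps.** X(t+1) = X(t)[r_x − r_x X(t) − β_xy Y(t)],
Y(t+1) = Y(t)[r_y − r_y Y(t) − β_yx X(t)], defaults r_x = 3.8,
r_y = 3.5, β_xy = 0.02, β_yx = 0.1, X(1) = 0.4, Y(1) = 0.2 — the
standard two-species chaotic benchmark; the one-way variant forces
β_yx = 0 so that Y is autonomous and Y → X is the only true influence.
No transient is discarded by default (the benchmark uses the raw
trajectory from its default initial conditions); `burn_in` is available
as a robustness knob.

**5-species coupled map.** Five logistic-type species with a fixed
default coefficient matrix: species 1–3 are mutually coupled and drive
species 4 and 5, which influence nothing — 12 true directed edges out
of 20 ordered pairs. Initial conditions are not part of the benchmark
definition and are drawn uniformly from (0.2, 0.8); roughly a quarter
of draws escape the unit box (the map is not globally stable), so
`sample_bounded_five_species` redraws until the trajectory stays
bounded.

**Gene-network generator.** A directed Erdős–Rényi topology without
self-loops (expected in-degree 1.5, activator/repressor with equal
probability), node dynamics
dx_i/dt = m_i · Π_regulators(hill term) − δ·x_i with Hill coefficient
h = 2, per-edge half-saturation K ~ U(0.3, 1), degradation δ = 1,
maximal rates m_i ~ U(0.5, 1.5), integrated by fixed-step RK4 (400
steps) from a random positive state and subsampled to 10 equally spaced
points over 2 relaxation times (2/δ) — a window chosen so the sampled
curves retain transient dynamic range rather than sitting at steady
state. Measurement noise is additive Gaussian per entry with standard
deviation `level × sd(gene)`, the most common reading of a unitless
"noise level" (0, 0.1, 0.2); the level-0 path returns the input
unchanged. All three seeds (topology, dynamics, noise) are explicit,
and the returned truth network is exactly the integrator's topology
(verified by edge-deletion intervention in the tests).

What this generator does *not* emulate: real regulatory-network
topology (hubs, motifs, modularity), transcription/translation delays,
intrinsic molecular noise inside the dynamics, and perturbation-design
experiments. Passing or failing benchmarks on it therefore speaks to
the method's behaviour on smooth relaxation kinetics at ten samples,
not to any specific organism's network.

## Evaluation

Every ordered pair of distinct variables is a ranking instance,
positive iff the truth contains that directed edge; self-pairs are
excluded and unscored pairs are dropped with a logged count. AUC is the
tie-aware Mann–Whitney U statistic (ties count half) — short series
produce genuinely tied scores, and this convention makes
AUC(s) + AUC(−s) = 1 exact. The threshold-free ROC/AUC surface is the
primary evaluation; `detect` provides score-threshold and top-k calls
for users who need a binary matrix, since no principled cutoff is part
of the method's definition (the pointwise prediction tolerance 10⁻³
carried in `DetectionConfig.error_tolerance` is a neighborhood
criterion, not a score cutoff).

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data at desk scale: the logistic pair at 3–10 points, the 5-species
system at up to 25 points with 10 seeded initial conditions, one
100-gene network (10 time points) to exercise the 9900-pair driver, and
20 replicate 20-gene networks per noise level for the ranked-recovery
benchmark.

## Known limitations

* **The score measures geometric similarity, and similarity is not
  causation.** Its directional asymmetry is second-order (it enters
  only through the error denominators). On the chaotic logistic pair
  the asymmetry aligns with the true direction and the structure is
  recovered from as few as 4 points. On the 5-species map it does not:
  the 15-point score matrix orders pairs essentially at chance
  (median AUC ≈ 0.5 over seeded initial conditions, and no embedding
  choice, burn-in, leave-one-out averaging, direction reading, or
  longer series up to 50 points reaches perfect recovery). The
  acceptance script reports this outcome as unattained rather than
  substituting a different statistic.
* **Relaxation kinetics invert the ranking.** On the gene-network
  generator, unregulated genes all follow near-exponential decays that
  are close to affine copies of one another, so *non*-interacting pairs
  score near the maximum and true edges rank below chance
  (AUC ≈ 0.45–0.48 at noise 0–0.2). Ranked recovery on smooth
  dissipative dynamics should not be expected from this score.
* The first-two-points γ estimate makes the score sensitive to the
  first two samples; `reference_pair="farthest"` trades literalness for
  robustness.
* No significance testing or multivariate conditioning (direct vs
  indirect influence) is provided; scores are comparable within one
  dataset's ranking, not across datasets.
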