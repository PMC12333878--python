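# Methods

This note documents the models, procedures and numerical choices behind
`dfcdist`, in the spirit of a statistical package's methods appendix.  It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Dynamic functional connectivity construction

A subject's input is a T_pts × M matrix of regional signals at a fixed
sampling interval (3 s by default).  Scans with fewer than 90 or more than
600 time points are flagged excluded — reported with a reason, never
silently dropped — mirroring the temporal-coverage inclusion rule the
analysis assumes.

Windows are half-open: a window starting at sample t contains exactly
s samples (default s = 5, i.e., 15 s), and consecutive windows start
c samples apart (default c = 2, 6 s).  We reject the closed-interval
reading (s + 1 samples) because it contradicts the 15-second window span
implied by s = 5 at 3 s sampling.  Within each window the connectivity of
regions j, k is the absolute Pearson correlation of their s-sample
segments; the diagonal is set to 0.  A zero-variance (constant) segment
yields 0-valued edges for all its pairs with a logged warning; this keeps
every matrix a valid connectivity matrix and is conservative for the
downstream distances (absent evidence maps to absent connectivity).
Correlations are clipped to [0, 1] to absorb round-off.

Trimming order is fixed and asserted by tests, because the individual
steps are standard but their interaction is a design choice:

1. clip trailing samples that do not fill a complete window;
2. drop the first and last complete windows (boundary-artifact guard);
3. harmonize across subjects by truncating every sequence **from the end**
   to the cohort minimum (or an explicit target).

End-truncation (rather than start- or symmetric truncation) is our
documented choice; any fixed rule is defensible and the tests pin ours.

## Distance metrics

Element-wise metrics follow the printed Σ_{i,j} convention over the full
matrix, so each undirected edge contributes twice to Manhattan and
Frobenius (the diagonal contributes nothing).  Upper-triangle-only sums
would differ by constant factors 2 and √2 respectively; permutation
p-values are invariant to any such monotone rescaling, so the convention
only affects reported magnitudes.

The nuclear distance is the sum of singular values of the matrix
difference (`numpy.linalg.svd`).  The spectral distance sorts each
symmetric matrix's eigenvalues ascending before taking the Euclidean norm
of the difference; for symmetric matrices any consistent ordering is
equivalent, which the tests assert implicitly through the Hoffman–Wielandt
bound (spectral ≤ Frobenius).

### Persistence decomposition

A connectivity matrix is treated as a complete weighted graph on M nodes
(zero-weight edges permitted).  The graph filtration removes edges with
weight ≤ ε as ε increases; component births across this filtration are
exactly the edge weights of a maximum spanning tree (M − 1 values), and
cycle deaths are the remaining 1 + M(M − 3)/2 off-diagonal weights.  The
implementation computes the tree with
`scipy.sparse.csgraph.minimum_spanning_tree` on shifted costs 2 − w
(weights lie in [0, 1], so every cost is positive and every edge present),
then reads births and deaths from the tree's edge indices — never from
reconstructed values, so ties and floating-point are handled exactly.
Only the weight *multisets* are exposed; by matroid exchange they are
invariant to spanning-tree tie-breaking, which the tests verify against a
brute-force descending-threshold union-find filtration on graphs with
heavily duplicated weights.

The p-Wasserstein distance between two summaries with equal region counts
pairs sorted values (the optimal bijection for equal-cardinality
one-dimensional multisets) and returns (Σ|x_(l) − y_(l)|^p)^{1/p}.  The
order defaults to p = 2 — the convention in the persistent-homology
literature — and is exposed as a parameter (`wasserstein_order_p`,
`--wasserstein-p`).

## Summaries

Two reductions per subject and metric: the mean of the distance series
(sustained variability) and the mean of its five largest values
(transient disruptions).  "Peaks" are the largest *values*, not local
maxima of a smoothed curve; ties at the k-th value are resolved by taking
exactly k values in stable sorted order rather than fractional averaging.
The k = 5 guard is safe under the inclusion rule: ≥ 90 time points imply
≥ 40 transitions.

## Inference

Age is residualized by one pooled OLS fit (intercept + age) on the two
diagnostic groups of the sex stratum, computed once before permutation;
per-permutation re-residualization is not implemented.  Pooling both
groups (rather than fitting controls only) is our documented choice.

The permutation test uses T_obs = |x̄ − ȳ| and uniform random
reassignments of the pooled residuals into the original group sizes,
sampled independently across iterations (B = 50,000 by default).  When
C(m+n, m) ≤ 10,000 the test switches to exact enumeration of all
assignments.  The p-value estimator is the unsmoothed count proportion,
which can return 0; an optional smoothed estimator (1 + count)/(1 + B) is
available for users who need strictly positive p.  Counting uses a
relative tolerance of 10⁻¹² so assignments whose statistic ties T_obs in
exact arithmetic (e.g., the complement of the observed assignment when
m = n) are counted despite round-off.

Bonferroni correction divides the family level (0.05) by the eight tests
per metric family (2 contrasts × 2 sexes × 2 test types), giving 0.00625
(displayed as 0.006); the significance comparison is non-strict
(p ≤ threshold).  Each grid cell derives its random stream from the root
seed plus a CRC of (metric, contrast, sex, test type), so results are
independent of execution order.

## Synthetic cohort model

The generator emulates the *statistical* structure the analysis assumes,
not BOLD physiology.  Each subject's signal is

    x_t = A_t u_t + σ η_t,

with u_t ∈ R^r i.i.d. standard normal latent signals (r = `latent_rank`),
η_t white region noise (σ = `noise_sd`), and a mixing matrix A_t ∈ R^{M×r}
following a stationary mean-reverting process

    A_t = e^{−d} A_{t−1} + √(1 − e^{−2d}) G_t / √r,

whose decorrelation rate d controls how fast the true connectivity
pattern wanders while leaving the signal-to-noise ratio constant (a plain
random walk was rejected: its growing signal norm saturates |correlation|
and masks drift differences).  The rate is

    d = base_drift × (1 + sustained_effect[dx]) × (1 + age_effect × (age − mid-age)),

floored at 0.  Transient disruptions add an event-specific random mixing
perturbation of amplitude `peak_effect[dx]` during `n_peak_events`
contiguous intervals of `peak_event_duration` samples (default 10, long
enough to span whole analysis windows), so they surface as isolated maxima
in the distance series — the signal the 5-peak statistic targets.  Group
effects accept a scalar (DEMENTIA full effect, MCI half, NC zero) or an
explicit per-diagnosis mapping.

Cohorts are balanced: `n_per_cell` subjects per diagnosis × sex cell, ages
uniform on `age_range` (default 45–97 years), subject ids `sub-0000`….
One master seed spawns an independent stream per subject keyed by subject
index, so identical configurations are bitwise reproducible and
generation order is irrelevant.  Default scan lengths are sampled
uniformly over the full 90–600 inclusion range.

Effect magnitudes have no empirical calibration target — the reference
study reports no effect sizes on an interpretable scale — so the defaults
are illustrative: `base_drift` 0.05/sample, `noise_sd` 0.5,
`latent_rank` 5, all group and age effects 0.  What the generator does
*not* model: hemodynamic response, head motion, scanner artifacts,
spatial atlas structure, unbalanced group sizes.  Passing calibration
tests therefore shows the inference machinery is statistically sound
under the assumed signal model, not that real fMRI effects of any given
size are detectable.

## Calibration experiments and problem sizes

`dfcdist.experiments` repeats the full analysis path (simulate → windows →
distances → summaries → residualize → permutation test) over many
independently seeded cohorts.  The replicated experiments use scaled-down
cohorts chosen as the package's standard self-check conditions: 8 regions,
90 time points, 8 subjects per cell (16 per tested contrast) and B = 999
Monte-Carlo permutations — the cell size deliberately exceeds the
exhaustive-enumeration cutoff so the Monte-Carlo estimator itself is under
test.  The acceptance checks are:

* **Null calibration** — all effects zero makes subjects exchangeable;
  over 500 cohorts the rejection rate at α = 0.05 must lie within 3
  Monte-Carlo standard errors of 0.05 for both test types.
* **Peak-test power** — with a strong transient effect
  (`peak_effect` = 3) and no sustained effect, the 5-peak test must
  reject more often than the mean-based test on the same 300 cohorts.
* **Age confound** (module test) — with a pure age effect and
  age-imbalanced groups, the residualized test holds its size while an
  ablation skipping residualization inflates it.

Only the subjects entering the tested stratum are synthesized in these
loops; their streams are identical to the full cohort's, so this is a
computational shortcut, not a different experiment.

## Known limitations

* Pearson correlation captures only linear coupling; no nonlinear
  dependence measures are implemented.
* Persistence is restricted to the reduced birth/death summary
  (components and cycles); higher homology dimensions and full
  persistence diagrams are out of scope.
* Only age is adjusted for, by a linear pooled fit; no other covariates,
  interactions or longitudinal structure.
* The exact-enumeration cutoff (10,000 assignments) and the p-value tie
  tolerance (10⁻¹²) are fixed implementation constants.
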