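# Methods notes

This note documents the statistical procedure the package implements, the
design choices made where the procedure was underdetermined, the synthetic
generator's assumptions, and the numerical conventions that affect
reproducibility. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dynamic connectivity and graph construction

**Windowing.** Windows are half-open volume ranges `[s, s + L)` with 0-based
onsets advanced by the step; the first window starts at volume 0. With the
default L = 20 TRs (≈34 s at TR = 1.714 s) and step 1 TR, a 260-volume run
yields `⌊(260 − 20)/1⌋ + 1 = 241` windows. No within-window tapering is
applied.

**Correlation and Fisher z.** Within each window the plain Pearson
correlation of every node pair is Fisher-transformed, `z = atanh(r)`.
Perfect correlations would map to ±∞, so |r| is clipped to `1 − 1e−7`
beforehand; clipped pairs remain the strongest weights under any threshold
while keeping the ordering total and finite. A window in which a node is
exactly constant has no defined correlation; by default this aborts the
subject with an error naming subject, window and node (preprocessed BOLD
essentially never triggers it), and an opt-in `drop` mode removes such
windows with a logged warning. Constancy is tested exactly (window range
zero), not via a floating-point variance threshold.

**Proportional threshold.** Each windowed z-matrix is binarized by keeping
the `k = round(d · N(N−1)/2)` largest *signed* z values among the
upper-triangle entries (d = 0.20 by default: 38 of 190 edges at N = 20).
Signed — not absolute — selection follows the convention of binarizing
"above the threshold" to 1 and below to 0; an absolute-value mode is
available for sensitivity analyses. Ties at the cut are resolved by the
lexicographically smallest (i, j) pair, which makes the graph reproducible
across runs and platforms; a tie at the boundary is logged. Every window
therefore retains exactly k edges.

**Betweenness and ranks.** Betweenness is computed on the unweighted,
undirected, binarized graph as the unnormalized sum over unordered pairs of
geodesic fractions (Brandes' algorithm via networkx; validated in the tests
against exhaustive path enumeration on all connected ≤7-node isomorphism
classes and against an independent implementation on 20-node graphs).
Disconnected graphs are legal: unreachable pairs contribute nothing and
isolated nodes score zero. Per window, values are converted to descending
ranks 1…N with average ranks for ties. Ties are frequent (sparse graphs
leave many nodes at BC = 0), and averaging keeps every window's rank sum at
N(N+1)/2, which the downstream clustering relies on; normalization of BC is
irrelevant after ranking.

## Centrality modes

Per node, the windowed rank sequences of all subjects are concatenated along
time (20 subjects × 241 windows = 4820 one-dimensional observations at the
default geometry) and clustered by k-means under the cityblock metric. In
one dimension the cityblock-optimal centroid is the *median*, so the solver
performs median-update k-means; because nearest-centroid assignment
partitions sorted 1-D data into contiguous blocks, each iteration costs
O(k log n) after one sort. Initialization is k-means++-style seeding with
cityblock distances, 20 seeded restarts, at most 300 iterations, best
restart kept by total cityblock cost; an emptied cluster is re-seeded at the
currently worst-served observation. Non-convergence keeps the best iterate
and logs a warning. Observations are used raw (ranks are already
commensurate across nodes and subjects), and all validity indices use the
same cityblock metric as the clustering.

**Model selection.** The cluster count is chosen over the candidate grid
k ∈ {2, …, 6} by maximizing

    MPFC = (CS · AS · DI) / DB

with CS = n/k (average cluster size), AS = mean silhouette
`s(i) = (b(i) − a(i)) / max(a(i), b(i))`, DI = minimum inter-cluster
distance over maximum intra-cluster diameter (Dunn), and DB the
Davies–Bouldin index with cityblock scatter about the fitted centroids.
The grid upper end generously bounds the 2–3 modes that paper-like data
exhibit. Degenerate cases are defined explicitly: an empty cluster excludes
that k from the grid (logged); coincident centroids (zero Davies–Bouldin
denominator) score −∞; a clustering whose clusters all have zero diameter
but positive separation scores +∞ (perfect separation). Exact score ties —
including several +∞ — resolve to the smallest k. If no candidate attains a
defined score (e.g. a single tight level), the smallest k is returned and a
low-separation warning logged.

**High-centrality mode.** Modes are relabeled by ascending centroid, and the
mode with the *smallest* mean rank (rank 1 = most central) is the HCM. On
the rank scale a "high centrality" mode necessarily sits near rank 1; the
HCM centroids produced on synthetic cohorts (≈3–6, see
`scripts/acceptance.py`) are consistent with reported values near 4 on a
1–20 scale. This reading is fixed in code rather than configurable, because
the opposite reading (largest centroid) would select the *least* central
mode under the stated rank convention. HCM occupancy is the per-subject
count of windows labeled with the HCM.

## Association testing

Spearman's ρ is computed as the Pearson correlation of average-tie ranks;
an input with zero rank variance raises a typed degeneracy error rather
than propagating NaN (a degenerate node yields a flagged, non-significant
result instead of a test).

**Permutation rule.** The score vector is permuted (default 1000 times;
the identical permutation set is shared across nodes within one run so
per-node results are comparable), the correlation recomputed each time, and
`q99` taken as the 99th percentile of the signed permuted correlations. The
default two-sided rule declares significance when |ρ_obs| > q99; by the
symmetry of the permutation null this is a ≈2% level, which is what lets a
strongly *negative* correlation be declared significant by a 99th-percentile
rule. The empirical level under a null coupling is recomputed by the
acceptance suite (500 null cohorts) and lands slightly below 0.02 because
the observed statistic is discrete under heavy score ties. A one-sided
(`"less"`) mode comparing ρ_obs with the 1st percentile is available.
`p_perm = (1 + #extreme)/(n_perm + 1)` never reaches zero. No
multiple-comparison correction is applied across nodes by default (matching
the procedure being reproduced); a Benjamini–Hochberg utility is available.

**DCMN and linked modes.** The DCMN is the significant node with the
largest |ρ|; exact ties resolve to the smallest node index, and all nodes
remain visible in the returned table. With no significant node the result
is an explicit "no DCMN". The linked-mode count for node v is the number of
windows in which v shares an edge with the DCMN *and* the DCMN's mode label
is its HCM; the DCMN's own column is excluded. Partial Spearman
correlations rank all three variables (average ties), regress the metric
and score ranks on the covariate ranks with intercept, and correlate the
residuals; a constant covariate falls back to the plain ρ (logged), and
zero residual variance raises the typed degeneracy error.

## Synthetic cohorts

The generator emulates the study geometry — 20 subjects, 20 nodes, 260
volumes, TR 1.714 s — and a band-limited-like signal is *not* imposed by
default (see Limitations).

**States.** Each subject follows a two-state Markov chain over volumes with
stationary hub-state probability equal to the subject's target occupancy and
mean hub-state dwell `state_dwell_mean_tr` (default 40 TRs ≈ 69 s, i.e. a
couple of window lengths, so 20-TR windows can resolve the states; dwell
times of tens of seconds are in the range reported for dynamic connectivity
states). Per-subject target occupancies are evenly spaced over
`occupancy_range` (default 0.15–0.70, a wide but sub-saturating spread).
Within a state, samples are i.i.d. draws from that state's multivariate
normal (via Cholesky), plus white measurement noise of sd 0.2 relative to
unit signal variance; temporal autocorrelation realism is deliberately
sacrificed for testability.

**State covariances.** In the hub state the hub correlates ≈0.48 with ten
satellite nodes (≈0.55 with the two designated *linked* nodes, one per
group); the satellites form two within-correlated groups (r ≈ 0.45) with no
cross-group correlation, so after 20% thresholding the hub is the unique
bridge between the groups and attains the top betweenness (checked against
brute-force path enumeration). A positive-definiteness constraint shapes
these numbers: a correlation matrix cannot have one node correlated ≥0.6
with ten mutually weakly-correlated others, so the hub-satellite strength
and the within-group correlation are chosen jointly near the feasible
boundary. A further, state-constant clique (six nodes at r ≈ 0.42–0.50)
absorbs the remainder of the 38-edge budget so that near-threshold noise
edges rarely attach stray nodes; its center is "strongly connected" in both
states yet — being inside a symmetric clique — carries no betweenness.
The baseline state equals the hub state with the hub's row collapsed to
background (r ≈ 0.05): *only the hub's bridging role switches with the
Markov state*, so no competing dynamic hub is planted and non-hub nodes act
as statistical nulls. Small seeded jitter (±0.01) decorrelates replicate
cohorts; any indefiniteness is repaired by eigenvalue clipping and logged.
For toy networks (≤5 nodes) a simplified star construction with hub
correlations ≈0.65 is used.

**Scores.** The ULS marginal follows the reported clinical distribution
(5% none, 55% mild/moderate, 40% severe), apportioned by largest-remainder
rounding (n = 20 → counts 1/6/5/4/4 for ULS 0…4). Coupling to occupancy is
by rank-binning a latent score: the sign-flipped normal scores of the
occupancy ranks are mixed with seeded Gaussian noise and the sorted latent
receives the ULS levels in ascending order. The mixing weight is
`min(1, 1.45·|coupling_rho|)`; the gain compensates both the attenuation
from binning into five tied levels and the finite-cohort scatter of a
realized correlation at n = 20, so that the contract — a realized
Spearman(occupancy, ULS) at least as strong as the requested coupling (within
0.15) — holds in essentially every cohort rather than merely on average. At
`coupling_rho = 0` the mixing weight is exactly zero and scores are
independent of occupancy by construction. All randomness flows from the
single spec seed through `numpy.random.SeedSequence` spawning.

**What the generator does not emulate.** Hemodynamics, 1/f drift, motion
and physiological artifacts, spatial lesion structure, temporal
autocorrelation within states, and band-limited spectra. Passing recovery
tests therefore demonstrate that the pipeline detects a planted
state-switching hub under realistic dimensions and noise — not that it is
robust to fMRI-specific confounds, which are assumed to be handled by
upstream preprocessing.

## Band-pass filter

The optional filter (off by default, since real inputs arrive already
filtered) is a 4th-order Butterworth band-pass (0.029–0.15 Hz) applied
forward–backward (`sosfiltfilt`): zero phase, squared magnitude response.
Validated behavior: a mid-band tone is preserved within 5%, a 0.01 Hz tone
attenuated by more than 80%, constants are removed, and the operator is
linear.

## Validation problem sizes

The test suite exercises: the exact window count at the full study geometry;
edge-count conservation across all windows of simulated cohorts; the
betweenness oracle on all 995 connected ≤7-node graphs (one per isomorphism
class — label equivariance is checked separately, which extends the result
to all labelings) plus 200 random 20-node graphs at density 0.20 against an
independent implementation; MPFC selection on 100 seeded three-level
mixtures; permutation calibration on 500 null cohorts; and planted-hub
recovery on 25 full-size replicate cohorts. The acceptance script uses 10
replicate cohorts for its recovery block to keep a single run under a
minute.

## Known limitations

- Betweenness on proportionally thresholded graphs is sensitive to the
  chosen density; only the 20% default is exercised.
- The MPFC combines four indices multiplicatively with an n/k size factor,
  which biases toward small k when clusters overlap; that is inherent to
  the criterion, not tuned away.
- With 20 subjects the permutation rule has limited power; associations
  with |ρ| ≲ 0.55 are generally not detectable, and at a ~2% per-node level
  one spurious node per few cohorts is expected among 20 nodes.
- The partial-correlation control uses the rank-residual formulation; other
  definitions of a "partial Spearman" differ slightly in small samples.
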