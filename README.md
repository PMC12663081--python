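# dynhub

Dynamic graph-topology analysis of a small functional brain network:
sliding-window functional connectivity, time-varying betweenness-centrality
ranks, k-means "centrality modes", and permutation-tested association of
high-centrality-mode occupancy with an ordinal impairment score.

The package is aimed at researchers analyzing resting-state fMRI of a
motor network after stroke (or any small ROI set with a per-subject
behavioral score), and at methodologists who want a fully seeded, testable
re-implementation of this analysis with a ground-truth synthetic cohort.

## The analysis

For each subject with an ROI time series `X ∈ R^{T×N}` (here N = 20 motor
nodes, T = 260 volumes, TR = 1.714 s):

1. **Sliding windows.** Cut `X` into windows of L = 20 TRs stepped by 1 TR:
   `W = ⌊(T − L)/step⌋ + 1 = 241` windows.
2. **Windowed connectivity.** Per window, Pearson correlation `r_w(i,j)`
   between all node pairs, Fisher-transformed `z = atanh(r)`.
3. **Proportional threshold.** Binarize each window keeping the
   `k = round(0.20 · N(N−1)/2) = 38` strongest (signed) z edges.
4. **Betweenness ranks.** Per window, unnormalized betweenness centrality
   `BC(v) = Σ_{s≠v≠t} σ_st(v)/σ_st`, converted to within-window descending
   ranks 1 (most central) … N (least central), ties averaged.
5. **Centrality modes.** Per node, k-means (cityblock distance, 1-D
   median-update) over the cohort-concatenated windowed ranks; the cluster
   count is chosen by the mixed performance criterion
   `MPFC = (CS · AS · DI) / DB` (average cluster size × average silhouette ×
   Dunn index / Davies–Bouldin index). The mode with the smallest centroid
   (mean rank nearest 1) is the **high-centrality mode (HCM)**; a subject's
   HCM occupancy is the number of windows spent in it.
6. **Association.** Per node, Spearman's ρ between HCM occupancy and the
   upper-limb score (ULS, 0 = no deficit … 4 = severe) across subjects,
   tested against 1000 permutations of the score: significant when |ρ|
   exceeds the 99th percentile of the permuted-correlation null. The
   significant node with the largest |ρ| is the **dynamic central motor
   node (DCMN)**. For every other node, the **linked mode** counts windows
   in which it shares an edge with the DCMN while the DCMN sits in its HCM,
   and the same permutation test is applied. Partial Spearman correlations
   (rank-residual formulation) support covariate controls such as lesion
   size.

Because no patient data are distributed, a synthetic-cohort generator plants
a hub node that switches (two-state Markov chain) between a bridging,
high-betweenness connectivity state and a baseline state, with per-subject
hub-state occupancy negatively rank-correlated with the ULS. Every
downstream stage therefore has a ground-truth recovery test.

## Worked example

```sh
python - <<'PY'
from dynhub import SyntheticCohortSpec, simulate_cohort, write_cohort
spec = SyntheticCohortSpec(seed=42)            # 20 subjects, 20 nodes, 260 volumes
series, truth = simulate_cohort(spec)
write_cohort(series, truth, "demo/cohort")
print("planted hub:", truth.hub_index, "| linked:", truth.linked_nodes)
PY
dynhub run --manifest demo/cohort/manifest.csv --out demo/run --seed 42
dynhub report --run demo/run
```

prints

```
planted hub: 5 | linked: (1, 7)
DCMN: node 5 (rho=-0.7079, p=0.001998)
dynhub 0.1.0 run summary
  subjects: 20  nodes: 20  windows/subject: 241  edges/window: 38
  modes per node: k=2:13, k=3:7
  DCMN: node 5 rho=-0.7079 p=0.001998
  significant nodes (HCM-ULS): [5, 13]
```

Reading: each subject's 260 volumes produced 241 windows of 38-edge graphs;
every node's rank trace clustered into 2–3 centrality modes; the planted hub
(node 5) was identified as the DCMN with ρ = −0.71 (permutation p ≈ 0.002),
i.e. subjects with worse upper-limb scores spent fewer windows in the hub's
high-centrality mode. (`[5, 13]` lists every node passing the 99th-percentile
rule; node 13 is a false positive of the ~2% two-sided level.) The run
directory contains `occupancy.csv`, `modes.csv`, `association_hcm.csv`,
`association_linked.csv`, `linked_mode.csv`, `run_metadata.json` and the
resolved configuration.

The same analysis is available as a library (`dynhub.analyze_cohort`,
`dynhub.run_pipeline`) for use on real manifests of delimited-text ROI
series.

## Layout

- `src/dynhub/synthetic.py` — cohort generator with planted state-switching hub
- `src/dynhub/io.py` — delimited-text ROI series + manifest I/O, band-pass
- `src/dynhub/dfc.py` — sliding-window Fisher-z connectivity
- `src/dynhub/topology.py` — proportional threshold, betweenness, ranks
- `src/dynhub/modes.py` — cityblock k-means, MPFC, HCM occupancy
- `src/dynhub/association.py` — Spearman, permutation tests, DCMN, linked modes
- `src/dynhub/pipeline.py`, `src/dynhub/cli.py` — orchestration and CLI
- `docs/methods.md` — model, parameter and design notes
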