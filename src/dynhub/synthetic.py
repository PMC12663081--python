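"""Synthetic cohorts with a planted state-switching hub node.

Real patient recordings behind this kind of analysis are not publicly
deposited, so every downstream stage is exercised on simulated cohorts with
known ground truth.  The generator emulates the study geometry — 20 subjects,
20 motor-network nodes, 260 volumes at TR = 1.714 s — and plants:

* a designated *hub* node that alternates between two connectivity states.
  In the hub state it bridges two otherwise uncorrelated satellite groups,
  so after proportional thresholding it lies on most shortest paths (top
  betweenness).  In the baseline state its correlations are weak and a
  different node is strongly connected — but inside a clique, which carries
  no betweenness, so no competing dynamic hub is planted.
* two designated *linked* nodes (one per satellite group) whose edges to the
  hub are the strongest, so their co-occurrence with the hub's
  high-centrality windows tracks hub-state occupancy.
* a per-subject upper-limb score (ULS, 0-4) whose rank correlation with
  hub-state occupancy is driven toward ``coupling_rho`` (negative: more
  impaired subjects spend less time in the hub state), with the cohort ULS
  marginal matching the reported clinical distribution (~5% none, ~55%
  mild/moderate, ~40% severe).

State switching is a two-state Markov chain parameterized by stationary
occupancy and mean dwell time; samples are temporally white within state
(autocorrelation realism is deliberately traded for testability).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .io import CohortManifest, RoiTimeSeries, write_timeseries

__all__ = [
    "SyntheticCohortSpec",
    "GroundTruth",
    "StateStructure",
    "state_structure",
    "make_state_covariances",
    "simulate_subject",
    "simulate_cohort",
    "assign_uls",
    "write_cohort",
]

log = logging.getLogger(__name__)

#: cohort ULS marginal: none / mild / moderate / severe(3) / severe(4)
ULS_MARGINAL = (0.05, 0.275, 0.275, 0.20, 0.20)

#: gain mapping |coupling_rho| to the latent mixing weight of `assign_uls`;
#: compensates the rank->5-level binning attenuation and the finite-cohort
#: scatter of the realized correlation, so that Spearman(occupancy, ULS)
#: lands at or beyond the requested coupling in essentially every cohort
#: (the coupling contract is one-sided: at least as strong as the target).
_COUPLING_GAIN = 1.45


@dataclasses.dataclass(frozen=True)
class SyntheticCohortSpec:
    """Cohort-level generator settings (defaults mirror the study geometry)."""

    n_subjects: int = 20
    n_nodes: int = 20
    n_volumes: int = 260
    tr_seconds: float = 1.714
    hub_index: int = 5
    occupancy_range: tuple[float, float] = (0.15, 0.70)
    coupling_rho: float = -0.6
    state_dwell_mean_tr: float = 40.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.occupancy_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ParameterError("occupancy_range must satisfy 0 <= lo < hi <= 1")
        if not (0 <= self.hub_index < self.n_nodes):
            raise ParameterError("hub_index must be a valid node index")
        if self.n_nodes < 3:
            raise ParameterError("need at least 3 nodes")
        if not (-1.0 <= self.coupling_rho <= 0.0):
            raise ParameterError("coupling_rho must lie in [-1, 0]")
        if self.state_dwell_mean_tr <= 0 or self.noise_sd <= 0:
            raise ParameterError("dwell time and noise_sd must be positive")
        if self.n_volumes < 20:
            raise ParameterError("n_volumes must cover at least one 20-TR window")


@dataclasses.dataclass
class GroundTruth:
    """What was planted: per-subject occupancies, scores and state paths."""

    occupancy: np.ndarray  # empirical fraction of volumes in the hub state
    uls: np.ndarray  # integers 0..4
    states: list[np.ndarray]  # per subject, length-T binary (1 = hub state)
    hub_index: int
    linked_nodes: tuple[int, ...]


@dataclasses.dataclass(frozen=True)
class StateStructure:
    """Deterministic node roles used by the two state covariances."""

    hub: int
    satellites_a: tuple[int, ...]
    satellites_b: tuple[int, ...]
    linked: tuple[int, ...]
    alt_center: int
    alt_clique: tuple[int, ...]


def state_structure(n_nodes: int, hub_index: int) -> StateStructure:
    """Assign node roles for the two planted connectivity states."""
    others = [i for i in range(n_nodes) if i != hub_index]
    if len(others) <= 4:
        sats = others
        alt = others[0]
        alt_clique = tuple(i for i in others if i != alt)
    else:
        alt = others[0]
        pool = others[1:]
        n_sat = min(10, max(2, len(pool) * 2 // 3))
        sats = pool[:n_sat]
        alt_clique = tuple(pool[n_sat : n_sat + 5])
        if not alt_clique:  # very small networks: reuse satellites
            alt_clique = tuple(sats[: max(2, len(sats) // 2)])
    half = (len(sats) + 1) // 2
    group_a, group_b = tuple(sats[:half]), tuple(sats[half:])
    linked = tuple(g[0] for g in (group_a, group_b) if g)
    return StateStructure(
        hub=hub_index,
        satellites_a=group_a,
        satellites_b=group_b,
        linked=linked,
        alt_center=alt,
        alt_clique=alt_clique,
    )


def _nearest_correlation(mat: np.ndarray, context: str) -> np.ndarray:
    """Eigenvalue-clip repair to the nearest well-conditioned correlation."""
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() > 1e-8:
        return mat
    log.warning(
        "%s: construction not positive definite (min eigenvalue %.3g); "
        "repaired by eigenvalue clipping",
        context,
        vals.min(),
    )
    clipped = (vecs * np.maximum(vals, 1e-6)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    fixed = clipped / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def make_state_covariances(
    n_nodes: int, hub_index: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Build the (hub-state, baseline-state) correlation matrices.

    Hub state: the hub correlates ~0.5 with every satellite (strongest with
    the two linked nodes), satellites correlate ~0.45 within their group and
    near zero across groups, so the hub is the unique bridge and ranks first
    in betweenness after a 20% proportional threshold.  Baseline state: hub
    correlations drop to ~0.05 while an alternative node sits in a clique of
    mutually correlated nodes (strongly connected, yet with no bridging
    role).  Small seeded jitter decorrelates replicate cohorts; any
    indefiniteness introduced by construction or jitter is repaired by
    eigenvalue clipping (logged).
    """
    if n_nodes < 3:
        raise ParameterError("need at least 3 nodes")
    if not (0 <= hub_index < n_nodes):
        raise ParameterError("hub_index out of range")
    roles = state_structure(n_nodes, hub_index)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x5C0FFEE])
    background = 0.05

    small = n_nodes <= 5
    hub_sat_r = 0.65 if small else 0.48
    hub_linked_r = 0.65 if small else 0.55
    within_group_r = 0.10 if small else 0.45

    hub_mat = np.full((n_nodes, n_nodes), background)
    for group in (roles.satellites_a, roles.satellites_b):
        for a in group:
            for b in group:
                if a != b:
                    hub_mat[a, b] = within_group_r
        for a in group:
            hub_mat[roles.hub, a] = hub_mat[a, roles.hub] = (
                hub_linked_r if a in roles.linked else hub_sat_r
            )
    if not small:
        # a state-constant side clique: its center is strongly connected in
        # both states, yet -- sitting inside a symmetric clique -- carries no
        # betweenness, so no competing dynamic hub is planted; it also soaks
        # up the proportional-threshold edge budget so near-threshold
        # background edges rarely attach stray nodes
        clique = (roles.alt_center, *roles.alt_clique)
        for a in clique:
            for b in clique:
                if a != b:
                    hub_mat[a, b] = 0.42
        for a in roles.alt_clique:
            hub_mat[roles.alt_center, a] = hub_mat[a, roles.alt_center] = 0.50

    # baseline state differs from the hub state only in the hub's row: its
    # correlations collapse to background, so the hub's bridging role -- and
    # nothing else -- switches with the Markov state
    base_mat = hub_mat.copy()
    base_mat[roles.hub, :] = base_mat[:, roles.hub] = background
    if small:
        for a in range(n_nodes):
            if a not in (roles.hub, roles.alt_center):
                base_mat[roles.alt_center, a] = base_mat[a, roles.alt_center] = 0.65

    out = []
    for name, mat in (("hub-state", hub_mat), ("baseline-state", base_mat)):
        jitter = rng.uniform(-0.01, 0.01, size=(n_nodes, n_nodes))
        jitter = 0.5 * (jitter + jitter.T)
        mat = mat + jitter
        np.fill_diagonal(mat, 1.0)
        out.append(_nearest_correlation(mat, name))
    return out[0], out[1]


def _markov_states(
    t: int, occupancy: float, dwell_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-state chain (1 = hub state) with given stationary occupancy and
    mean hub-state dwell (in TRs)."""
    if occupancy <= 0.0:
        return np.zeros(t, dtype=np.int8)
    if occupancy >= 1.0:
        return np.ones(t, dtype=np.int8)
    leave_hub = min(1.0, 1.0 / dwell_mean)
    leave_base = min(1.0, leave_hub * occupancy / (1.0 - occupancy))
    states = np.empty(t, dtype=np.int8)
    u = rng.random(t)
    states[0] = 1 if u[0] < occupancy else 0
    for i in range(1, t):
        p_leave = leave_hub if states[i - 1] == 1 else leave_base
        if u[i] < p_leave:
            states[i] = 1 - states[i - 1]
        else:
            states[i] = states[i - 1]
    return states


def simulate_subject(
    spec: SyntheticCohortSpec,
    occupancy: float,
    seed: int | np.random.SeedSequence,
    subject_id: str = "sub",
) -> tuple[RoiTimeSeries, np.ndarray]:
    """Simulate one subject: a Markov state path and state-conditional
    multivariate normal samples plus white measurement noise.

    Returns the series and the binary state sequence (1 = hub state); the
    subject's empirical occupancy is exactly the mean of that sequence.
    """
    if not (0.0 <= occupancy <= 1.0):
        raise ParameterError("occupancy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hub_cov, base_cov = make_state_covariances(
        spec.n_nodes, spec.hub_index, spec.seed
    )
    states = _markov_states(
        spec.n_volumes, occupancy, spec.state_dwell_mean_tr, rng
    )
    chol_hub = np.linalg.cholesky(hub_cov)
    chol_base = np.linalg.cholesky(base_cov)
    z = rng.standard_normal((spec.n_volumes, spec.n_nodes))
    data = np.where(
        (states == 1)[:, None], z @ chol_hub.T, z @ chol_base.T
    )
    data = data + spec.noise_sd * rng.standard_normal(data.shape)
    ts = RoiTimeSeries(
        subject_id=subject_id,
        data=data,
        tr_seconds=spec.tr_seconds,
        node_labels=[f"node{i:02d}" for i in range(spec.n_nodes)],
    )
    return ts, states


def _uls_counts(n: int) -> np.ndarray:
    """Largest-remainder rounding of the ULS marginal to n subjects."""
    raw = np.array(ULS_MARGINAL) * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for idx in np.argsort(-remainder, kind="stable")[: n - counts.sum()]:
        counts[idx] += 1
    return counts


def assign_uls(
    occupancy: np.ndarray, coupling_rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Rank-bin occupancies into ULS levels with a controlled coupling.

    A latent score mixes the (sign-flipped) normal scores of the occupancy
    ranks with seeded noise; subjects sorted by the latent receive ULS levels
    in ascending order following the clinical marginal, so high occupancy
    maps to low impairment with rank correlation driven toward
    ``coupling_rho`` (and exactly none when ``coupling_rho = 0``).
    """
    occupancy = np.asarray(occupancy, dtype=float)
    n = occupancy.size
    a = min(1.0, _COUPLING_GAIN * abs(coupling_rho))
    z = stats.norm.ppf((stats.rankdata(occupancy) - 0.5) / n)
    latent = -a * z + np.sqrt(1.0 - a * a) * rng.standard_normal(n)
    levels = np.repeat(np.arange(5), _uls_counts(n))
    uls = np.empty(n, dtype=int)
    uls[np.argsort(latent, kind="stable")] = levels
    return uls


def simulate_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[RoiTimeSeries], GroundTruth]:
    """Simulate a full cohort: evenly spaced target occupancies over
    ``occupancy_range``, coupled ULS scores, and one series per subject."""
    if spec.n_subjects < 5:
        raise ParameterError(
            "fewer than 5 subjects cannot support the association stage"
        )
    root = np.random.SeedSequence(spec.seed)
    uls_seed, *subject_seeds = root.spawn(1 + spec.n_subjects)
    targets = np.linspace(*spec.occupancy_range, spec.n_subjects)
    series, states_all = [], []
    for i, (target, child) in enumerate(zip(targets, subject_seeds)):
        ts, states = simulate_subject(
            spec, float(target), child, subject_id=f"sub{i:02d}"
        )
        series.append(ts)
        states_all.append(states)
    occupancy = np.array([s.mean() for s in states_all])
    uls = assign_uls(occupancy, spec.coupling_rho, np.random.default_rng(uls_seed))
    roles = state_structure(spec.n_nodes, spec.hub_index)
    truth = GroundTruth(
        occupancy=occupancy,
        uls=uls,
        states=states_all,
        hub_index=spec.hub_index,
        linked_nodes=roles.linked,
    )
    return series, truth


def write_cohort(
    series: list[RoiTimeSeries],
    truth: GroundTruth,
    outdir: str | Path,
    delimiter: str = ",",
) -> Path:
    """Write per-subject tables, the cohort manifest, and the ground truth.

    Returns the manifest path.  Layout: ``<outdir>/<subject_id>.csv`` per
    subject, ``manifest.csv``, ``ground_truth.json`` (roles and per-subject
    occupancy/ULS) and ``states.csv`` (T x n_subjects binary state paths).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ts in series:
        p = outdir / f"{ts.subject_id}.csv"
        write_timeseries(ts, p, delimiter=delimiter)
        paths.append(p)
    manifest = CohortManifest(
        subject_ids=[ts.subject_id for ts in series],
        paths=[Path(p.name) for p in paths],
        uls=truth.uls,
        covariates=pd.DataFrame(index=range(len(series))),
    )
    manifest_path = outdir / "manifest.csv"
    manifest.to_csv(manifest_path)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "hub_index": truth.hub_index,
                "linked_nodes": list(truth.linked_nodes),
                "occupancy": truth.occupancy.tolist(),
                "uls": truth.uls.tolist(),
            },
            fh,
            indent=2,
        )
    states = np.column_stack(truth.states)
    np.savetxt(
        outdir / "states.csv",
        states,
        fmt="%d",
        delimiter=",",
        header=",".join(ts.subject_id for ts in series),
        comments="",
    )
    return manifest_path
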