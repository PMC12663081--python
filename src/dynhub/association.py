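"""Association of dynamic-topology metrics with the upper-limb score (ULS).

Per node, the HCM occupancy (or linked-mode occurrence) is correlated with
the ordinal ULS across subjects by Spearman's rho.  Significance is assessed
by a permutation test: the ULS vector is permuted (default 1000 times, one
shared permutation set across nodes so per-node results are comparable) and
the observed correlation is compared with the 99th percentile of the null
distribution of permuted correlation values.

Under the default two-sided reading, |rho_obs| must exceed the 99th
percentile of the *signed* null, which by symmetry is a ~2% level; a
one-sided (negative) mode compares rho_obs with the 1st percentile instead.
The node whose occupancy shows the strongest significant association is the
dynamic central motor node (DCMN).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateStatisticError, ParameterError, StructureError
from .modes import ModeModel
from .topology import BinaryGraphSeries

__all__ = [
    "AssociationResult",
    "spearman",
    "permutation_test",
    "identify_dcmn",
    "linked_mode",
    "linked_mode_association",
    "partial_spearman",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class AssociationResult:
    """Outcome of one node-level permutation-tested Spearman correlation."""

    node: int
    rho: float
    p_perm: float
    null_q99: float
    significant: bool
    n_perm: int
    degenerate: bool = False


def _ranks(x: np.ndarray) -> np.ndarray:
    r = rankdata(np.asarray(x, dtype=float))
    if np.ptp(r) == 0:
        raise DegenerateStatisticError("zero rank variance")
    return r


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Spearman rho: Pearson correlation of average-tie ranks.

    Raises
    ------
    DegenerateStatisticError
        If either input has no rank variance (all values tied).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    if x.size < 5:
        raise ParameterError("need n >= 5 observations")
    rx, ry = _ranks(x), _ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def _permutation_matrix(
    n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)


def _null_rhos(rx: np.ndarray, ry: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Spearman rho of rx against each row-permutation of ry (vectorized)."""
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    norm = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    return (ryc[perms] @ rxc) / norm


def permutation_test(
    metric: np.ndarray,
    uls: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
    node: int = 0,
    permutations: np.ndarray | None = None,
) -> AssociationResult:
    """Permutation-tested Spearman correlation of a per-subject metric vs ULS.

    Parameters
    ----------
    metric, uls : per-subject vectors (ties allowed)
    n_perm : number of ULS permutations (>= 100)
    alternative : {"two-sided", "less"}
        ``"two-sided"``: significant when |rho| exceeds the 99th percentile
        of the signed null.  ``"less"``: significant when rho falls below the
        1st percentile (negative associations only).
    permutations : optional pre-drawn (n_perm, n) index matrix, so several
        nodes can share one null ensemble.

    Notes
    -----
    ``p_perm = (1 + #{extreme nulls}) / (n_perm + 1)`` never reaches 0; a
    degenerate observed correlation (all-tied input) yields a result with
    ``degenerate=True`` and no test.
    """
    metric = np.asarray(metric, dtype=float)
    uls = np.asarray(uls, dtype=float)
    if permutations is None:
        if n_perm < 100:
            raise ParameterError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        permutations = _permutation_matrix(metric.size, n_perm, rng)
    n_perm = permutations.shape[0]
    try:
        rho = spearman(metric, uls)
    except DegenerateStatisticError:
        log.warning("node %d: degenerate Spearman input; test not run", node)
        return AssociationResult(
            node=node,
            rho=float("nan"),
            p_perm=1.0,
            null_q99=float("nan"),
            significant=False,
            n_perm=n_perm,
            degenerate=True,
        )
    null = _null_rhos(rankdata(metric), rankdata(uls), permutations)
    q99 = float(np.quantile(null, 0.99))
    if alternative == "two-sided":
        significant = abs(rho) > q99
        p = float((1 + np.sum(np.abs(null) >= abs(rho))) / (n_perm + 1))
    elif alternative == "less":
        significant = rho < float(np.quantile(null, 0.01))
        p = float((1 + np.sum(null <= rho)) / (n_perm + 1))
    else:
        raise ParameterError("alternative must be 'two-sided' or 'less'")
    return AssociationResult(
        node=node,
        rho=rho,
        p_perm=p,
        null_q99=q99,
        significant=bool(significant),
        n_perm=n_perm,
    )


def identify_dcmn(
    occupancy: pd.DataFrame | np.ndarray,
    uls: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> tuple[int | None, list[AssociationResult]]:
    """Per-node HCM-ULS permutation tests; the significant node with the
    largest |rho| is the dynamic central motor node (DCMN).

    Returns ``(None, results)`` when no node reaches significance.  Should
    several nodes tie exactly on |rho|, the smallest node index wins (and all
    remain visible in the returned table).
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.ndim != 2 or occ.shape[1] < 2:
        raise ParameterError("occupancy must be subjects x nodes with >= 2 nodes")
    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(occ.shape[0], n_perm, rng)
    results = [
        permutation_test(
            occ[:, v], uls, alternative=alternative, node=v, permutations=perms
        )
        for v in range(occ.shape[1])
    ]
    candidates = [r for r in results if r.significant and not r.degenerate]
    if not candidates:
        return None, results
    best = max(candidates, key=lambda r: (abs(r.rho), -r.node))
    return best.node, results


def linked_mode(
    graphs: list[BinaryGraphSeries], dcmn_model: ModeModel, dcmn: int
) -> pd.DataFrame:
    """Count, per subject and non-DCMN node, the windows in which the node
    shares an edge with the DCMN while the DCMN sits in its high-centrality
    mode (the "DCMN linked mode", DCMN-LM)."""
    rows = {}
    for g, labels in zip(graphs, dcmn_model.labels, strict=True):
        if g.n_windows != len(labels):
            raise StructureError(
                f"subject {g.subject_id!r}: {g.n_windows} windows but "
                f"{len(labels)} mode labels"
            )
        in_hcm = labels == dcmn_model.hcm_id
        counts = g.adj[in_hcm, :, dcmn].sum(axis=0)
        rows[g.subject_id] = counts
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    return table.drop(columns=[dcmn])


def linked_mode_association(
    lm_table: pd.DataFrame,
    uls: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> list[AssociationResult]:
    """Permutation-tested Spearman of each node's DCMN-LM count vs ULS."""
    rng = np.random.default_rng(seed)
    perms = _permutation_matrix(lm_table.shape[0], n_perm, rng)
    return [
        permutation_test(
            lm_table[col].to_numpy(dtype=float),
            uls,
            alternative=alternative,
            node=int(col),
            permutations=perms,
        )
        for col in lm_table.columns
    ]


def partial_spearman(
    metric: np.ndarray, uls: np.ndarray, covariate: np.ndarray
) -> float:
    """Spearman correlation of metric and ULS controlling for one covariate.

    All three variables are rank-transformed (average ties); metric- and
    ULS-ranks are each regressed on the covariate ranks (with intercept) and
    the residuals are Pearson-correlated.  A constant covariate carries no
    information and falls back to the plain Spearman rho (logged).
    """
    metric = np.asarray(metric, dtype=float)
    uls = np.asarray(uls, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    if not (metric.size == uls.size == covariate.size):
        raise ParameterError("inputs must have equal length")
    if metric.size < 6:
        raise ParameterError("need n >= 6 observations for a partial correlation")
    rc = rankdata(covariate)
    if np.ptp(rc) == 0:
        log.info("constant covariate: partial correlation reduces to Spearman")
        return spearman(metric, uls)
    rm, ru = _ranks(metric), _ranks(uls)
    design = np.column_stack([np.ones_like(rc), rc])
    res_m = rm - design @ np.linalg.lstsq(design, rm, rcond=None)[0]
    res_u = ru - design @ np.linalg.lstsq(design, ru, rcond=None)[0]
    sm, su = np.sqrt(res_m @ res_m), np.sqrt(res_u @ res_u)
    if sm <= 1e-10 * np.sqrt(rm @ rm) or su <= 1e-10 * np.sqrt(ru @ ru):
        raise DegenerateStatisticError(
            "residual variance is zero after removing the covariate"
        )
    return float(res_m @ res_u / (sm * su))
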