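"""Sliding-window dynamic functional connectivity.

Each subject's T x N series is segmented into overlapping windows (default
20 TRs long, onset advanced by 1 TR, so T=260 gives 241 windows).  Within
each window the Pearson correlation between every node pair is computed and
Fisher-transformed (z = atanh r), yielding one symmetric N x N z-matrix per
window.  The diagonal is set to 0 and never used downstream.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateWindowError, ParameterError
from .io import RoiTimeSeries

__all__ = ["WindowSpec", "DynamicFCSeries", "count_windows", "windowed_fc"]

log = logging.getLogger(__name__)

#: |r| is clipped here before atanh so perfectly correlated pairs stay finite
#: while remaining the strongest weights under any proportional threshold.
R_CLIP = 1.0 - 1e-7


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in TR units (half-open windows [s, s+length))."""

    length_tr: int = 20
    step_tr: int = 1

    def __post_init__(self) -> None:
        if self.length_tr < 3:
            raise ParameterError("window length must be >= 3 TRs")
        if not (1 <= self.step_tr <= self.length_tr):
            raise ParameterError("need 1 <= step_tr <= length_tr")


@dataclasses.dataclass
class DynamicFCSeries:
    """W windowed Fisher-z connectivity matrices for one subject."""

    subject_id: str
    z: np.ndarray  # (W, N, N), symmetric, zero diagonal
    window_starts: np.ndarray  # (W,) 0-based first volume of each window

    @property
    def n_windows(self) -> int:
        return self.z.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.z.shape[1]


def count_windows(t: int, spec: WindowSpec) -> int:
    """Number of sliding windows for a series of t volumes.

    ``floor((t - length) / step) + 1``; the canonical acquisition (260
    volumes, 20-TR windows, 1-TR step) yields 241.
    """
    if t < spec.length_tr:
        raise ParameterError(
            f"series too short: t={t} < window length {spec.length_tr}"
        )
    return (t - spec.length_tr) // spec.step_tr + 1


def windowed_fc(
    ts: RoiTimeSeries,
    spec: WindowSpec = WindowSpec(),
    on_degenerate: str = "raise",
) -> DynamicFCSeries:
    """Windowed Pearson correlation, Fisher z-transformed.

    Parameters
    ----------
    ts : RoiTimeSeries
    spec : WindowSpec
    on_degenerate : {"raise", "drop"}
        A window in which some node has zero variance has no defined Pearson
        r.  ``"raise"`` aborts the subject (default); ``"drop"`` removes the
        window with a logged warning.

    Returns
    -------
    DynamicFCSeries
        ``z[w, i, j] = atanh(r_w(i, j))`` for i != j, with |r| clipped just
        below 1; diagonal entries are 0.
    """
    if on_degenerate not in ("raise", "drop"):
        raise ParameterError("on_degenerate must be 'raise' or 'drop'")
    t = ts.n_volumes
    w_count = count_windows(t, spec)
    starts = np.arange(w_count) * spec.step_tr

    # (W_all, N, L) view, then stride by step along the window axis
    windows = sliding_window_view(ts.data, spec.length_tr, axis=0)[:: spec.step_tr]
    windows = windows[:w_count]

    mean = windows.mean(axis=-1, keepdims=True)
    centered = windows - mean
    ss = np.sqrt((centered**2).sum(axis=-1))  # (W, N)

    # exact constancy, not ss == 0: mean subtraction of a constant column
    # leaves O(eps) residue that would slip past a zero test
    degenerate = np.ptp(windows, axis=-1) == 0.0
    keep = np.ones(w_count, dtype=bool)
    if degenerate.any():
        w_bad, n_bad = np.argwhere(degenerate)[0]
        if on_degenerate == "raise":
            raise DegenerateWindowError(ts.subject_id, int(w_bad), int(n_bad))
        keep = ~degenerate.any(axis=1)
        log.warning(
            "subject %s: dropping %d degenerate window(s) (first: window %d, node %d)",
            ts.subject_id,
            int((~keep).sum()),
            int(w_bad),
            int(n_bad),
        )
        centered, ss, starts = centered[keep], ss[keep], starts[keep]

    cov = np.einsum("wil,wjl->wij", centered, centered)
    r = cov / (ss[:, :, None] * ss[:, None, :])
    np.clip(r, -R_CLIP, R_CLIP, out=r)
    z = np.arctanh(r)
    z = 0.5 * (z + z.transpose(0, 2, 1))  # exact symmetry
    idx = np.arange(ts.n_nodes)
    z[:, idx, idx] = 0.0
    return DynamicFCSeries(subject_id=ts.subject_id, z=z, window_starts=starts)
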