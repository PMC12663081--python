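"""Reading and writing ROI time series and cohort manifests.

A subject's data is a plain delimited-text table: one header row of node
labels, then T rows (acquisition order) by N numeric columns, one column per
motor-network node.  The cohort manifest is a CSV with columns
``subject_id, path, uls`` followed by any number of numeric covariate columns
(lesion size, lesion-centroid distance, % corticospinal-tract damage, ...).

An optional zero-phase band-pass filter matching the resting-state band used
upstream of this pipeline (0.029-0.15 Hz) is provided for raw synthetic data;
real inputs are assumed to arrive already filtered.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FormatError, ParameterError

__all__ = [
    "RoiTimeSeries",
    "CohortManifest",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "bandpass",
]

#: resting-state band used by the preprocessing this pipeline expects (Hz)
DEFAULT_BAND = (0.029, 0.15)


@dataclasses.dataclass
class RoiTimeSeries:
    """One subject's T x N BOLD-like matrix with sampling info.

    Parameters
    ----------
    subject_id : str
        Cohort-unique identifier.
    data : ndarray, shape (T, N)
        Node time series, rows in acquisition order. Arbitrary units.
    tr_seconds : float
        Sampling interval (repetition time), seconds.
    node_labels : list of str
        N unique node names, column order.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float
    node_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("data must be a 2-D T x N matrix")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise ParameterError(f"need T >= 2 and N >= 2, got shape {(t, n)}")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ParameterError("tr_seconds must be positive")
        self.node_labels = [str(x) for x in self.node_labels]
        if len(self.node_labels) != n:
            raise ParameterError("node_labels length must match number of columns")
        if len(set(self.node_labels)) != n:
            raise ParameterError("node_labels must be unique")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclasses.dataclass
class CohortManifest:
    """Cohort table: subject ids, time-series paths, the ordinal upper-limb
    score (ULS, 0-4; 0 = no deficit, 4 = severe), and optional numeric
    covariates for partial-correlation controls."""

    subject_ids: list[str]
    paths: list[Path]
    uls: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.uls = np.asarray(self.uls, dtype=int)
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise FormatError("subject_id values must be unique")
        if len(self.paths) != n or len(self.uls) != n:
            raise FormatError("manifest columns have inconsistent lengths")
        if np.any((self.uls < 0) | (self.uls > 4)):
            raise FormatError("uls values must lie in {0,...,4}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "path": [str(p) for p in self.paths],
                "uls": self.uls,
            }
        )
        for col in self.covariates.columns:
            frame[col] = np.asarray(self.covariates[col])
        frame.to_csv(path, index=False)


def _sniff_delimiter(first_line: str) -> str:
    """Comma- or tab-separated, decided by which separator appears."""
    if first_line.count("\t") > first_line.count(","):
        return "\t"
    return ","


def read_timeseries(
    path: str | Path, tr_seconds: float, subject_id: str | None = None
) -> RoiTimeSeries:
    """Read one subject's T x N delimited table (header row of node labels).

    Raises
    ------
    FormatError
        On ragged rows, non-numeric or missing cells (the offending line is
        named), or duplicate node labels.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
    sep = _sniff_delimiter(header_line)
    raw_labels = [s.strip() for s in header_line.rstrip("\n").split(sep)]
    if len(set(raw_labels)) != len(raw_labels):
        # checked on the raw header: pandas would silently rename duplicates
        raise FormatError(f"{path}: duplicate node labels in header")
    try:
        frame = pd.read_csv(path, sep=sep, header=0, dtype=str, skipinitialspace=True)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed table: {exc}") from exc
    labels = [str(c).strip() for c in frame.columns]
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate node labels in header")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(converted.to_numpy(dtype=float)))
        if bad.size:
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"{path}: non-numeric or missing value in column {labels[j]!r} "
                f"at line {bad[0] + 2}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return RoiTimeSeries(
        subject_id=subject_id if subject_id is not None else path.stem,
        data=values,
        tr_seconds=tr_seconds,
        node_labels=labels,
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path, delimiter: str = ",") -> None:
    """Write a subject table in the format `read_timeseries` accepts."""
    frame = pd.DataFrame(ts.data, columns=ts.node_labels)
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.10g")


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV; extra numeric columns become covariates."""
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"subject_id", "path", "uls"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: manifest is missing columns {sorted(missing)}")
    cov_cols = [c for c in frame.columns if c not in required]
    covariates = frame[cov_cols].apply(pd.to_numeric, errors="raise")
    # relative paths resolve against the manifest's own directory
    paths = [
        p if Path(p).is_absolute() else path.parent / p for p in frame["path"]
    ]
    return CohortManifest(
        subject_ids=[str(s) for s in frame["subject_id"]],
        paths=[Path(p) for p in paths],
        uls=frame["uls"].to_numpy(),
        covariates=covariates,
    )


def bandpass(
    ts: RoiTimeSeries,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = 4,
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass applied per node column.

    A 4th-order Butterworth is run forward and backward (``sosfiltfilt``), so
    the effective magnitude response is squared and the phase is zero: no
    temporal shift of the windows downstream.
    """
    nyquist = 0.5 / ts.tr_seconds
    if not (0.0 < low_hz < high_hz):
        raise ParameterError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ParameterError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist:.4g} Hz"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, ts.data, axis=0)
    return RoiTimeSeries(
        subject_id=ts.subject_id,
        data=filtered,
        tr_seconds=ts.tr_seconds,
        node_labels=list(ts.node_labels),
    )
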