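"""Sliding-window construction of dynamic functional connectivity (dFC).

A subject's regional time series (rows = scan volumes at a fixed sampling
interval, columns = brain regions) is cut into overlapping windows of
``window_size`` samples advanced by ``step`` samples.  Within each window the
connectivity of a region pair is the absolute Pearson correlation of the two
regional signals, giving a symmetric, hollow matrix with entries in [0, 1].
The ordered per-window matrices form the subject's dFC sequence
(C_1, ..., C_T) consumed by the distance metrics.

Trimming is applied in a fixed order: trailing samples that do not fill a
complete window are clipped, then the first and last complete windows are
dropped to avoid boundary artifacts, and finally cohort-level harmonisation
(:func:`harmonize_lengths`) truncates every sequence from the end to a common
length so that subjects are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._errors import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "RegionalTimeSeries",
    "ConnectivityMatrix",
    "DFCSequence",
    "length_exclusion_reason",
    "read_time_series",
    "window_correlation",
    "build_dfc",
    "harmonize_lengths",
]


@dataclass(frozen=True)
class WindowSpec:
    """Windowing and inclusion parameters.

    Parameters
    ----------
    window_size
        Samples per window (``s``).  With a 3 s sampling interval the
        default of 5 spans 15 seconds.
    step
        Samples between consecutive window starts (``c``); the default of 2
        offsets adjacent windows by 6 seconds.
    drop_first_last
        Drop the first and last complete windows (boundary-artifact guard).
    min_timepoints, max_timepoints
        Inclusion range for the raw series length; scans outside the range
        are flagged as excluded rather than silently dropped.
    """

    window_size: int = 5
    step: int = 2
    drop_first_last: bool = True
    min_timepoints: int = 90
    max_timepoints: int = 600

    def __post_init__(self) -> None:
        if self.window_size < 3:
            raise ConfigError("window_size must be >= 3 (Pearson correlation "
                              "is undefined/unstable on fewer samples)")
        if self.step < 1:
            raise ConfigError("step must be >= 1")
        if not (0 < self.min_timepoints <= self.max_timepoints):
            raise ConfigError("need 0 < min_timepoints <= max_timepoints")


@dataclass
class RegionalTimeSeries:
    """One subject's time-by-region signal matrix."""

    values: np.ndarray
    region_labels: list[str]
    sampling_interval_s: float = 3.0
    subject_id: str = ""
    exclusion_reason: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("time series must be a 2-D (time x region) matrix")
        if self.values.shape[1] != len(self.region_labels):
            raise DataError("region_labels length does not match column count")
        if self.values.shape[1] < 3:
            raise DataError("need at least 3 regions")
        if not np.isfinite(self.values).all():
            raise DataError("time series contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Absolute-correlation connectivity for one window: symmetric, hollow,
    entries in [0, 1]."""

    entries: np.ndarray
    window_index: int = 0

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        m = self.entries.shape[0]
        if self.entries.ndim != 2 or self.entries.shape[1] != m:
            raise DataError("connectivity matrix must be square")
        if np.any(np.diag(self.entries) != 0):
            raise DataError("connectivity matrix diagonal must be exactly 0")
        if not np.allclose(self.entries, self.entries.T):
            raise DataError("connectivity matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.entries.shape[0]


@dataclass
class DFCSequence:
    """Time-ordered connectivity matrices (C_1, ..., C_T) for one subject.

    Matrices are stored stacked as a ``(T, M, M)`` array for efficiency;
    indexing returns :class:`ConnectivityMatrix` views.
    """

    matrices: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise DataError("DFCSequence expects a (T, M, M) stack")
        if len(self.matrices) < 2:
            raise DataError("a dFC sequence needs at least 2 windows")

    def __len__(self) -> int:
        return len(self.matrices)

    def __getitem__(self, i: int) -> ConnectivityMatrix:
        return ConnectivityMatrix(self.matrices[i], window_index=i)

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]


def length_exclusion_reason(n_timepoints: int, spec: WindowSpec) -> str | None:
    """Return why a series of this length fails the inclusion filter, or None."""
    if n_timepoints < spec.min_timepoints:
        return f"too few time points ({n_timepoints} < {spec.min_timepoints})"
    if n_timepoints > spec.max_timepoints:
        return f"too many time points ({n_timepoints} > {spec.max_timepoints})"
    return None


def read_time_series(
    path: str | Path,
    spec: WindowSpec | None = None,
    sampling_interval_s: float = 3.0,
    subject_id: str | None = None,
) -> RegionalTimeSeries:
    """Parse a tab-separated regional time-series file.

    The first line must be a header of region labels; each following line
    holds one time point with one floating-point value per region.  Series
    whose length falls outside the inclusion range of ``spec`` are returned
    with ``exclusion_reason`` set (they are reported, not silently dropped).

    Raises
    ------
    DataError
        On a missing header, ragged rows or non-numeric cells; the message
        names the offending 1-based line number.
    """
    path = Path(path)
    spec = spec or WindowSpec()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise DataError(f"{path}: empty file, expected a header row (line 1)")
    header = lines[0].split("\t")
    numeric_header = True
    for cell in header:
        try:
            float(cell)
        except ValueError:
            numeric_header = False
            break
    if numeric_header:
        raise DataError(
            f"{path}: line 1: expected a header row of region labels, "
            "found numeric data"
        )
    n_cols = len(header)
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise DataError(
                f"{path}: line {lineno}: expected {n_cols} columns, "
                f"got {len(cells)} (ragged row)"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            raise DataError(f"{path}: line {lineno}: non-numeric cell ({exc})") from exc
    values = np.asarray(rows, dtype=float).reshape(len(rows), n_cols)
    sid = subject_id if subject_id is not None else path.stem.removesuffix("_timeseries")
    ts = RegionalTimeSeries(
        values=values,
        region_labels=list(header),
        sampling_interval_s=sampling_interval_s,
        subject_id=sid,
    )
    ts.exclusion_reason = length_exclusion_reason(ts.n_timepoints, spec)
    if ts.exclusion_reason:
        logger.info("excluded %s: %s", sid, ts.exclusion_reason)
    return ts


def _batched_abs_corr(segments: np.ndarray) -> np.ndarray:
    """Absolute Pearson correlation matrices for a (W, N, M) stack of window
    segments.  Zero-variance (constant) columns yield 0-valued edges."""
    X = segments - segments.mean(axis=1, keepdims=True)
    denom = np.sqrt((X ** 2).sum(axis=1))  # (W, M)
    zero = denom == 0.0
    if zero.any():
        logger.warning(
            "%d constant region/window segments; their edges are set to 0",
            int(zero.sum()),
        )
    safe = np.where(zero, 1.0, denom)
    Xn = X / safe[:, None, :]
    corr = np.abs(np.einsum("wlm,wln->wmn", Xn, Xn))
    np.clip(corr, 0.0, 1.0, out=corr)
    # zero out rows/cols of degenerate regions and the diagonal
    corr *= ~zero[:, :, None]
    corr *= ~zero[:, None, :]
    m = corr.shape[1]
    corr[:, np.arange(m), np.arange(m)] = 0.0
    return corr


def window_correlation(segment: np.ndarray, window_index: int = 0) -> ConnectivityMatrix:
    """Absolute Pearson correlation between the columns of one window segment.

    ``segment`` has N = window_size rows and M region columns.  Constant
    columns produce 0-valued edges (with a logged warning) rather than NaN.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2:
        raise DataError("window segment must be 2-D")
    if segment.shape[0] < 3:
        raise DataError(
            f"window has {segment.shape[0]} samples; Pearson correlation "
            "needs at least 3"
        )
    corr = _batched_abs_corr(segment[None])[0]
    return ConnectivityMatrix(corr, window_index=window_index)


def window_starts(n_timepoints: int, spec: WindowSpec) -> list[int]:
    """Start rows of all complete windows before boundary trimming."""
    s, c = spec.window_size, spec.step
    if n_timepoints < s:
        return []
    return list(range(0, n_timepoints - s + 1, c))


def build_dfc(ts: RegionalTimeSeries, spec: WindowSpec | None = None) -> DFCSequence:
    """Slide the window over a subject's series and stack the per-window
    absolute-correlation matrices.

    Windows start at rows 0, c, 2c, ...; trailing samples that do not fill a
    complete window are clipped; the first and last complete windows are then
    removed when ``spec.drop_first_last`` is on.
    """
    spec = spec or WindowSpec()
    if ts.exclusion_reason:
        raise DataError(f"subject {ts.subject_id!r} is excluded: {ts.exclusion_reason}")
    starts = window_starts(ts.n_timepoints, spec)
    if spec.drop_first_last:
        starts = starts[1:-1]
    if len(starts) < 2:
        raise DataError(
            f"subject {ts.subject_id!r}: series too short after trimming "
            f"({len(starts)} windows survive; need >= 2)"
        )
    s = spec.window_size
    segments = np.stack([ts.values[i : i + s] for i in starts])
    return DFCSequence(_batched_abs_corr(segments), subject_id=ts.subject_id)


def harmonize_lengths(
    sequences: Sequence[DFCSequence], target: int | str = "min"
) -> list[DFCSequence]:
    """Truncate every sequence from the end to a common length.

    ``target`` is either ``"min"`` (the cohort minimum) or an explicit count
    no larger than every subject's length.
    """
    if len(sequences) == 0:
        raise DataError("harmonize_lengths: empty sequence list")
    lengths = {seq.subject_id: len(seq) for seq in sequences}
    if target == "min":
        t = min(lengths.values())
    else:
        t = int(target)
        for sid, n in lengths.items():
            if t > n:
                raise DataError(
                    f"target length {t} exceeds subject {sid!r}'s length {n}"
                )
    return [
        DFCSequence(seq.matrices[:t], subject_id=seq.subject_id) for seq in sequences
    ]
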