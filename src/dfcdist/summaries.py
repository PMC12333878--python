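"""Per-subject scalar summaries of a distance series.

Two complementary reductions: the mean over all window transitions
(sustained temporal variability) and the mean of the k = 5 largest values
(transient, high-amplitude disruptions).  "Peaks" are the largest values of
the series, not local maxima; ties at the k-th value are resolved by taking
exactly k values in stable sorted order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import DataError
from .metrics import DistanceSeries

__all__ = ["SubjectSummary", "series_mean", "top_k_peak_mean", "summarize"]

DEFAULT_PEAK_K = 5


@dataclass
class SubjectSummary:
    subject_id: str
    metric_name: str
    mean_value: float
    peak_value: float
    series_length: int


def _values(series) -> np.ndarray:
    if isinstance(series, DistanceSeries):
        return series.values
    return np.asarray(series, dtype=float)


def series_mean(series) -> float:
    """Arithmetic mean of all distance-series values."""
    v = _values(series)
    if len(v) == 0:
        raise DataError("cannot summarize an empty distance series")
    return float(v.mean())


def top_k_peak_mean(series, k: int = DEFAULT_PEAK_K) -> float:
    """Mean of the k largest values of the series."""
    v = _values(series)
    if k < 1:
        raise DataError("k must be >= 1")
    if len(v) < k:
        raise DataError(f"series shorter than k ({len(v)} < {k})")
    return float(np.sort(v)[-k:].mean())


def summarize_series(series: DistanceSeries, k: int = DEFAULT_PEAK_K) -> SubjectSummary:
    return SubjectSummary(
        subject_id=series.subject_id,
        metric_name=series.metric_name,
        mean_value=series_mean(series),
        peak_value=top_k_peak_mean(series, k),
        series_length=len(series),
    )


def summarize(
    series_list: Iterable[DistanceSeries], k: int = DEFAULT_PEAK_K
) -> pd.DataFrame:
    """Summary table for a collection of distance series.

    Columns: subject_id, metric, mean_value, peak_value, series_length.
    """
    rows = [summarize_series(s, k) for s in series_list]
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "metric": [r.metric_name for r in rows],
            "mean_value": [r.mean_value for r in rows],
            "peak_value": [r.peak_value for r in rows],
            "series_length": [r.series_length for r in rows],
        }
    )
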