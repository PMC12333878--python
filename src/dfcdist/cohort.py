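"""Synthetic cohorts with the statistical structure the analysis assumes.

Real resting-state fMRI is replaced by a generative model chosen so that
sliding-window correlation has genuine temporal structure: each subject's
regional signal is a low-rank mixture of shared latent signals plus white
noise, and the mixing matrix performs a random walk over time ("covariance
drift").  Three knobs shape group structure:

* ``sustained_effect`` scales the baseline drift magnitude per diagnostic
  group, producing sustained elevation of window-to-window variability;
* ``peak_effect`` injects a few short, abrupt covariance perturbations
  (contiguous in time, long enough to span whole analysis windows), which
  surface as isolated maxima in the distance series — the kind of transient
  disruption the 5-peak summary targets;
* ``age_effect`` adds a linear age confound on drift magnitude.

Both group effects accept a scalar (applied to DEMENTIA, half to MCI, zero
to NC) or an explicit per-diagnosis mapping.  Effect magnitudes are
illustrative free parameters, not calibrated to any real cohort.

Ages are uniform within the configured range; sexes are assigned in
balanced blocks.  A single master seed spawns an independent stream per
subject (keyed by subject index), so generation order is irrelevant and
identical configurations yield bitwise-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataError
from .connectivity import RegionalTimeSeries, WindowSpec, read_time_series

__all__ = [
    "DIAGNOSES",
    "SEXES",
    "SimConfig",
    "SubjectRecord",
    "Cohort",
    "generate_subject_series",
    "generate_records",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

DIAGNOSES = ("NC", "MCI", "DEMENTIA")
SEXES = ("F", "M")

# Raw series lengths accepted by the analysis; the simulator refuses to
# generate scans it would immediately exclude.
_MIN_TIMEPOINTS, _MAX_TIMEPOINTS = 90, 600


def _as_group_map(value, name: str) -> dict[str, float]:
    """Normalize a scalar or per-diagnosis mapping into a full mapping.

    A scalar v means: NC 0, MCI v/2, DEMENTIA v (MCI intermediate)."""
    if isinstance(value, Mapping):
        out = {d: float(value.get(d, 0.0)) for d in DIAGNOSES}
    else:
        v = float(value)
        out = {"NC": 0.0, "MCI": v / 2.0, "DEMENTIA": v}
    for d, v in out.items():
        if not np.isfinite(v):
            raise ConfigError(f"{name}[{d}] must be finite")
    return out


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation parameters.

    ``n_timepoints`` is either a fixed count or an inclusive ``(lo, hi)``
    range sampled per subject; either way it must lie within the analysis
    inclusion window of 90-600 samples.
    """

    n_per_cell: int = 20
    n_regions: int = 116
    n_timepoints: int | tuple[int, int] = (90, 600)
    sampling_interval_s: float = 3.0
    age_range: tuple[float, float] = (45.0, 97.0)
    age_effect: float = 0.0
    sustained_effect: float | Mapping = 0.0
    peak_effect: float | Mapping = 0.0
    n_peak_events: int = 2
    peak_event_duration: int = 10
    latent_rank: int = 5
    base_drift: float = 0.05
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1 or self.n_regions < 3 or self.latent_rank < 1:
            raise ConfigError("counts must be positive (and n_regions >= 3)")
        lo, hi = self.timepoint_range
        if not (_MIN_TIMEPOINTS <= lo <= hi <= _MAX_TIMEPOINTS):
            raise ConfigError(
                f"n_timepoints must lie within [{_MIN_TIMEPOINTS}, {_MAX_TIMEPOINTS}]"
            )
        if self.n_peak_events < 0 or self.peak_event_duration < 1:
            raise ConfigError("peak-event counts must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must satisfy min < max")
        for v in (self.age_effect, self.base_drift, self.noise_sd,
                  self.sampling_interval_s):
            if not np.isfinite(v):
                raise ConfigError("all real-valued parameters must be finite")
        if self.noise_sd < 0 or self.base_drift < 0:
            raise ConfigError("noise_sd and base_drift must be >= 0")
        # validate group maps eagerly
        _as_group_map(self.sustained_effect, "sustained_effect")
        _as_group_map(self.peak_effect, "peak_effect")

    @property
    def timepoint_range(self) -> tuple[int, int]:
        if isinstance(self.n_timepoints, (tuple, list)):
            return int(self.n_timepoints[0]), int(self.n_timepoints[1])
        return int(self.n_timepoints), int(self.n_timepoints)

    @property
    def age_mean(self) -> float:
        return 0.5 * (self.age_range[0] + self.age_range[1])


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    age: float
    sex: str
    diagnosis: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ConfigError(
                f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}"
            )


@dataclass
class Cohort:
    records: list[SubjectRecord]
    series: dict[str, RegionalTimeSeries]

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate subject ids")
        if set(ids) != set(self.series):
            raise DataError("records and series must cover the same subjects")
        regions = {ts.n_regions for ts in self.series.values()}
        if len(regions) > 1:
            raise DataError(f"inconsistent region counts across subjects: {regions}")

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.records],
                "age": [r.age for r in self.records],
                "sex": [r.sex for r in self.records],
                "diagnosis": [r.diagnosis for r in self.records],
            }
        )

    def __len__(self) -> int:
        return len(self.records)


def generate_subject_series(
    record: SubjectRecord, cfg: SimConfig, stream: np.random.Generator
) -> RegionalTimeSeries:
    """Simulate one subject's T x M regional signal matrix.

    The mixing matrix A_t (M x latent_rank) follows a stationary
    mean-reverting process, A_t = exp(-d) A_{t-1} + sqrt(1 - exp(-2d)) G_t,
    whose per-sample decorrelation rate d equals
    base_drift * (1 + sustained_effect[dx]) * (1 + age_effect * (age - mid-age)),
    floored at 0.  Stationarity keeps the signal-to-noise ratio constant, so
    d controls purely how fast the connectivity pattern wanders.  During each
    of ``n_peak_events`` contiguous intervals the effective mixing is
    abruptly shifted by an event-specific perturbation of amplitude
    peak_effect[dx], changing the instantaneous covariance for the event's
    duration and reverting afterwards.
    """
    sustained = _as_group_map(cfg.sustained_effect, "sustained_effect")[record.diagnosis]
    peak_amp = _as_group_map(cfg.peak_effect, "peak_effect")[record.diagnosis]
    lo, hi = cfg.timepoint_range
    T = int(stream.integers(lo, hi + 1)) if lo != hi else lo
    M, r = cfg.n_regions, cfg.latent_rank

    drift = cfg.base_drift * (1.0 + sustained)
    drift *= max(0.0, 1.0 + cfg.age_effect * (record.age - cfg.age_mean))

    A0 = stream.normal(size=(M, r)) / np.sqrt(r)
    retain = np.exp(-drift)
    innov_sd = np.sqrt(max(0.0, 1.0 - retain * retain)) / np.sqrt(r)
    eps = stream.normal(size=(T, M, r))
    A = np.empty((T, M, r))
    prev = A0
    for t in range(T):
        prev = retain * prev + innov_sd * eps[t]
        A[t] = prev

    in_event = np.zeros(T, dtype=bool)
    if peak_amp > 0 and cfg.n_peak_events > 0:
        dur = min(cfg.peak_event_duration, max(1, T // 4))
        margin = dur  # keep events away from the very edges
        lo_start, hi_start = margin, T - margin - dur
        starts = (
            stream.choice(np.arange(lo_start, hi_start + 1),
                          size=cfg.n_peak_events,
                          replace=cfg.n_peak_events > (hi_start - lo_start + 1))
            if hi_start >= lo_start
            else np.array([], dtype=int)
        )
        perturb = np.zeros((T, M, r))
        for start in np.sort(starts):
            B = peak_amp * stream.normal(size=(M, r)) / np.sqrt(r)
            in_event[start : start + dur] = True
            perturb[start : start + dur] += B[None]
        A = A + perturb

    latent = stream.normal(size=(T, r))
    noise = cfg.noise_sd * stream.normal(size=(T, M)) if cfg.noise_sd > 0 else 0.0
    values = np.einsum("tmr,tr->tm", A, latent) + noise
    labels = [f"region_{i:03d}" for i in range(M)]
    return RegionalTimeSeries(
        values=values,
        region_labels=labels,
        sampling_interval_s=cfg.sampling_interval_s,
        subject_id=record.subject_id,
    )


def _subject_stream(cfg: SimConfig, index: int) -> np.random.Generator:
    # spawn_key indexed by subject position => order-independent streams
    return np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(index + 1,))
    )


def generate_records(cfg: SimConfig) -> list[SubjectRecord]:
    """The metadata half of a cohort: ``n_per_cell`` records per diagnosis x
    sex cell, ages uniform on ``age_range``, in a deterministic order."""
    meta_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,))
    )
    records: list[SubjectRecord] = []
    k = 0
    for diagnosis in DIAGNOSES:
        for sex in SEXES:
            for _ in range(cfg.n_per_cell):
                age = float(meta_rng.uniform(*cfg.age_range))
                records.append(
                    SubjectRecord(
                        subject_id=f"sub-{k:04d}", age=age, sex=sex,
                        diagnosis=diagnosis,
                    )
                )
                k += 1
    return records


def generate_cohort(cfg: SimConfig) -> Cohort:
    """Generate ``n_per_cell`` subjects for every diagnosis x sex cell."""
    records = generate_records(cfg)
    series = {
        rec.subject_id: generate_subject_series(rec, cfg, _subject_stream(cfg, i))
        for i, rec in enumerate(records)
    }
    return Cohort(records=records, series=series)


def write_cohort(cohort: Cohort, directory: str | Path) -> list[Path]:
    """Write ``participants.tsv`` plus one ``<subject_id>_timeseries.tsv``
    per subject; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    ppath = directory / "participants.tsv"
    cohort.metadata().to_csv(ppath, sep="\t", index=False, float_format="%.10g")
    if not cohort.records:  # ensure header-only file for empty cohorts
        ppath.write_text("subject_id\tage\tsex\tdiagnosis\n")
    paths.append(ppath)
    for rec in cohort.records:
        ts = cohort.series[rec.subject_id]
        spath = directory / f"{rec.subject_id}_timeseries.tsv"
        frame = pd.DataFrame(ts.values, columns=ts.region_labels)
        frame.to_csv(spath, sep="\t", index=False, float_format="%.12g")
        paths.append(spath)
    return paths


def read_cohort(
    directory: str | Path,
    spec: WindowSpec | None = None,
    sampling_interval_s: float = 3.0,
) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (or any directory with
    a participants.tsv and per-subject time-series files)."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "participants.tsv", sep="\t")
    records = [
        SubjectRecord(
            subject_id=str(row.subject_id),
            age=float(row.age),
            sex=str(row.sex),
            diagnosis=str(row.diagnosis),
        )
        for row in meta.itertuples()
    ]
    series = {
        rec.subject_id: read_time_series(
            directory / f"{rec.subject_id}_timeseries.tsv",
            spec=spec,
            sampling_interval_s=sampling_interval_s,
            subject_id=rec.subject_id,
        )
        for rec in records
    }
    return Cohort(records=records, series=series)
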