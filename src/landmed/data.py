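"""Core data containers and CSV interchange for trial data.

A trial is exchanged as two long/wide CSV files:

* ``longitudinal.csv`` with columns ``subject_id,time,value`` — one row per
  tumor-burden assessment (LDSUM, the RECIST sum of longest diameters).
* ``survival.csv`` with columns ``subject_id,time,event,treatment`` plus any
  baseline covariate columns, split by the caller into covariates for the
  longitudinal model (``x_cols``) and for the survival model (``z_cols``).

Longitudinal time and survival time may live on different scales: the
longitudinal axis is typically rescaled to [0, 1] by dividing by the maximum
follow-up duration (``rescale_time``), while survival stays on its raw scale
(e.g. days).  The divisor is recorded in :attr:`TrialDataset.time_scale_factor`
so landmark times expressed on the survival scale can be mapped onto the
longitudinal axis (``landmark / time_scale_factor``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectTrajectory",
    "SurvivalRecord",
    "TrialDataset",
    "read_trial",
    "write_trial",
    "rescale_time",
    "filter_min_visits",
]


@dataclass(frozen=True)
class SubjectTrajectory:
    """One subject's longitudinal tumor-burden measurements.

    ``times`` are strictly increasing visit times; after rescaling they lie in
    [0, 1].  The first visit is treated as baseline.
    """

    subject_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError(f"subject {self.subject_id}: times/values must be 1-d and equal length")
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValueError(f"subject {self.subject_id}: visit times must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(values))):
            raise ValueError(f"subject {self.subject_id}: non-finite measurement")

    @property
    def baseline_value(self) -> float:
        """Measurement at the earliest visit (t = 0 for simulated data)."""
        return float(self.values[0])

    @property
    def n_post_baseline(self) -> int:
        return max(len(self.times) - 1, 0)

    @property
    def last_time(self) -> float:
        """Upper limit of the observation window, tau_i."""
        return float(self.times[-1])


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject's survival outcome and baseline covariates.

    ``observed_time`` is the censored survival duration min(T, C) and ``event``
    the indicator I(T <= C).  ``covariates_long`` (X) feed the longitudinal
    model, ``covariates_surv`` (Z) the survival model.
    """

    subject_id: str
    observed_time: float
    event: int
    treatment: int
    covariates_long: np.ndarray = field(default_factory=lambda: np.empty(0))
    covariates_surv: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        object.__setattr__(self, "covariates_long", np.atleast_1d(np.asarray(self.covariates_long, dtype=float)))
        object.__setattr__(self, "covariates_surv", np.atleast_1d(np.asarray(self.covariates_surv, dtype=float)))
        if not self.observed_time > 0:
            raise ValueError(f"subject {self.subject_id}: observed_time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: event must be 0 or 1, got {self.event!r}")
        if self.treatment not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: treatment must be 0 or 1, got {self.treatment!r}")


@dataclass(frozen=True)
class TrialDataset:
    """Paired trajectories and survival records for a cohort.

    ``time_scale_factor`` is the divisor that mapped raw longitudinal time to
    the stored scale (1.0 means unscaled).  Raw longitudinal time is recovered
    as ``times * time_scale_factor`` and is required not to exceed the
    subject's observed survival time (no measurements after death/censoring).
    """

    subjects: tuple
    time_scale_factor: float = 1.0
    x_names: tuple = ()
    z_names: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "x_names", tuple(self.x_names))
        object.__setattr__(self, "z_names", tuple(self.z_names))
        if self.time_scale_factor <= 0:
            raise ValueError("time_scale_factor must be positive")
        for traj, surv in self.subjects:
            if traj.subject_id != surv.subject_id:
                raise ValueError(f"trajectory/survival id mismatch: {traj.subject_id} vs {surv.subject_id}")
            raw_last = traj.last_time * self.time_scale_factor
            if raw_last > surv.observed_time * (1 + 1e-9) + 1e-12:
                raise ValueError(
                    f"subject {traj.subject_id}: last longitudinal time {raw_last:g} exceeds "
                    f"observed survival time {surv.observed_time:g}"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def trajectories(self) -> list:
        return [t for t, _ in self.subjects]

    @property
    def survival(self) -> list:
        return [s for _, s in self.subjects]

    @property
    def subject_ids(self) -> list:
        return [t.subject_id for t, _ in self.subjects]

    def observed_times(self) -> np.ndarray:
        return np.array([s.observed_time for _, s in self.subjects])

    def events(self) -> np.ndarray:
        return np.array([s.event for _, s in self.subjects], dtype=int)

    def treatments(self) -> np.ndarray:
        return np.array([s.treatment for _, s in self.subjects], dtype=int)

    def covariates_long(self) -> np.ndarray:
        return np.vstack([s.covariates_long for _, s in self.subjects]) if len(self) else np.empty((0, 0))

    def covariates_surv(self) -> np.ndarray:
        return np.vstack([s.covariates_surv for _, s in self.subjects]) if len(self) else np.empty((0, 0))

    def subset(self, ids: Sequence[str]) -> "TrialDataset":
        keep = set(ids)
        return replace(self, subjects=tuple(p for p in self.subjects if p[0].subject_id in keep))


_LONG_COLS = ("subject_id", "time", "value")
_SURV_COLS = ("subject_id", "time", "event", "treatment")


def read_trial(longitudinal_path, survival_path, x_cols=(), z_cols=()) -> TrialDataset:
    """Read and validate a trial from its two CSV files.

    ``x_cols``/``z_cols`` name the survival-file columns holding the
    longitudinal-model (X) and survival-model (Z) covariates.  Subjects present
    in only one file are rejected; subjects with no post-baseline measurement
    are dropped with a warning.
    """
    long_df = pd.read_csv(longitudinal_path)
    surv_df = pd.read_csv(survival_path)

    missing = [c for c in _LONG_COLS if c not in long_df.columns]
    if missing:
        raise ValueError(f"longitudinal file missing required columns: {missing}")
    missing = [c for c in _SURV_COLS if c not in surv_df.columns] + [
        c for c in (*x_cols, *z_cols) if c not in surv_df.columns
    ]
    if missing:
        raise ValueError(f"survival file missing required columns: {missing}")
    for df, name, cols in ((long_df, "longitudinal", _LONG_COLS), (surv_df, "survival", _SURV_COLS)):
        if df[list(cols)].isna().any().any():
            raise ValueError(f"{name} file contains missing values in required columns")

    long_df["subject_id"] = long_df["subject_id"].astype(str)
    surv_df["subject_id"] = surv_df["subject_id"].astype(str)

    dup = long_df.duplicated(subset=["subject_id", "time"])
    if dup.any():
        bad = long_df.loc[dup, "subject_id"].iloc[0]
        raise ValueError(f"duplicate (subject, time) rows in longitudinal file (e.g. subject {bad})")
    if surv_df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject rows in survival file")
    if not surv_df["event"].isin((0, 1)).all():
        raise ValueError("event values outside {0, 1} in survival file")

    long_ids = set(long_df["subject_id"])
    surv_ids = set(surv_df["subject_id"])
    if long_ids != surv_ids:
        odd = sorted(long_ids.symmetric_difference(surv_ids))
        raise ValueError(f"subjects present in only one file: {odd[:10]}")

    pairs = []
    n_dropped = 0
    surv_df = surv_df.set_index("subject_id")
    for sid, grp in long_df.sort_values("time").groupby("subject_id", sort=True):
        if len(grp) < 2:
            n_dropped += 1
            continue
        row = surv_df.loc[sid]
        traj = SubjectTrajectory(sid, grp["time"].to_numpy(), grp["value"].to_numpy())
        rec = SurvivalRecord(
            sid,
            float(row["time"]),
            int(row["event"]),
            int(row["treatment"]),
            row[list(x_cols)].to_numpy(dtype=float) if x_cols else np.empty(0),
            row[list(z_cols)].to_numpy(dtype=float) if z_cols else np.empty(0),
        )
        pairs.append((traj, rec))
    if n_dropped:
        logger.warning("dropped %d subject(s) with no post-baseline measurement", n_dropped)
    return TrialDataset(tuple(pairs), x_names=tuple(x_cols), z_names=tuple(z_cols))


def write_trial(dataset: TrialDataset, longitudinal_path, survival_path) -> None:
    """Write a dataset to the two-file CSV interchange format."""
    rows = [
        {"subject_id": t.subject_id, "time": ti, "value": v}
        for t, _ in dataset.subjects
        for ti, v in zip(t.times, t.values)
    ]
    pd.DataFrame(rows, columns=list(_LONG_COLS)).to_csv(longitudinal_path, index=False)

    srows = []
    for _, s in dataset.subjects:
        row = {"subject_id": s.subject_id, "time": s.observed_time, "event": s.event, "treatment": s.treatment}
        for name, v in zip(dataset.x_names, s.covariates_long):
            row[name] = v
        for name, v in zip(dataset.z_names, s.covariates_surv):
            row[name] = v
        srows.append(row)
    cols = list(_SURV_COLS) + list(dataset.x_names) + list(dataset.z_names)
    pd.DataFrame(srows, columns=cols).to_csv(survival_path, index=False)


def rescale_time(dataset: TrialDataset, max_time: float | None = None) -> TrialDataset:
    """Divide all longitudinal visit times by ``max_time``.

    Defaults to the maximum observed longitudinal time so the scaled axis is
    [0, 1].  Survival times are deliberately left on their own scale; the
    divisor is accumulated into ``time_scale_factor``.
    """
    if max_time is None:
        max_time = max((t.last_time for t, _ in dataset.subjects), default=0.0)
    if not max_time > 0:
        raise ValueError("max_time must be positive")
    subjects = tuple(
        (SubjectTrajectory(t.subject_id, t.times / max_time, t.values), s) for t, s in dataset.subjects
    )
    return replace(dataset, subjects=subjects, time_scale_factor=dataset.time_scale_factor * max_time)


def filter_min_visits(dataset: TrialDataset, min_visits: int = 3):
    """Retain subjects with at least ``min_visits`` post-baseline measurements.

    Returns ``(filtered_dataset, n_removed)``.  Matches the analysis-set rule
    of keeping only patients with enough tumor-burden follow-up.
    """
    if min_visits < 1:
        raise ValueError("min_visits must be >= 1")
    keep = tuple(p for p in dataset.subjects if p[0].n_post_baseline >= min_visits)
    n_removed = len(dataset.subjects) - len(keep)
    if not keep:
        logger.warning("filter_min_visits removed every subject (min_visits=%d)", min_visits)
    return replace(dataset, subjects=keep), n_removed
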