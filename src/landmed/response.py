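"""Mediator construction: tumor-response summaries at a landmark.

Three variants of the surrogate R_i built from data observed strictly before
the landmark (no look-ahead):

* ``binary``     — RECIST-style objective response: 1 if the tumor burden ever
                   dropped to <= 70% of baseline (partial response) or reached
                   0 (complete response) before the landmark;
* ``fpc``        — the first K conditional-expectation FPC scores, recomputed
                   in the pre-landmark window with the full-window eigensystem;
* ``integrated`` — the integral of the reconstructed mean-removed trajectory
                   over [0, min(tau_i, L_p)];
* ``none``       — no mediator (reference model).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import SubjectTrajectory, TrialDataset
from .fpca import EigenSystem, conditional_scores, integrate_trajectory, smooth_trajectory

logger = logging.getLogger(__name__)

__all__ = ["VARIANTS", "objective_response", "build_summaries"]

VARIANTS = ("none", "binary", "fpc", "integrated")
PR_THRESHOLD = 0.7  # a 30% decrease from baseline (inclusive) is a partial response


def objective_response(trajectory: SubjectTrajectory, landmark: float = np.inf) -> int:
    """Binary objective response from pre-landmark measurements.

    1 if any post-baseline value before the landmark is <= 70% of baseline
    (PR, ties count as response) or equals 0 (CR); else 0.  Requires a
    positive baseline value.
    """
    baseline = trajectory.baseline_value
    if baseline <= 0:
        raise ValueError(f"subject {trajectory.subject_id}: baseline value must be positive")
    mask = (trajectory.times > trajectory.times[0]) & (trajectory.times < landmark)
    vals = trajectory.values[mask]
    if len(vals) == 0:
        return 0
    return int(vals.min() <= PR_THRESHOLD * baseline or np.any(vals == 0))


def build_summaries(
    dataset: TrialDataset,
    eigen_system: EigenSystem | None,
    landmark: float = np.inf,
    variant: str = "none",
    K: int | None = None,
):
    """Per-subject mediator values under the chosen variant.

    ``landmark`` is on the longitudinal (scaled) axis; only measurements with
    time strictly before it are used.  Returns ``(table, excluded_ids)`` where
    ``table`` is indexed by subject id with one column per mediator dimension,
    and ``excluded_ids`` lists risk-set subjects with no pre-landmark data.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    ids = dataset.subject_ids
    excluded = []
    if variant == "none":
        return pd.DataFrame(index=pd.Index(ids, name="subject_id")), excluded
    if variant == "binary":
        vals = {sid: [objective_response(t, landmark)] for (t, _), sid in zip(dataset.subjects, ids)}
        cols = ["response"]
    else:
        if eigen_system is None:
            raise ValueError(f"variant {variant!r} requires a fitted eigensystem")
        K = eigen_system.n_components if K is None else K
        vals = {}
        cols = [f"fpc{k+1}" for k in range(K)] if variant == "fpc" else ["int_traj"]
        for t, _ in dataset.subjects:
            if not np.any(t.times < landmark):
                excluded.append(t.subject_id)
                continue
            ss = conditional_scores(t, eigen_system, K, window_end=landmark)
            if variant == "fpc":
                vals[t.subject_id] = list(ss.scores)
            else:
                dhat = smooth_trajectory(ss, eigen_system, K)
                upper = min(t.last_time, landmark)
                vals[t.subject_id] = [integrate_trajectory(dhat, eigen_system.grid, upper)]
    table = pd.DataFrame.from_dict(vals, orient="index", columns=cols)
    table.index.name = "subject_id"
    return table.loc[[i for i in ids if i in table.index]], excluded
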