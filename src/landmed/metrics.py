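"""Landmark-conditional prediction metrics: AUC, C-index at the median, Brier.

The landmark AUC at horizon u is the probability that a subject failing in
(L_p, L_p + u] receives a lower predicted survival probability than a subject
surviving past L_p + u, estimated by the fraction of concordant (case,
control) pairs with ties counted one half.  Subjects censored inside the
window are excluded from both sets (naive estimator; no IPCW weighting — the
inverse-weighted Brier variant is known to be numerically unstable and is
deliberately out of scope, so the true-probability Brier score is offered for
simulations only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cox import LandmarkFit, predict_survival

logger = logging.getLogger(__name__)

__all__ = ["MetricResult", "auc_landmark", "c_index_at_median", "brier_true"]


@dataclass(frozen=True)
class MetricResult:
    landmark: float
    horizon: float
    metric: str
    value: float
    n: int


def auc_landmark(predicted_survival, observed_times, events, landmark: float, u: float) -> MetricResult:
    """Pairwise landmark AUC at horizon u.

    All arrays are over risk-set subjects with times on the (unshifted)
    survival scale.  Cases fail in (L_p, L_p + u]; controls survive past
    L_p + u.  Returns NaN (with a warning) if either set is empty.
    """
    if u <= 0:
        raise ValueError("horizon u must be positive")
    S = np.asarray(predicted_survival, dtype=float)
    tt = np.asarray(observed_times, dtype=float)
    ee = np.asarray(events, dtype=int)
    cases = (tt > landmark) & (tt <= landmark + u) & (ee == 1)
    controls = tt > landmark + u
    n_pairs = int(cases.sum() * controls.sum())
    if n_pairs == 0:
        logger.warning("AUC undefined at landmark %.4g, u %.4g: zero cases or controls", landmark, u)
        return MetricResult(landmark, u, "auc", float("nan"), 0)
    sc = S[cases][:, None]
    sn = S[controls][None, :]
    conc = (sc < sn).sum() + 0.5 * (sc == sn).sum()
    return MetricResult(landmark, u, "auc", float(conc / n_pairs), n_pairs)


def c_index_at_median(landmark_fit: LandmarkFit, dataset) -> MetricResult:
    """Landmark AUC with the horizon anchored at the median observed event time.

    The median is computed over event (delta = 1) subjects of the full
    dataset, on the survival scale; the horizon is median - L_p.  Landmarks at
    or beyond the median yield NaN with a warning (skipped in sweeps).
    """
    times = dataset.observed_times()
    events = dataset.events()
    if events.sum() == 0:
        raise ValueError("no events: median survival time not estimable")
    median = float(np.median(times[events == 1]))
    L = landmark_fit.landmark
    u = median - L
    if u <= 0:
        logger.warning("median event time %.4g not beyond landmark %.4g; C-index skipped", median, L)
        return MetricResult(L, float("nan"), "c_index_at_median", float("nan"), 0)
    if len(landmark_fit.durations) and u > landmark_fit.durations.max():
        raise ValueError("median survival time lies beyond follow-up of the risk set")
    S = predict_survival(landmark_fit.fit, landmark_fit.design.to_numpy(dtype=float), u)
    S = np.atleast_2d(S)[:, -1] if S.ndim > 1 else np.atleast_1d(S)
    res = auc_landmark(S, landmark_fit.durations + L, landmark_fit.events, L, u)
    return MetricResult(L, u, "c_index_at_median", res.value, res.n)


def brier_true(predicted_survival, true_event_times, landmark: float, u: float, events=None) -> MetricResult:
    """Mean squared error of predicted survival against the true survival status.

    Requires uncensored true event times (simulation use).  Over subjects with
    true T > L_p: mean of (I(T > L_p + u) - S-hat(L_p + u))^2.
    """
    if events is not None and not np.all(np.asarray(events) == 1):
        raise ValueError(
            "brier_true requires uncensored true event times; for censored data see the "
            "documented limitation on inverse-probability-weighted Brier scores"
        )
    S = np.asarray(predicted_survival, dtype=float)
    T = np.asarray(true_event_times, dtype=float)
    at_risk = T > landmark
    if not at_risk.any():
        raise ValueError(f"no subjects truly at risk at landmark {landmark}")
    status = (T[at_risk] > landmark + u).astype(float)
    value = float(np.mean((status - S[at_risk]) ** 2))
    return MetricResult(landmark, u, "brier", value, int(at_risk.sum()))
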