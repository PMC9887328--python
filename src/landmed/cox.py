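"""Proportional-hazards fitting, landmark sweeps, and dynamic prediction.

The working model at landmark L_p, fitted on the risk set {i : T_i > L_p}
with residual time T_i - L_p, is

    h(t | O_p) = h0_p(t) * exp{ beta1(L_p) A + beta2(L_p) Z + alpha(L_p) R_p },

where R_p is the pre-landmark tumor-burden summary (binary response, FPC
scores, or integrated smoothed trajectory).  Sweeping L_p over a grid yields
coefficient trajectories and, through the Breslow baseline, dynamic survival
predictions S(L_p + t | alive at L_p, data before L_p).

Partial-likelihood maximization uses Efron tie handling; the baseline
cumulative hazard is the Breslow/Efron estimator evaluated at the sample mean
of the predictors, with the centering vector stored on the fit so predictions
stay center-consistent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .data import TrialDataset
from .fpca import EigenSystem
from .response import build_summaries

logger = logging.getLogger(__name__)

__all__ = ["CoxFit", "LandmarkFit", "risk_set", "fit_cox", "landmark_sweep", "predict_survival", "coefficient_table"]

_DIVERGENCE_BOUND = 25.0  # |coef| beyond this flags monotone likelihood / separation


@dataclass
class CoxFit:
    """A fitted PH model with Breslow baseline at mean-centered predictors."""

    names: tuple
    coef: np.ndarray
    vcov: np.ndarray
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    center: np.ndarray
    n_at_risk: int
    n_events: int
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov)) if self.vcov.size else np.empty(0)


@dataclass
class LandmarkFit:
    """A CoxFit at one landmark, with the design it was fitted on."""

    landmark: float
    fit: CoxFit
    variant: str
    design: pd.DataFrame = field(repr=False)
    durations: np.ndarray = field(repr=False)  # residual times T - L_p
    events: np.ndarray = field(repr=False)
    subject_ids: list = field(repr=False, default_factory=list)


def risk_set(dataset: TrialDataset, landmark: float) -> TrialDataset:
    """Subjects still under observation strictly after the landmark.

    Survival times are shifted to the residual scale T - L_p; trajectories are
    carried unchanged (summary construction applies its own window).
    """
    if landmark < 0:
        raise ValueError("landmark must be >= 0")
    if landmark == 0:
        return dataset
    pairs = tuple(
        (t, _shift(s, landmark)) for t, s in dataset.subjects if s.observed_time > landmark
    )
    if not pairs:
        raise ValueError(f"empty risk set at landmark {landmark}")
    ds = TrialDataset.__new__(TrialDataset)
    object.__setattr__(ds, "subjects", pairs)
    object.__setattr__(ds, "time_scale_factor", dataset.time_scale_factor)
    object.__setattr__(ds, "x_names", dataset.x_names)
    object.__setattr__(ds, "z_names", dataset.z_names)
    return ds


def _shift(s, landmark):
    from dataclasses import replace

    return replace(s, observed_time=s.observed_time - landmark)


def _breslow_efron_baseline(durations, events, lp):
    """Baseline cumulative hazard with Efron correction for tied events.

    ``lp`` must already be centered; returns (event_times, cumhaz) as a
    right-continuous step function starting at H0(0) = 0.
    """
    order = np.argsort(durations, kind="stable")
    tt, ee, ll = durations[order], events[order], np.exp(lp[order])
    # risk-set sums by suffix cumulative sum
    event_times = np.unique(tt[ee == 1])
    increments = np.empty(len(event_times))
    for k, et in enumerate(event_times):
        at_risk = tt >= et
        tied = (tt == et) & (ee == 1)
        d = tied.sum()
        s_risk = ll[at_risk].sum()
        s_tied = ll[tied].sum()
        inc = 0.0
        for r in range(d):
            inc += 1.0 / (s_risk - (r / d) * s_tied)
        increments[k] = inc
    return event_times, np.cumsum(increments)


def fit_cox(durations, events, predictors: pd.DataFrame) -> CoxFit:
    """Maximum partial likelihood PH fit (Efron ties) with Breslow baseline.

    An empty predictor frame is allowed and yields the no-covariate model
    (Nelson-Aalen-type baseline, empty coefficient vector).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("no events in the data; PH model unidentifiable")
    predictors = pd.DataFrame(predictors)
    names = tuple(predictors.columns)
    X = predictors.to_numpy(dtype=float)
    n, q = X.shape

    if q == 0:
        bt, bh = _breslow_efron_baseline(durations, events, np.zeros(n))
        return CoxFit(names, np.empty(0), np.empty((0, 0)), bt, bh, np.empty(0), n, int(events.sum()), True)

    if np.linalg.matrix_rank(X - X.mean(axis=0)) < q:
        raise ValueError("predictor matrix is rank deficient among at-risk subjects")

    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.PHReg(durations, X, status=events, ties="efron")
        try:
            result = model.fit(method="newton", maxiter=50, tol=1e-9, disp=False)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"PH fit failed (possible separation or collinearity): {err}") from err
        if any(issubclass(w.category, (ConvergenceWarning, RuntimeWarning)) for w in caught):
            converged = False
    coef = np.asarray(result.params, dtype=float)
    vcov = np.asarray(result.cov_params(), dtype=float)
    if np.max(np.abs(coef)) > _DIVERGENCE_BOUND:
        logger.warning("coefficient divergence detected (|coef| > %g); flagging non-convergence", _DIVERGENCE_BOUND)
        converged = False

    center = X.mean(axis=0)
    lp = (X - center) @ coef
    bt, bh = _breslow_efron_baseline(durations, events, lp)
    return CoxFit(names, coef, vcov, bt, bh, center, n, int(events.sum()), converged)


def predict_survival(fit: CoxFit, new_predictors, horizon_t) -> np.ndarray:
    """Conditional survival S-hat(L_p + t | L_p) for new subjects.

    ``new_predictors`` is (n, q) in the fit's declared order; ``horizon_t`` a
    scalar or array of residual times.  S = S0(t)^exp(lp), with the Breslow
    baseline step-interpolated (right-continuous); horizons beyond the last
    baseline jump use the last value with a warning.
    """
    X = np.atleast_2d(np.asarray(new_predictors, dtype=float))
    t = np.atleast_1d(np.asarray(horizon_t, dtype=float))
    if np.any(t < 0):
        raise ValueError("horizon_t must be >= 0")
    if fit.coef.size:
        lp = (X - fit.center) @ fit.coef
    else:
        lp = np.zeros(max(X.shape[0], 1))
    if len(fit.baseline_times) and np.any(t > fit.baseline_times[-1]):
        logger.warning("horizon beyond last baseline-hazard jump; extrapolating flat")
    idx = np.searchsorted(fit.baseline_times, t, side="right")
    H0 = np.concatenate([[0.0], fit.baseline_cumhaz])[idx]
    S = np.exp(-np.outer(np.exp(lp), H0))
    return S[0] if np.isscalar(horizon_t) and S.shape[0] == 1 else np.squeeze(S)


def landmark_sweep(
    dataset: TrialDataset,
    landmarks,
    variant: str = "none",
    K: int | None = None,
    eigen_system: EigenSystem | None = None,
    min_events: int = 5,
) -> list:
    """Fit the landmark PH model at each landmark time.

    Landmarks are on the survival scale; summary windows are mapped onto the
    longitudinal axis via ``dataset.time_scale_factor``.  Landmarks whose risk
    set has fewer than ``min_events`` events are skipped with a warning.
    """
    landmarks = np.asarray(landmarks, dtype=float)
    if np.any(np.diff(landmarks) <= 0):
        raise ValueError("landmarks must be strictly increasing")
    fits = []
    for L in landmarks:
        try:
            rs = risk_set(dataset, L)
        except ValueError:
            logger.warning("landmark %.4g skipped: empty risk set", L)
            continue
        if rs.events().sum() < min_events:
            logger.warning("landmark %.4g skipped: fewer than %d events", L, min_events)
            continue
        window = np.inf if L == 0 else L / dataset.time_scale_factor
        summaries, excluded = build_summaries(rs, eigen_system, landmark=window, variant=variant, K=K)
        if excluded:
            logger.info("landmark %.4g: excluded %d subject(s) with no pre-landmark data", L, len(excluded))
            rs = rs.subset(list(summaries.index))
        design = pd.DataFrame({"treatment": rs.treatments().astype(float)}, index=rs.subject_ids)
        Z = rs.covariates_surv()
        z_names = rs.z_names if rs.z_names else tuple(f"z{j+1}" for j in range(Z.shape[1]))
        for j, name in enumerate(z_names):
            design[name] = Z[:, j]
        for col in summaries.columns:
            design[col] = summaries.loc[design.index, col].to_numpy()
        fit = fit_cox(rs.observed_times(), rs.events(), design)
        fits.append(
            LandmarkFit(
                landmark=float(L),
                fit=fit,
                variant=variant,
                design=design,
                durations=rs.observed_times(),
                events=rs.events(),
                subject_ids=rs.subject_ids,
            )
        )
    return fits


def coefficient_table(fits) -> pd.DataFrame:
    """Long-format coefficient trajectories: (landmark, coefficient, estimate, se)."""
    rows = []
    for lf in fits:
        for name, est, se in zip(lf.fit.names, lf.fit.coef, lf.fit.se):
            rows.append({"landmark": lf.landmark, "coefficient": name, "estimate": est, "se": se})
    return pd.DataFrame(rows, columns=["landmark", "coefficient", "estimate", "se"])
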