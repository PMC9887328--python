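"""R-squared effect-size measures for treatment mediation on survival.

Three proportional-hazards models are fitted on the complete data:

* direct:   h(t | A)    = h0_D(t) exp{beta1_D A}
* mediated: h(t | R)    = h0_M(t) exp{alpha_M' R}
* full:     h(t | A, R) = h0_F(t) exp{beta1_F A + alpha_F' R}

Each yields an explained-variation measure R^2 in [0, 1); the mediated effect
size and the shared-over-simple (SOS) effect are

    R2_med = R2_{T,D} + R2_{T,M} - R2_{T,F},        SOS = R2_med / R2_{T,D}.

Two R^2 measures are supported:

* ``Rb`` — Heller's explained relative risk,
  R2_b = log[N^-1 sum exp(theta' P~)] / (c + log[N^-1 sum exp(theta' P~)] - 1)
  with P~ mean-centered predictors and c = 1 + Euler-Mascheroni ~ 1.5772, the
  entropy of the standard extreme-value (Gumbel) error distribution;
* ``Rw`` — the Weibull-model approximation based on the product-moment
  correlation with standard-normal error variance,
  R2_w = theta' Sigma_P theta / (1 + theta' Sigma_P theta).

Both are identically 0 when all fitted coefficients vanish.  Estimated R2_med
and SOS can legitimately fall outside [0, 1] in finite samples (small total
effects, moderate N); such values are flagged, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cox import fit_cox

__all__ = ["GUMBEL_ENTROPY", "MediationResult", "r2_heller", "r2_weibull_approx", "combine_r2", "mediation_decomposition"]

#: Entropy of the standard extreme-value distribution, 1 + Euler-Mascheroni.
#: Printed to four decimals this is 1.5772.
GUMBEL_ENTROPY = 1.0 + float(np.euler_gamma)


@dataclass
class MediationResult:
    measure: str  # "Rb" or "Rw"
    variant: str
    r2_direct: float
    r2_mediated_model: float
    r2_full: float
    r2_med: float
    sos: float
    flags: dict = field(default_factory=dict)


def r2_heller(theta_hat, predictor_matrix) -> float:
    """Heller's explained relative risk R2_b for a fitted PH model."""
    theta = np.atleast_1d(np.asarray(theta_hat, dtype=float))
    P = np.atleast_2d(np.asarray(predictor_matrix, dtype=float))
    if P.shape[1] != len(theta):
        P = P.T
    n = P.shape[0]
    if n == 0:
        raise ValueError("empty predictor matrix")
    lp = (P - P.mean(axis=0)) @ theta
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite linear predictors")
    num = float(logsumexp(lp) - np.log(n))  # log[N^-1 sum exp(theta' P~)]
    return num / (GUMBEL_ENTROPY + num - 1.0)


def r2_weibull_approx(theta_hat, predictor_matrix) -> float:
    """Weibull-approximation explained risk R2_w = q / (1 + q), q = theta' Sigma theta."""
    theta = np.atleast_1d(np.asarray(theta_hat, dtype=float))
    P = np.atleast_2d(np.asarray(predictor_matrix, dtype=float))
    if P.shape[1] != len(theta):
        P = P.T
    Sigma = np.atleast_2d(np.cov(P, rowvar=False, ddof=1))
    q = float(theta @ Sigma @ theta)
    return q / (1.0 + q)


_MEASURES = {"Rb": r2_heller, "Rw": r2_weibull_approx}


def combine_r2(r2_direct: float, r2_mediated_model: float, r2_full: float):
    """Mediated effect size and SOS from the three model-level R^2 components.

    Returns ``(r2_med, sos, flags)``; SOS is NaN (flagged) when the total
    effect R2_direct is zero.
    """
    r2_med = r2_direct + r2_mediated_model - r2_full
    flags = {}
    if r2_direct > 0:
        sos = r2_med / r2_direct
    else:
        sos = float("nan")
        flags["sos_undefined"] = True
    if r2_med < 0:
        flags["negative_r2_med"] = True
    if np.isfinite(sos) and not (0 <= sos <= 1):
        flags["sos_out_of_range"] = True
    return r2_med, sos, flags


def mediation_decomposition(
    durations,
    events,
    treatment,
    mediator,
    measure: str = "Rw",
    variant: str = "",
    Z=None,
    include_Z: bool = False,
) -> MediationResult:
    """Fit the direct/mediated/full PH models and decompose explained variation.

    ``mediator`` is an (N,) or (N, K) array or DataFrame — multidimensional
    mediators (K FPC scores) enter as K columns and the R^2 formulas operate
    on the full coefficient vector.  ``include_Z`` adds the survival
    covariates Z to all three models symmetrically (off by default; the
    canonical decomposition uses A and R alone).
    """
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(_MEASURES)}")
    r2 = _MEASURES[measure]
    A = pd.DataFrame({"treatment": np.asarray(treatment, dtype=float)})
    R = pd.DataFrame(mediator)
    R.columns = [str(c) for c in R.columns]
    R.index = A.index
    extra = pd.DataFrame(index=A.index)
    if include_Z and Z is not None and np.size(Z):
        Zm = np.atleast_2d(np.asarray(Z, dtype=float))
        if Zm.shape[0] != len(A):
            Zm = Zm.T
        for j in range(Zm.shape[1]):
            extra[f"z{j+1}"] = Zm[:, j]

    designs = {
        "direct": pd.concat([A, extra], axis=1),
        "mediated": pd.concat([R, extra], axis=1),
        "full": pd.concat([A, R, extra], axis=1),
    }
    comps = {}
    for key, X in designs.items():
        fit = fit_cox(durations, events, X)
        comps[key] = r2(fit.coef, X.to_numpy(dtype=float))
    r2_med, sos, flags = combine_r2(comps["direct"], comps["mediated"], comps["full"])
    return MediationResult(
        measure=measure,
        variant=variant,
        r2_direct=comps["direct"],
        r2_mediated_model=comps["mediated"],
        r2_full=comps["full"],
        r2_med=r2_med,
        sos=sos,
        flags=flags,
    )
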