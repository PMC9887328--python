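"""Varying-coefficient (function-on-scalar) regression of smoothed trajectories.

Fits, at every grid point t, ordinary least squares of the reconstructed
trajectories on (1, A, X):

    Y-hat_i(t) = eta0(t) + eta1(t) A_i + eta2(t)' X_i + error,

yielding the time-varying treatment and covariate effect curves with pointwise
standard errors.  The inputs are already smooth PACE reconstructions, so no
additional smoothing across t is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CoefficientFunctions", "fit_varying_coefficients"]


@dataclass
class CoefficientFunctions:
    grid: np.ndarray
    names: tuple  # ("intercept", "treatment", x names...)
    coef: np.ndarray  # (q, G)
    se: np.ndarray  # (q, G)

    @property
    def intercept(self) -> np.ndarray:
        return self.coef[0]

    @property
    def treatment_effect(self) -> np.ndarray:
        return self.coef[1]

    @property
    def covariate_effects(self) -> np.ndarray:
        return self.coef[2:]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.names):
            for g, t in enumerate(self.grid):
                rows.append({"t": t, "coefficient": name, "estimate": self.coef[i, g], "se": self.se[i, g]})
        return pd.DataFrame(rows)


def fit_varying_coefficients(trajectories, treatments, X=None, grid=None, x_names=()) -> CoefficientFunctions:
    """Pointwise OLS of trajectories (N x G, on the common grid) on (1, A, X)."""
    Y = np.asarray(trajectories, dtype=float)
    A = np.asarray(treatments, dtype=float)
    n, G = Y.shape
    grid = np.linspace(0, 1, G) if grid is None else np.asarray(grid, dtype=float)
    cols = [np.ones(n), A]
    names = ["intercept", "treatment"]
    if X is not None and np.size(X):
        Xm = np.atleast_2d(np.asarray(X, dtype=float))
        if Xm.shape[0] != n:
            Xm = Xm.T
        for j in range(Xm.shape[1]):
            cols.append(Xm[:, j])
            names.append(x_names[j] if j < len(x_names) else f"x{j+1}")
    D = np.column_stack(cols)
    q = D.shape[1]
    if np.linalg.matrix_rank(D) < q:
        raise ValueError("rank-deficient design (e.g. all subjects in one arm)")
    DtD_inv = np.linalg.inv(D.T @ D)
    coef = DtD_inv @ D.T @ Y  # (q, G)
    resid = Y - D @ coef
    dof = max(n - q, 1)
    sigma2 = (resid**2).sum(axis=0) / dof  # per grid point
    se = np.sqrt(np.outer(np.diag(DtD_inv), sigma2))
    return CoefficientFunctions(grid=grid, names=tuple(names), coef=coef, se=se)
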