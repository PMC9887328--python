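"""Sparse functional principal component analysis by conditional expectation (PACE).

Irregular, noisy tumor-burden trajectories Y_i(t) are modelled as

    Y_i(t) = eta0(t) + D_i(t) + eps_i(t),      eps ~ N(0, sigma^2),

with the mean-removed process expanded in a Karhunen--Loeve basis,
D_i(t) = sum_k gamma_ik rho_k(t), where the rho_k are orthonormal
eigenfunctions of the covariance surface G(s, t) = Cov{D(s), D(t)} and the
gamma_ik are subject-level scores with Var(gamma_ik) = lambda_k.

Estimation follows the standard PACE recipe for sparse designs:

1. pool all (t, Y) points and smooth them (local linear) for eta0-hat;
2. form raw covariance cross-products of residuals for visit pairs j != l and
   smooth them into a surface G-hat; the diagonal (j = l) carries the extra
   measurement-error variance sigma^2 and is excluded from the surface fit;
3. eigendecompose G-hat under trapezoid quadrature weights;
4. predict each subject's scores by their conditional expectation (best linear
   prediction) given the subject's own sparse observations — this shrinks raw
   projections toward zero in proportion to the noise, and is what makes the
   method usable with a handful of visits per subject.

Landmark use: the eigensystem is fitted once on the full observation window;
per-landmark summaries only recompute scores from data observed strictly
before the landmark (``window_end``), never re-fitting the basis.

Smoothing bandwidths are chosen by generalized cross-validation over a
geometric candidate grid on data binned to the evaluation grid (binning makes
the fit O(grid) rather than O(n_pairs) and is exact when observation times lie
on the grid, as simulated visit schedules do).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh

from .data import SubjectTrajectory, TrialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "EigenSystem",
    "ScoreSet",
    "estimate_mean",
    "estimate_covariance",
    "eigendecompose",
    "select_K",
    "conditional_scores",
    "smooth_trajectory",
    "integrate_trajectory",
    "fit_pace",
    "default_grid",
]

SIGMA2_FLOOR = 1e-8


def default_grid(n: int = 51) -> np.ndarray:
    """Equispaced evaluation grid on [0, 1]."""
    return np.linspace(0.0, 1.0, n)


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights w such that sum(w * f) = trapz(f, grid)."""
    w = np.empty_like(grid)
    d = np.diff(grid)
    w[0] = d[0] / 2
    w[-1] = d[-1] / 2
    w[1:-1] = (d[:-1] + d[1:]) / 2
    return w


@dataclass
class EigenSystem:
    """Estimated mean function, eigenfunctions and eigenvalues on a grid.

    ``eigenfunctions`` has one row per component, orthonormal in L2 under
    trapezoid quadrature; ``eigenvalues`` are non-negative and non-increasing;
    ``fve`` is the cumulative fraction of variance explained.
    """

    grid: np.ndarray
    mean: np.ndarray
    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    noise_variance: float
    fve: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def to_json(self, path) -> None:
        payload = {
            "grid": self.grid.tolist(),
            "mean": self.mean.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "noise_variance": self.noise_variance,
            "fve": self.fve.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "EigenSystem":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            np.array(p["grid"]),
            np.array(p["mean"]),
            np.array(p["eigenfunctions"]),
            np.array(p["eigenvalues"]),
            float(p["noise_variance"]),
            np.array(p["fve"]),
        )


@dataclass(frozen=True)
class ScoreSet:
    """Conditional-expectation FPC scores for one subject.

    ``window_end`` records the upper time limit of the data used (the
    subject's last observation tau_i, or the landmark when smaller).
    """

    subject_id: str
    scores: np.ndarray
    window_end: float


# ---------------------------------------------------------------------------
# local-linear smoothing on binned data


def _bin_1d(x, y, grid):
    spacing = grid[1] - grid[0]
    idx = np.clip(np.rint((x - grid[0]) / spacing).astype(int), 0, len(grid) - 1)
    counts = np.bincount(idx, minlength=len(grid)).astype(float)
    sums = np.bincount(idx, weights=y, minlength=len(grid))
    mask = counts > 0
    with np.errstate(invalid="ignore"):
        means = np.where(mask, sums / np.maximum(counts, 1), 0.0)
    return grid[mask], means[mask], counts[mask]


def _loclin_1d(xb, yb, wb, eval_x, h):
    """Weighted local-linear fit at eval_x; Gaussian kernel, bandwidth h."""
    d = xb[None, :] - eval_x[:, None]
    u = wb[None, :] * np.exp(-0.5 * (d / h) ** 2)
    s0 = u.sum(axis=1)
    s1 = (u * d).sum(axis=1)
    s2 = (u * d * d).sum(axis=1)
    t0 = (u * yb[None, :]).sum(axis=1)
    t1 = (u * d * yb[None, :]).sum(axis=1)
    det = s0 * s2 - s1 * s1
    det = np.where(np.abs(det) < 1e-300, 1e-300, det)
    return (s2 * t0 - s1 * t1) / det


def _gcv_1d(xb, yb, wb, h):
    d = xb[None, :] - xb[:, None]
    u = wb[None, :] * np.exp(-0.5 * (d / h) ** 2)
    s0 = u.sum(axis=1)
    s1 = (u * d).sum(axis=1)
    s2 = (u * d * d).sum(axis=1)
    det = s0 * s2 - s1 * s1
    if np.any(det <= 0):
        return np.inf
    fit = (s2 * (u * yb[None, :]).sum(axis=1) - s1 * (u * d * yb[None, :]).sum(axis=1)) / det
    lev = np.diag(u) * s2 / det  # own-bin leverage
    n = len(xb)
    denom = (1 - lev.sum() / n) ** 2
    if denom <= 0:
        return np.inf
    rss = np.sum(wb * (yb - fit) ** 2) / wb.sum()
    return rss / denom


def _select_bandwidth_1d(xb, yb, wb, grid):
    span = grid[-1] - grid[0]
    spacing = grid[1] - grid[0]
    candidates = np.geomspace(max(1.5 * spacing, 0.02 * span), 0.4 * span, 8)
    scores = [_gcv_1d(xb, yb, wb, h) for h in candidates]
    if not np.any(np.isfinite(scores)):
        logger.warning("mean GCV failed for all candidate bandwidths; using fallback 0.1*span")
        return 0.1 * span
    return float(candidates[int(np.nanargmin(scores))])


def estimate_mean(dataset: TrialDataset, grid: np.ndarray | None = None, bandwidth="auto") -> np.ndarray:
    """Local-linear estimate of the overall mean trajectory eta0(t).

    Pools (time, value) points across subjects; ``bandwidth`` may be a float
    or ``"auto"`` for GCV selection.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    t = np.concatenate([traj.times for traj in dataset.trajectories])
    y = np.concatenate([traj.values for traj in dataset.trajectories])
    if len(t) < 10:
        raise ValueError(f"need >= 10 pooled observations to smooth a mean, got {len(t)}")
    xb, yb, wb = _bin_1d(t, y, grid)
    spacing = grid[1] - grid[0]
    if bandwidth == "auto":
        bandwidth = _select_bandwidth_1d(xb, yb, wb, grid)
    elif bandwidth < spacing:
        raise ValueError(f"bandwidth {bandwidth} smaller than grid spacing {spacing}")
    mean = _loclin_1d(xb, yb, wb, grid, float(bandwidth))
    if not np.all(np.isfinite(mean)):
        raise RuntimeError("mean smoothing produced non-finite values")
    return mean


def _loclin_2d(sb, tb, yb, wb, Seval, Teval, h):
    """Local-linear plane fit at each (Seval, Teval) point; product Gaussian kernel."""
    out = np.empty(len(Seval))
    chunk = 256
    for start in range(0, len(Seval), chunk):
        sl = slice(start, start + chunk)
        ds = sb[None, :] - Seval[sl, None]
        dt = tb[None, :] - Teval[sl, None]
        u = wb[None, :] * np.exp(-0.5 * ((ds / h) ** 2 + (dt / h) ** 2))
        A = np.empty((ds.shape[0], 3, 3))
        A[:, 0, 0] = u.sum(1)
        A[:, 0, 1] = A[:, 1, 0] = (u * ds).sum(1)
        A[:, 0, 2] = A[:, 2, 0] = (u * dt).sum(1)
        A[:, 1, 1] = (u * ds * ds).sum(1)
        A[:, 1, 2] = A[:, 2, 1] = (u * ds * dt).sum(1)
        A[:, 2, 2] = (u * dt * dt).sum(1)
        b = np.stack([(u * yb).sum(1), (u * ds * yb).sum(1), (u * dt * yb).sum(1)], axis=1)
        A += 1e-12 * np.eye(3)
        try:
            beta = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.stack([np.linalg.lstsq(Ai, bi, rcond=None)[0] for Ai, bi in zip(A, b)])
        out[sl] = beta[:, 0]
    return out


def _gcv_2d(sb, tb, yb, wb, h):
    fit = _loclin_2d(sb, tb, yb, wb, sb, tb, h)
    # own-bin leverage: u_b * [A^{-1}]_00 at each bin
    lev = np.empty(len(sb))
    chunk = 256
    for start in range(0, len(sb), chunk):
        sl = slice(start, start + chunk)
        ds = sb[None, :] - sb[sl, None]
        dt = tb[None, :] - tb[sl, None]
        u = wb[None, :] * np.exp(-0.5 * ((ds / h) ** 2 + (dt / h) ** 2))
        A = np.empty((ds.shape[0], 3, 3))
        A[:, 0, 0] = u.sum(1)
        A[:, 0, 1] = A[:, 1, 0] = (u * ds).sum(1)
        A[:, 0, 2] = A[:, 2, 0] = (u * dt).sum(1)
        A[:, 1, 1] = (u * ds * ds).sum(1)
        A[:, 1, 2] = A[:, 2, 1] = (u * ds * dt).sum(1)
        A[:, 2, 2] = (u * dt * dt).sum(1)
        A += 1e-12 * np.eye(3)
        try:
            inv00 = np.linalg.inv(A)[:, 0, 0]
        except np.linalg.LinAlgError:
            return np.inf
        own = wb[sl] * 1.0  # kernel at zero distance = 1
        lev[sl] = own * inv00
    n = len(sb)
    denom = (1 - lev.sum() / n) ** 2
    if denom <= 0 or not np.all(np.isfinite(fit)):
        return np.inf
    rss = np.sum(wb * (yb - fit) ** 2) / wb.sum()
    return rss / denom


def estimate_covariance(dataset: TrialDataset, mean: np.ndarray, grid: np.ndarray | None = None, bandwidth="auto"):
    """Smooth raw covariance cross-products into a surface; estimate sigma^2.

    Off-diagonal residual products (j != l) are binned to the grid x grid
    lattice and smoothed with a 2-d local-linear fit.  The noise variance is
    the average gap between a 1-d smooth of the squared residuals (which
    carries sigma^2) and the surface diagonal, over the central 80% of the
    domain, floored at ``SIGMA2_FLOOR``.

    Returns ``(surface, noise_variance)``; the surface is exactly symmetric.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    G = len(grid)
    spacing = grid[1] - grid[0]

    sum2d = np.zeros((G, G))
    cnt2d = np.zeros((G, G))
    diag_t, diag_v = [], []
    any_pairs = False
    for traj in dataset.trajectories:
        resid = traj.values - np.interp(traj.times, grid, mean)
        idx = np.argmin(np.abs(traj.times[:, None] - grid[None, :]), axis=1)
        diag_t.append(traj.times)
        diag_v.append(resid**2)
        m = len(idx)
        if m < 2:
            continue
        any_pairs = True
        cross = np.outer(resid, resid)
        off = ~np.eye(m, dtype=bool)
        np.add.at(sum2d, (idx[:, None].repeat(m, 1)[off], idx[None, :].repeat(m, 0)[off]), cross[off])
        np.add.at(cnt2d, (idx[:, None].repeat(m, 1)[off], idx[None, :].repeat(m, 0)[off]), 1.0)
    if not any_pairs:
        raise ValueError("no subject has >= 2 visits; covariance surface unidentifiable")

    mask = cnt2d > 0
    ii, jj = np.nonzero(mask)
    sb, tb = grid[ii], grid[jj]
    wb = cnt2d[mask]
    yb = sum2d[mask] / wb

    if bandwidth == "auto":
        span = grid[-1] - grid[0]
        candidates = np.geomspace(max(2.0 * spacing, 0.05 * span), 0.45 * span, 6)
        scores = [_gcv_2d(sb, tb, yb, wb, h) for h in candidates]
        if not np.any(np.isfinite(scores)):
            logger.warning("covariance GCV failed; using fallback 0.1*span")
            bandwidth = 0.1 * span
        else:
            bandwidth = float(candidates[int(np.nanargmin(scores))])
    elif bandwidth < spacing:
        raise ValueError(f"bandwidth {bandwidth} smaller than grid spacing {spacing}")

    SS, TT = np.meshgrid(grid, grid, indexing="ij")
    surface = _loclin_2d(sb, tb, yb, wb, SS.ravel(), TT.ravel(), float(bandwidth)).reshape(G, G)
    surface = (surface + surface.T) / 2.0

    # diagonal smooth of squared residuals carries G(t,t) + sigma^2
    dt_all = np.concatenate(diag_t)
    dv_all = np.concatenate(diag_v)
    xb, ybd, wbd = _bin_1d(dt_all, dv_all, grid)
    vdiag = _loclin_1d(xb, ybd, wbd, grid, float(bandwidth))
    lo, hi = grid[0] + 0.1 * (grid[-1] - grid[0]), grid[-1] - 0.1 * (grid[-1] - grid[0])
    central = (grid >= lo) & (grid <= hi)
    sigma2 = float(np.mean(vdiag[central] - np.diag(surface)[central]))
    sigma2 = max(sigma2, SIGMA2_FLOOR)
    return surface, sigma2


def eigendecompose(
    surface: np.ndarray,
    grid: np.ndarray,
    mean: np.ndarray | None = None,
    noise_variance: float = 0.0,
) -> EigenSystem:
    """Quadrature-weighted eigendecomposition of a covariance surface.

    Eigenvalues are clipped at zero; eigenfunctions are rescaled to unit L2
    norm under trapezoid quadrature and signed so each has a non-negative
    integral (falling back to a non-negative left-most non-zero value).
    """
    grid = np.asarray(grid, dtype=float)
    w = trapezoid_weights(grid)
    sq = np.sqrt(w)
    M = sq[:, None] * ((surface + surface.T) / 2.0) * sq[None, :]
    vals, vecs = eigh((M + M.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(vals.max(initial=0.0), 0.0) * 1e-12
    keep = vals > tol
    if not keep.any():
        raise ValueError("covariance surface has no positive eigenvalue")
    vals = vals[keep]
    phis = vecs[:, keep] / sq[:, None]
    # unit L2 norm and sign convention
    for k in range(phis.shape[1]):
        nrm = np.sqrt(np.trapezoid(phis[:, k] ** 2, grid))
        phis[:, k] /= nrm
        integral = np.trapezoid(phis[:, k], grid)
        if abs(integral) > 1e-10:
            sign = np.sign(integral)
        else:
            nz = np.nonzero(np.abs(phis[:, k]) > 1e-10)[0]
            sign = np.sign(phis[nz[0], k]) if len(nz) else 1.0
        phis[:, k] *= sign
    fve = np.cumsum(vals) / vals.sum()
    return EigenSystem(
        grid=grid,
        mean=np.zeros_like(grid) if mean is None else np.asarray(mean, dtype=float),
        eigenfunctions=phis.T.copy(),
        eigenvalues=vals,
        noise_variance=float(noise_variance),
        fve=fve,
    )


def select_K(eigen_system: EigenSystem, fve_threshold: float = 0.90) -> int:
    """Smallest K whose cumulative fraction of variance explained meets the threshold."""
    if not 0 < fve_threshold <= 1:
        raise ValueError("fve_threshold must be in (0, 1]")
    return int(np.searchsorted(eigen_system.fve, fve_threshold - 1e-12) + 1)


def conditional_scores(
    subject: SubjectTrajectory,
    eigen_system: EigenSystem,
    K: int,
    window_end: float = np.inf,
) -> ScoreSet:
    """Best-linear-prediction (conditional expectation) FPC scores.

    Only observations strictly before ``window_end`` are used, so the same
    fitted eigensystem serves every landmark.  The model covariance at the
    subject's observed times is built from all retained components plus the
    noise variance on the diagonal; a small ridge is added if it is
    numerically singular.
    """
    es = eigen_system
    if K > es.n_components:
        raise ValueError(f"K={K} exceeds available components ({es.n_components})")
    use = subject.times < window_end
    if not use.any():
        raise ValueError(f"subject {subject.subject_id}: no observations before window_end={window_end}")
    t = subject.times[use]
    y = subject.values[use]
    mu = np.interp(t, es.grid, es.mean)
    Phi = np.vstack([np.interp(t, es.grid, phi) for phi in es.eigenfunctions]).T  # m x Kall
    Sigma = (Phi * es.eigenvalues[None, :]) @ Phi.T + es.noise_variance * np.eye(len(t))
    try:
        cf = cho_factor(Sigma)
    except np.linalg.LinAlgError:
        cf = cho_factor(Sigma + 1e-8 * np.eye(len(t)))
    sol = cho_solve(cf, y - mu)
    scores = es.eigenvalues[:K] * (Phi[:, :K].T @ sol)
    return ScoreSet(subject.subject_id, scores, float(min(window_end, subject.last_time)))


def smooth_trajectory(score_set: ScoreSet, eigen_system: EigenSystem, K: int | None = None) -> np.ndarray:
    """K-truncated reconstruction D-hat_i(t) on the grid (mean removed).

    Defined on the full grid, i.e. extrapolated beyond the subject's observed
    window as well; ``score_set.window_end`` records where observation ends.
    """
    K = len(score_set.scores) if K is None else K
    if K > eigen_system.n_components or K > len(score_set.scores):
        raise ValueError("K exceeds available components/scores")
    return score_set.scores[:K] @ eigen_system.eigenfunctions[:K]


def integrate_trajectory(values: np.ndarray, grid: np.ndarray, upper_limit: float) -> float:
    """Trapezoid integral of a reconstructed trajectory over [0, upper_limit].

    In landmark mode the caller passes ``upper_limit = min(tau_i, L_p)``.
    """
    if upper_limit <= 0:
        raise ValueError("upper_limit must be positive")
    if upper_limit > grid[-1] + 1e-9:
        raise ValueError(f"upper_limit {upper_limit} beyond grid maximum {grid[-1]}")
    upper_limit = min(upper_limit, grid[-1])
    inside = grid <= upper_limit
    xs = grid[inside]
    ys = values[inside]
    if xs[-1] < upper_limit:
        xs = np.append(xs, upper_limit)
        ys = np.append(ys, np.interp(upper_limit, grid, values))
    return float(np.trapezoid(ys, xs))


def fit_pace(
    dataset: TrialDataset,
    grid: np.ndarray | None = None,
    mean_bandwidth="auto",
    cov_bandwidth="auto",
) -> EigenSystem:
    """Full PACE fit: mean, covariance surface + noise, eigendecomposition."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    mean = estimate_mean(dataset, grid, mean_bandwidth)
    surface, sigma2 = estimate_covariance(dataset, mean, grid, cov_bandwidth)
    return eigendecompose(surface, grid, mean=mean, noise_variance=sigma2)
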