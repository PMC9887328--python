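import numpy as np
import pytest

import landmed as lm


@pytest.fixture(scope="session")
def trial_c():
    """A moderately sized simulated trial with both direct and mediated effects."""
    return lm.simulate_trial("c", lm.SimConfig(n_subjects=250), seed=42)


@pytest.fixture(scope="session")
def pace_c(trial_c):
    """Full-window PACE fit on the shared trial."""
    return lm.fit_pace(trial_c.dataset)


@pytest.fixture()
def toy_dataset():
    """Three handcrafted subjects with known trajectories and survival."""
    subjects = []
    specs = [
        ("p1", [0.0, 0.1, 0.3, 0.5], [10.0, 9.0, 8.0, 7.0], 2.0, 1, 1),
        ("p2", [0.0, 0.2, 0.4], [12.0, 11.0, 6.0], 1.5, 1, 0),
        ("p3", [0.0, 0.15, 0.6, 0.9], [8.0, 8.5, 9.0, 7.5], 3.0, 0, 1),
    ]
    for sid, t, v, ot, ev, arm in specs:
        subjects.append(
            (
                lm.SubjectTrajectory(sid, np.array(t), np.array(v)),
                lm.SurvivalRecord(sid, ot, ev, arm, np.array([v[0]]), np.array([v[0]])),
            )
        )
    return lm.TrialDataset(tuple(subjects), x_names=("x1",), z_names=("z1",))


def analytic_eigensystem(n_grid=201, lam=(4.0, 1.0), sigma2=1e-4):
    """An exactly specified eigensystem: phi1 = 1, phi2 = sqrt(3)(2t - 1).

    Both are orthonormal on [0, 1]; useful as a known truth for score and
    reconstruction oracles.
    """
    grid = np.linspace(0, 1, n_grid)
    phi1 = np.ones_like(grid)
    phi2 = np.sqrt(3.0) * (2 * grid - 1)
    return lm.EigenSystem(
        grid=grid,
        mean=np.zeros_like(grid),
        eigenfunctions=np.vstack([phi1, phi2]),
        eigenvalues=np.array(lam, dtype=float),
        noise_variance=sigma2,
        fve=np.cumsum(lam) / np.sum(lam),
    )
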