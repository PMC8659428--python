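"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy import integrate
from scipy.spatial.transform import Rotation

import comtrack as ct

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------
def procrustes_objective(rotations: np.ndarray, l0: np.ndarray, y0: np.ndarray) -> np.ndarray:
    """Direct evaluation of the centred Procrustes objective for a batch of
    rotations: sum_m || R l0_m - y0_m ||^2."""
    fitted = np.einsum("kij,mj->kmi", rotations, l0)
    return ((fitted - y0[None]) ** 2).sum(axis=(1, 2))


def brute_force_pose(local: np.ndarray, observed: np.ndarray, coarse: int = 30,
                     levels: int = 9) -> tuple[np.ndarray, np.ndarray, float]:
    """Dense rotation-space search for the rigid pose minimising the marker
    fit error. Independent of the SVD solution: rotations are enumerated on
    an Euler-angle grid and refined locally; the objective is evaluated
    directly. Returns (R, t, objective)."""
    lbar, ybar = local.mean(axis=0), observed.mean(axis=0)
    l0, y0 = local - lbar, observed - ybar
    grid1 = np.linspace(-np.pi, np.pi, coarse, endpoint=False)
    az, ay, ax = np.meshgrid(grid1, grid1, grid1, indexing="ij")
    angles = np.column_stack([az.ravel(), ay.ravel(), ax.ravel()])
    rots = Rotation.from_euler("zyx", angles).as_matrix()
    objs = procrustes_objective(rots, l0, y0)
    best = angles[int(np.argmin(objs))]
    width = 2 * np.pi / coarse
    for _ in range(levels):
        offs = np.linspace(-width, width, 11)
        dz, dy, dx = np.meshgrid(offs, offs, offs, indexing="ij")
        cand = best + np.column_stack([dz.ravel(), dy.ravel(), dx.ravel()])
        rots = Rotation.from_euler("zyx", cand).as_matrix()
        objs = procrustes_objective(rots, l0, y0)
        k = int(np.argmin(objs))
        best = cand[k]
        width /= 4.0
    r_best = Rotation.from_euler("zyx", best).as_matrix()
    t_best = ybar - r_best @ lbar
    return r_best, t_best, float(procrustes_objective(r_best[None], l0, y0)[0])


def jzs_bf10_g_oracle(t: float, n: int, r: float) -> float:
    """JZS paired Bayes factor via the Zellner-Siow g-prior integral
    (scale-inverse-chi-square mixing density), an algebraically different
    route from the package's noncentral-t/Cauchy quadrature."""
    nu = n - 1

    def integrand(g: float) -> float:
        a = 1.0 + n * g * r * r
        return (
            a**-0.5
            * (1.0 + t * t / (a * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    num, _ = integrate.quad(integrand, 0, np.inf, epsabs=0.0, epsrel=1e-10, limit=300)
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return num / den


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# shared (expensive) study fixtures, generated once per session
# ---------------------------------------------------------------------------
@pytest.fixture(scope="session")
def small_default_study():
    """Default 13x12 study at desk-scale durations, default error model."""
    config = ct.StudyConfig.default(seed=11, duration_scale=0.05, min_duration_s=5.0)
    dataset = ct.generate_study(config)
    rows, disp = ct.analyze_study(dataset)
    summary = ct.summarize_by_task(rows)
    return dataset, rows, disp, summary


@pytest.fixture(scope="session")
def identity_study():
    """Default design with an identity tracker error model, no missingness."""
    config = ct.StudyConfig.default(
        seed=7,
        duration_scale=0.05,
        min_duration_s=5.0,
        sensor_error=ct.SensorErrorModel.identity(),
        missingness=ct.MissingnessPlan(),
    )
    dataset = ct.generate_study(config)
    rows, disp = ct.analyze_study(dataset)
    return dataset, rows, disp
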