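import numpy as np
import pytest

from polyhelix.helix_model import (
    HelicalCurve,
    TraceFixtureSpec,
    generate_ideal_calphas,
)
from polyhelix.scoring import default_class_params

ALPHA_P, G310_P, PI_P = default_class_params()

CLASS_CURVES = {
    "alpha": HelicalCurve(radius=ALPHA_P.mu_r, rise=ALPHA_P.mu_p, turn=ALPHA_P.mu_t),
    "310": HelicalCurve(radius=G310_P.mu_r, rise=G310_P.mu_p, turn=G310_P.mu_t),
    "pi": HelicalCurve(radius=PI_P.mu_r, rise=PI_P.mu_p, turn=PI_P.mu_t),
}
STRAND_CURVE = HelicalCurve(radius=0.96, rise=3.34, turn=177.9)


@pytest.fixture(scope="session")
def class_curves():
    return CLASS_CURVES


@pytest.fixture(scope="session")
def strand_curve():
    return STRAND_CURVE


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def ideal_trace(curve: HelicalCurve, n: int, noise: float = 0.0, seed: int = 0):
    return generate_ideal_calphas(
        TraceFixtureSpec(curve=curve, n_residues=n, noise_sigma=noise, seed=seed)
    )


def random_rigid_motion(rng) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a translation."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.normal(scale=10.0, size=3)


def random_quadruple(rng, noise: float = 0.2) -> np.ndarray:
    """A noise-perturbed helical quadruple with random parameters/pose."""
    r = rng.uniform(1.2, 3.2)
    p = rng.uniform(0.5, 2.5)
    t = rng.uniform(60.0, 150.0)
    curve = HelicalCurve(radius=r, rise=p, turn=t)
    pts = ideal_trace(curve, 4)
    rot, trans = random_rigid_motion(rng)
    pts = pts @ rot.T + trans
    return pts + rng.normal(scale=noise, size=pts.shape)
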