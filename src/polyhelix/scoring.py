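"""Helix scores against the three standard protein helices, and thresholds.

Each helix class (α, 3₁₀, π) carries normal-distribution parameters (μ, σ)
for the fitted radius r, rise p, turn angle t and quadruple RMSD Δ, obtained
from large-scale statistics over high-resolution structures.  The (μ_r,
μ_p, μ_t) triple of a class is its *standard protein helix*.  A residue's
score for a class combines the four standardized squared deviations

    (r - μ_r)² / 2σ_r²,  (p - μ_p)² / 2σ_p²,  (t - μ_t)² / 2σ_t²,  Δ² / 2σ_Δ²

of its best-fit curve.  Three combiners are supported:

``sum`` (default)
    Σ (x − μ)²/σ², the squared-z-score (Mahalanobis) distance.  The factor
    ½ of the individual terms is dropped: with it, an exact standard
    α-helix scores 4.85 against the 3₁₀ class — below the 3₁₀ start
    threshold g_T = 6 — so the 3₁₀ pass (which precedes α) would claim
    every good α-helix.  The un-halved sum is the only combiner of these
    terms that separates all three classes at the stated thresholds.
``halfsum``
    Σ (x − μ)²/2σ², the individual terms exactly as defined, summed.
``product``
    Π (x − μ)²/2σ², the score formula read literally as a product; it
    collapses to zero whenever any single parameter hits its class mean,
    so it cannot discriminate between classes and exists only for
    fidelity experiments.

Lower score = closer to the standard helix of that class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .curve_fitting import QuadrupleFit

__all__ = [
    "HelixClassParams",
    "ScoreTriple",
    "ThresholdConfig",
    "helix_scores",
    "default_class_params",
    "standard_curve",
    "ALPHA",
    "THREE_TEN",
    "PI",
]

ALPHA = "alpha"
THREE_TEN = "310"
PI = "pi"


@dataclass(frozen=True)
class HelixClassParams:
    """Normal-distribution parameters of one helix class.

    ``mu_delta`` is stored for completeness but the Δ score term is
    Δ²/2σ_Δ² (the deviation is taken from zero, not from μ_Δ).
    """

    label: str
    mu_r: float
    sigma_r: float
    mu_p: float
    sigma_p: float
    mu_t: float
    sigma_t: float
    mu_delta: float
    sigma_delta: float

    def __post_init__(self) -> None:
        for name in ("sigma_r", "sigma_p", "sigma_t", "sigma_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ScoreTriple:
    """Per-residue scores against the α (h), 3₁₀ (g) and π standard helices."""

    h: float = math.inf
    g: float = math.inf
    pi: float = math.inf


@dataclass(frozen=True)
class ThresholdConfig:
    """The ten assignment thresholds.

    Score thresholds (dimensionless): ``h_T``/``g_T``/``pi_T`` gate the start
    and growth of α/3₁₀/π helices; ``h_max`` is the looser score bound used
    for α merging and C-terminal extension.  Axis-angle thresholds (degrees):
    ``a_T``/``a_G``/``a_I`` gate α/3₁₀/π starts; ``a_max`` bounds the local
    bend tolerated inside a merged or extended α-helix.  RMSD thresholds (Å):
    ``delta_G`` gates the two-residue 3₁₀ C-terminal extension and
    ``delta_max`` the α merge.
    """

    h_T: float = 20.0
    h_max: float = 160.0
    g_T: float = 6.0
    pi_T: float = 14.0
    a_T: float = 20.0
    a_max: float = 40.0
    a_G: float = 10.0
    a_I: float = 20.0
    delta_G: float = 0.12
    delta_max: float = 0.3

    def __post_init__(self) -> None:
        if not self.h_T < self.h_max:
            raise ValueError("require h_T < h_max")
        for name in (
            "h_T", "h_max", "g_T", "pi_T", "a_T", "a_max", "a_G", "a_I",
            "delta_G", "delta_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def with_overrides(self, **kwargs: float) -> "ThresholdConfig":
        return replace(self, **kwargs)


def default_class_params() -> tuple[HelixClassParams, HelixClassParams, HelixClassParams]:
    """The default (α, 3₁₀, π) class parameters.

    Derived from normal fits of r, p, t, Δ over dssp-labelled helices in a
    non-redundant set of high-resolution x-ray structures; the (μ_r, μ_p,
    μ_t) of each class is its standard protein helix.
    """
    alpha = HelixClassParams(
        label=ALPHA,
        mu_r=2.314, sigma_r=0.061,
        mu_p=1.516, sigma_p=0.086,
        mu_t=100.1, sigma_t=2.56,
        mu_delta=0.02, sigma_delta=0.031,
    )
    three_ten = HelixClassParams(
        label=THREE_TEN,
        mu_r=2.109, sigma_r=0.118,
        mu_p=1.829, sigma_p=0.138,
        mu_t=107.4, sigma_t=5.90,
        mu_delta=0.045, sigma_delta=0.038,
    )
    pi = HelixClassParams(
        label=PI,
        mu_r=2.779, sigma_r=0.086,
        mu_p=1.196, sigma_p=0.056,
        mu_t=82.8, sigma_t=2.80,
        mu_delta=0.129, sigma_delta=0.056,
    )
    return alpha, three_ten, pi


def _class_score(fit: QuadrupleFit, cls: HelixClassParams, combiner: str) -> float:
    half_terms = (
        (fit.r - cls.mu_r) ** 2 / (2.0 * cls.sigma_r**2),
        (fit.p - cls.mu_p) ** 2 / (2.0 * cls.sigma_p**2),
        (fit.t - cls.mu_t) ** 2 / (2.0 * cls.sigma_t**2),
        fit.delta**2 / (2.0 * cls.sigma_delta**2),
    )
    if combiner == "sum":
        return 2.0 * sum(half_terms)
    if combiner == "halfsum":
        return sum(half_terms)
    if combiner == "product":
        return half_terms[0] * half_terms[1] * half_terms[2] * half_terms[3]
    raise ValueError(f"unknown combiner {combiner!r}")


def helix_scores(
    fit: QuadrupleFit | None,
    classes: tuple[HelixClassParams, HelixClassParams, HelixClassParams] | None = None,
    combiner: str = "sum",
) -> ScoreTriple:
    """Score one quadruple fit against the three standard protein helices.

    An absent or invalid fit yields infinite scores, which fail every
    threshold test downstream.
    """
    if fit is None or not fit.valid:
        return ScoreTriple()
    if classes is None:
        classes = default_class_params()
    alpha, three_ten, pi = classes
    return ScoreTriple(
        h=_class_score(fit, alpha, combiner),
        g=_class_score(fit, three_ten, combiner),
        pi=_class_score(fit, pi, combiner),
    )


def standard_curve(label: str):
    """The standard helical curve (class-mean r, p, t) for a class label."""
    from .helix_model import HelicalCurve

    by_label = {c.label: c for c in default_class_params()}
    aliases = {"a": ALPHA, "h": ALPHA, "g": THREE_TEN, "i": PI, "p": PI}
    key = aliases.get(label.lower(), label.lower())
    if key not in by_label:
        raise ValueError(f"unknown helix class {label!r}")
    cls = by_label[key]
    return HelicalCurve(radius=cls.mu_r, rise=cls.mu_p, turn=cls.mu_t)
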