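"""Parameter calibration helpers and length-binned RMSD clustering.

The class parameters used by the scorer are normal fits (μ, σ) of helical
parameters over labelled helices; :func:`fit_normal` performs one such fit.
π-helix statistics average the (r, p, t) of the first three residues of
each helix before fitting (:func:`pi_average`).

Assigned helices of equal length can be compared structurally with a
greedy leader clustering under a Cα-RMSD threshold (default 1.5 Å): each
helix joins the first existing cluster whose representative it superposes
onto within the threshold, else it founds a new cluster.  Deterministic for
a fixed input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .curve_fitting import kabsch_superpose

__all__ = ["NormalFit", "HelixCluster", "fit_normal", "pi_average", "cluster_helices"]


@dataclass(frozen=True)
class NormalFit:
    """Sample mean and population (n-denominator) standard deviation."""

    mu: float
    sigma: float
    n_samples: int


@dataclass
class HelixCluster:
    """A leader cluster: representative coordinates plus member indices."""

    representative: np.ndarray
    members: list[int] = field(default_factory=list)
    rmsd_threshold: float = 1.5


def fit_normal(samples: Sequence[float]) -> NormalFit:
    """Fit a normal distribution by moments (population σ).

    Raises ``ValueError`` with fewer than 2 samples.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 samples")
    return NormalFit(mu=float(arr.mean()), sigma=float(arr.std(ddof=0)), n_samples=arr.size)


def pi_average(
    first_three: Sequence[tuple[float, float, float]]
) -> tuple[float, float, float]:
    """Component-wise mean of the (r, p, t) triples of a π-helix's first
    three residues."""
    triples = list(first_three)
    if len(triples) != 3:
        raise ValueError("exactly three (r, p, t) triples required")
    arr = np.asarray(triples, dtype=float)
    if arr.shape != (3, 3):
        raise ValueError("each entry must be an (r, p, t) triple")
    mean = arr.mean(axis=0)
    return (float(mean[0]), float(mean[1]), float(mean[2]))


def cluster_helices(
    helices: Sequence[np.ndarray], threshold: float = 1.5
) -> list[HelixCluster]:
    """Greedy leader clustering of equal-length Cα coordinate sets.

    Each helix (in input order) joins the first cluster whose representative
    it superposes onto within ``threshold`` Å RMSD, else founds a new
    cluster.  All coordinate sets must have the same length (≥ 3).
    """
    sets = [np.asarray(h, dtype=float) for h in helices]
    if not sets:
        return []
    n = sets[0].shape
    if any(s.shape != n for s in sets):
        raise ValueError("all coordinate sets must have equal length")
    if n[0] < 3:
        raise ValueError("coordinate sets must have >= 3 points")
    clusters: list[HelixCluster] = []
    for idx, coords in enumerate(sets):
        placed = False
        for cluster in clusters:
            _, _, rmsd = kabsch_superpose(coords, cluster.representative)
            if rmsd <= threshold or math.isinf(threshold):
                cluster.members.append(idx)
                placed = True
                break
        if not placed:
            clusters.append(
                HelixCluster(
                    representative=coords, members=[idx], rmsd_threshold=threshold
                )
            )
    return clusters
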