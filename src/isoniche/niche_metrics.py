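"""Population-year isotopic niche structure in d13C-d15N space.

Layman-style metrics summarise the cloud of territory-year observations:
isotopic ranges (CR, NR), mean distance to centroid (CD, trophic diversity)
and the SD of nearest-neighbour distances (SDNND, trophic evenness).  To
compare population-years with different territory counts, each metric is
bootstrapped at a fixed resample size (the minimum n across population-years
in the study design).  Niche width is the standard ellipse area
SEA = pi sqrt(det(Sigma)) of the sample covariance, with the small-sample
correction SEAc = SEA (n-1)/(n-2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateGeometryError, InvalidInputError

#: bootstrap defaults: replicates and the fixed resample size (minimum
#: territory count across the seven population-years of the study design)
DEFAULT_BOOTSTRAP_B = 10_000
DEFAULT_BOOTSTRAP_M = 12


class LaymanMetrics(NamedTuple):
    cr: float     # d13C range, permil
    nr: float     # d15N range, permil
    cd: float     # mean distance to centroid, permil
    sdnnd: float  # SD (population, ddof=0) of nearest-neighbour distances


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an (n, 2) array of (d13c, d15n)")
    if not np.isfinite(pts).all():
        raise InvalidInputError("points must be finite")
    return pts


def layman_metrics(points) -> LaymanMetrics:
    """CR, NR, CD and SDNND of a point cloud (needs >= 2 distinct points)."""
    pts = _as_points(points)
    n = len(pts)
    if n < 2 or np.unique(pts, axis=0).shape[0] < 2:
        raise InvalidInputError("need at least 2 distinct points")
    cr = float(np.ptp(pts[:, 0]))
    nr = float(np.ptp(pts[:, 1]))
    centroid = pts.mean(axis=0)
    cd = float(np.linalg.norm(pts - centroid, axis=1).mean())
    d = squareform(pdist(pts))
    np.fill_diagonal(d, np.inf)
    nnd = d.min(axis=1)
    sdnnd = float(np.std(nnd, ddof=0))
    return LaymanMetrics(cr, nr, cd, sdnnd)


def bootstrap_metrics(points, m: int = DEFAULT_BOOTSTRAP_M,
                      B: int = DEFAULT_BOOTSTRAP_B,
                      seed: int | np.random.Generator = 0,
                      with_replacement: bool = True) -> LaymanMetrics:
    """Bootstrapped means of the Layman metrics at fixed resample size m.

    Each of the B replicates draws one shared resample of size m (with
    replacement by default; ``with_replacement=False`` subsamples instead)
    and evaluates all four metrics on it, so the metrics of a replicate are
    mutually consistent.  Returns the mean of each metric over replicates.
    """
    pts = _as_points(points)
    n = len(pts)
    if m > n:
        raise InvalidInputError(f"resample size m={m} exceeds n={n}")
    if B < 1:
        raise InvalidInputError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if with_replacement:
        idx = rng.integers(0, n, size=(B, m))
    else:
        idx = np.array([rng.permutation(n)[:m] for _ in range(B)])
    sample = pts[idx]                            # (B, m, 2)
    cr = np.ptp(sample[:, :, 0], axis=1)
    nr = np.ptp(sample[:, :, 1], axis=1)
    cent = sample.mean(axis=1, keepdims=True)
    cd = np.linalg.norm(sample - cent, axis=2).mean(axis=1)
    diff = sample[:, :, None, :] - sample[:, None, :, :]
    d = np.linalg.norm(diff, axis=3)             # (B, m, m)
    ii = np.arange(m)
    d[:, ii, ii] = np.inf
    nnd = d.min(axis=2)
    sdnnd = nnd.std(axis=1, ddof=0)
    return LaymanMetrics(float(cr.mean()), float(nr.mean()),
                         float(cd.mean()), float(sdnnd.mean()))


@dataclass(frozen=True)
class StandardEllipse:
    """The standard ellipse of a bivariate sample.

    Boundary at Mahalanobis distance 1 from the mean under the sample
    covariance (the 1-SD ellipse), whose area is pi sqrt(det(Sigma)).
    """

    mean: tuple[float, float]
    cov: tuple[tuple[float, float], tuple[float, float]]

    @property
    def area(self) -> float:
        return float(np.pi * np.sqrt(np.linalg.det(np.asarray(self.cov))))


def fit_standard_ellipse(points) -> StandardEllipse:
    pts = _as_points(points)
    if len(pts) < 3:
        raise InvalidInputError("need at least 3 points for an ellipse")
    cov = np.cov(pts.T, ddof=1)
    if np.linalg.det(cov) <= 0:
        raise DegenerateGeometryError("singular sample covariance")
    return StandardEllipse(tuple(pts.mean(axis=0)), tuple(map(tuple, cov)))


def standard_ellipse_area(points, corrected: bool = True) -> float:
    """SEA = pi sqrt(det(Sigma_hat)); SEAc multiplies by (n-1)/(n-2)."""
    pts = _as_points(points)
    n = len(pts)
    ellipse = fit_standard_ellipse(pts)
    sea = ellipse.area
    if corrected:
        return sea * (n - 1) / (n - 2)
    return sea


def ellipse_containment(points, ellipse: StandardEllipse) -> float:
    """Fraction of points inside or on the standard ellipse.

    A point is inside when its squared Mahalanobis distance from the
    ellipse centre is <= 1.  For bivariate normal data the squared
    Mahalanobis distance is chi^2 with 2 df, so the expected fraction is
    1 - exp(-1/2) ~ 0.3935 -- the "core" ~40% of the data that the
    standard ellipse is meant to delimit.
    """
    pts = _as_points(points)
    cov = np.asarray(ellipse.cov)
    diff = pts - np.asarray(ellipse.mean)
    sol = np.linalg.solve(cov, diff.T)
    d2 = (diff.T * sol).sum(axis=0)
    return float(np.mean(d2 <= 1.0))


def niche_table(observations: pd.DataFrame,
                m: int = DEFAULT_BOOTSTRAP_M, B: int = DEFAULT_BOOTSTRAP_B,
                seed: int = 0) -> pd.DataFrame:
    """Per population-year niche summary in study-table column order.

    ``observations`` needs columns population, year, d13c_mean, d15n_mean
    (one row per territory-year).  Metrics CR/NR/CD/SDNND are bootstrapped
    at resample size ``min(m, smallest group n)``; SEAc is computed on the
    full group.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for (pop, yr), grp in observations.groupby(["population", "year"], sort=False):
        pts = grp[["d13c_mean", "d15n_mean"]].to_numpy(dtype=float)
        boot = bootstrap_metrics(pts, m=min(m, len(pts)), B=B, seed=rng)
        rows.append({
            "population": pop, "year": yr,
            "mean_d13c": pts[:, 0].mean(), "mean_d15n": pts[:, 1].mean(),
            "cr_b": boot.cr, "nr_b": boot.nr, "cd_b": boot.cd,
            "sdnnd_b": boot.sdnnd,
            "sea_c": standard_ellipse_area(pts, corrected=True),
            "n": len(pts)})
    return pd.DataFrame(rows)
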