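"""Territory-level diet indices and rank-correlation utilities.

Diet diversity is the Shannon-Weaver index H' = -sum p ln p (natural log, so
the ceiling for K = 8 prey categories is ln 8 ~ 2.079); diet specificity is
the proportional similarity PSi = 1 - 0.5 sum |p_ik - q_k| between a
territory's diet and the population mean diet q.  Both are computed on
posterior-mean diet vectors in the headline pipeline.
"""

from __future__ import annotations

import logging
import math
from itertools import permutations
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError
from .isotope_io import CATEGORIES

logger = logging.getLogger(__name__)

#: largest n for which the Spearman p-value is computed by full enumeration
EXACT_PERMUTATION_MAX_N = 9


def _check_simplex(p, name="p", tol=1e-6):
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise InvalidInputError(f"{name} must be 1-D")
    if (p < -1e-12).any():
        raise InvalidInputError(f"{name} has negative components")
    if abs(p.sum() - 1.0) > tol:
        raise InvalidInputError(f"{name} must sum to 1 (got {p.sum():.6f})")
    return np.clip(p, 0.0, None)


def shannon_diversity(p: Sequence[float]) -> float:
    """Shannon-Weaver diversity H' = -sum p ln p (nats), with 0 ln 0 := 0."""
    p = _check_simplex(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def proportional_similarity(p_i: Sequence[float], q: Sequence[float]) -> float:
    """Proportional similarity PSi = 1 - 0.5 sum_k |p_ik - q_k|, in [0, 1]."""
    p_i = _check_simplex(p_i, "p_i")
    q = _check_simplex(q, "q")
    if p_i.shape != q.shape:
        raise InvalidInputError("p_i and q must have the same length")
    return float(1.0 - 0.5 * np.abs(p_i - q).sum())


def population_mean_diet(diet_vectors) -> np.ndarray:
    """Unweighted componentwise mean of diet vectors, renormalized to 1."""
    arr = np.asarray(diet_vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.size == 0:
        raise InvalidInputError("need at least one diet vector")
    for row in arr:
        _check_simplex(row)
    q = arr.mean(axis=0)
    return q / q.sum()


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    n: int
    method: str  # "exact" or "t-approx"


def spearman(x: Sequence[float], y: Sequence[float],
             method: str = "auto") -> SpearmanResult:
    """Spearman rank correlation with an exact small-sample p-value.

    rho is the Pearson correlation of mid-ranks (average ranks for ties).
    The two-sided p-value is computed by full enumeration of all n!
    orderings for n <= 9 (counting permutations with |rho| >= |rho_obs|),
    and by the t approximation with n - 2 degrees of freedom otherwise.
    Undefined correlations (a constant argument) are reported as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise InvalidInputError("need at least 3 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        logger.warning("spearman: constant ranks, correlation undefined")
        return SpearmanResult(math.nan, math.nan, n, "undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if method == "auto":
        method = "exact" if n <= EXACT_PERMUTATION_MAX_N else "t-approx"
    if method == "exact":
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
        perms = np.array(list(permutations(range(n))))
        rhos = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho ** 2, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, min(p, 1.0), n, method)


def preferred_prey_screen(diet_table: pd.DataFrame,
                          categories: Sequence[str] = CATEGORIES,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Screen for preferred prey: per-category Spearman rho against H'.

    Higher consumption of a preferred prey is expected to reduce the
    predator's diet diversity, so categories whose consumption correlates
    significantly negatively with H' across territories are flagged as
    candidate preferred prey.

    ``diet_table`` needs one row per territory-year with columns ``p_<cat>``
    and, optionally, ``h`` (recomputed from the proportions if absent).
    """
    pcols = [f"p_{c}" for c in categories]
    missing = [c for c in pcols if c not in diet_table.columns]
    if missing:
        raise InvalidInputError(f"diet table missing columns {missing}")
    if len(diet_table) < 5:
        raise InvalidInputError("need at least 5 territories for the screen")
    if "h" in diet_table.columns:
        h = diet_table["h"].to_numpy(dtype=float)
    else:
        h = np.array([shannon_diversity(r) for r in
                      diet_table[pcols].to_numpy(dtype=float)])
    rows = []
    for cat, col in zip(categories, pcols):
        vals = diet_table[col].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            logger.warning("preferred_prey_screen: %s has constant share, "
                           "rho undefined", cat)
            rows.append((cat, math.nan, math.nan, False))
            continue
        res = spearman(vals, h)
        flagged = (not math.isnan(res.rho)) and res.rho < 0 and res.p_value < alpha
        rows.append((cat, res.rho, res.p_value, flagged))
    return pd.DataFrame(rows, columns=["category", "rho", "p_value", "preferred"])
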