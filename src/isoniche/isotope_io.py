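"""Data model and CSV I/O for feather/prey stable-isotope tables.

Conventions: comma-separated UTF-8 CSV with a header row, ``.`` decimal,
lower-snake column names.  delta values are per-mil (permil) deviations from the
international standards (PDB for carbon, atmospheric N2 for nitrogen).
Missing isotope values are rejected, never imputed: every analysis in this
package operates on complete (d13c, d15n) pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, RowError, SchemaError

logger = logging.getLogger(__name__)

#: The eight prey categories used throughout: European rabbit (OC),
#: red-legged partridge (AR), wood pigeon (CP), domestic pigeon foraging on
#: crops (CLw), domestic pigeon from dovecotes fed with corn (CLd),
#: passerines (PAS), red squirrel (SV) and ocellated lizard (TL).
CATEGORIES: tuple[str, ...] = ("OC", "AR", "CP", "CLw", "CLd", "PAS", "SV", "TL")

#: Raw prey tables may carry domestic pigeons as a single category that is
#: split into CLw/CLd by :func:`pool_sources`.
RAW_PIGEON_CATEGORY = "CL"

CONSUMER_COLUMNS = ("population", "year", "territory", "chick_id", "d13c", "d15n")
SOURCE_COLUMNS = ("category", "d13c", "d15n")
BREEDING_COLUMNS = ("population", "year", "territory", "pair_age", "replacement", "fledglings")


@dataclass(frozen=True)
class ConsumerRecord:
    """One nestling's feather isotope pair with its territory identity."""

    population: str
    year: int
    territory: str
    chick_id: str
    d13c: float
    d15n: float

    def __post_init__(self):
        if not (np.isfinite(self.d13c) and np.isfinite(self.d15n)):
            raise InvalidInputError(
                f"non-finite isotope value for chick {self.chick_id!r} "
                f"({self.population}, {self.year}, {self.territory})"
            )


@dataclass(frozen=True)
class TerritoryYearObservation:
    """Sibling-averaged isotope values for one territory in one season."""

    population: str
    year: int
    territory: str
    d13c_mean: float
    d15n_mean: float
    n_chicks: int

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.population, self.year, self.territory)


@dataclass(frozen=True)
class SourceDistribution:
    """A prey category's tissue isotope distribution plus its TDF.

    ``mu``/``omega`` are the per-isotope tissue mean/SD (d13c, d15n);
    ``tdf_mu``/``tdf_sd`` the trophic discrimination factor mean/SD applied
    when the source enters a consumer mixing model.
    """

    category: str
    mu: tuple[float, float]
    omega: tuple[float, float]
    tdf_mu: tuple[float, float]
    tdf_sd: tuple[float, float]
    n_samples: int = 0

    def __post_init__(self):
        if any(w < 0 for w in self.omega) or any(t < 0 for t in self.tdf_sd):
            raise InvalidInputError(f"negative SD in source {self.category!r}")


# ---------------------------------------------------------------------------
# delta notation
# ---------------------------------------------------------------------------

def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """delta value (permil) from a sample and standard isotope ratio.

    delta = (R_sample / R_standard - 1) * 1000.
    """
    r_sample = np.asarray(r_sample, dtype=float)
    if np.any(np.asarray(r_standard, dtype=float) <= 0):
        raise InvalidInputError("standard ratio must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def ratio_from_delta(delta: float, r_standard: float) -> float:
    """Inverse of :func:`delta_from_ratio`."""
    if np.any(np.asarray(r_standard, dtype=float) <= 0):
        raise InvalidInputError("standard ratio must be positive")
    return (np.asarray(delta, dtype=float) / 1000.0 + 1.0) * r_standard


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def _read_checked(path, required: Sequence[str], numeric: Sequence[str],
                  integer: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        logger.warning("%s: no data rows (header only)", path)

    bad: list[tuple[int, str, str]] = []
    out = df.copy()
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in np.flatnonzero(vals.isna().to_numpy()):
            # +2: header line plus 1-based numbering
            bad.append((int(idx) + 2, col, df[col].iloc[idx]))
        out[col] = vals
    if bad:
        cells = ", ".join(f"line {ln} column {c!r} value {v!r}" for ln, c, v in bad)
        raise RowError(f"{path}: unparseable numeric cells: {cells}", bad)
    for col in integer:
        out[col] = out[col].astype(int)
    return out


def load_consumers(path) -> list[ConsumerRecord]:
    """Read a consumer CSV into typed records (one row per chick)."""
    df = _read_checked(path, CONSUMER_COLUMNS, numeric=("year", "d13c", "d15n"),
                       integer=("year",))
    records = [
        ConsumerRecord(str(r.population), int(r.year), str(r.territory),
                       str(r.chick_id), float(r.d13c), float(r.d15n))
        for r in df.itertuples(index=False)
    ]
    keys = [(r.population, r.year, r.territory, r.chick_id) for r in records]
    if len(set(keys)) != len(keys):
        raise InvalidInputError(f"{path}: duplicate (population, year, territory, chick_id) keys")
    return records


def load_sources(path) -> pd.DataFrame:
    """Read a raw prey sample CSV (one row per prey individual)."""
    return _read_checked(path, SOURCE_COLUMNS, numeric=("d13c", "d15n"))


def load_breeding(path) -> pd.DataFrame:
    """Read a breeding outcome CSV (one row per successful territory-year)."""
    df = _read_checked(path, BREEDING_COLUMNS,
                       numeric=("year", "replacement", "fledglings"),
                       integer=("year", "replacement", "fledglings"))
    bad_age = ~df["pair_age"].isin(["adult", "nonadult"])
    if bad_age.any():
        raise InvalidInputError(
            f"{path}: pair_age must be 'adult' or 'nonadult', got "
            f"{sorted(df.loc[bad_age, 'pair_age'].unique())}")
    if not df["replacement"].isin([0, 1]).all():
        raise InvalidInputError(f"{path}: replacement must be 0 or 1")
    if not df["fledglings"].isin([1, 2]).all():
        raise InvalidInputError(f"{path}: fledglings must be 1 or 2")
    return df


def write_consumers(records: Iterable[ConsumerRecord], path) -> None:
    pd.DataFrame([r.__dict__ for r in records], columns=CONSUMER_COLUMNS).to_csv(
        path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# sibling aggregation
# ---------------------------------------------------------------------------

def aggregate_siblings(records: Sequence[ConsumerRecord]) -> list[TerritoryYearObservation]:
    """Collapse chicks to one observation per territory-year.

    Territories with two chicks contribute the arithmetic mean of the two
    sibling isotope pairs; single chicks pass through unchanged.  More than
    two chicks in a territory-year is rejected (broods of this species hold
    at most two fledged chicks).
    """
    by_key: dict[tuple[str, int, str], list[ConsumerRecord]] = {}
    for r in records:
        by_key.setdefault((r.population, r.year, r.territory), []).append(r)
    out = []
    for key, chicks in by_key.items():
        if len(chicks) > 2:
            raise InvalidInputError(
                f"territory-year {key} has {len(chicks)} chicks (max 2)")
        out.append(TerritoryYearObservation(
            key[0], key[1], key[2],
            float(np.mean([c.d13c for c in chicks])),
            float(np.mean([c.d15n for c in chicks])),
            len(chicks)))
    return out


def observations_to_frame(obs: Sequence[TerritoryYearObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.population, o.year, o.territory, o.d13c_mean, o.d15n_mean, o.n_chicks)
         for o in obs],
        columns=["population", "year", "territory", "d13c_mean", "d15n_mean", "n_chicks"])


# ---------------------------------------------------------------------------
# prey pooling and the domestic-pigeon split
# ---------------------------------------------------------------------------

def two_means_split_1d(values: np.ndarray) -> np.ndarray:
    """Exact 1-D two-cluster k-means.

    Returns a boolean mask that is True for members of the higher-valued
    cluster.  Because 1-D k-means clusters are contiguous in sorted order,
    scanning all n-1 split points of the sorted sequence and minimising the
    within-cluster sum of squares is exact.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise InvalidInputError("need at least 2 values to split")
    order = np.argsort(values, kind="stable")
    s = values[order]
    best_sse, best_i = np.inf, 1
    for i in range(1, n):
        lo, hi = s[:i], s[i:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best_i = sse, i
    mask = np.zeros(n, dtype=bool)
    mask[order[best_i:]] = True
    return mask


def pool_sources(samples: pd.DataFrame,
                 tdf_mu: tuple[float, float],
                 tdf_sd: tuple[float, float],
                 split_pigeons: bool = True,
                 pigeon_threshold: float | None = None,
                 require_all: bool = True) -> list[SourceDistribution]:
    """Pool raw prey samples into per-category source distributions.

    Domestic pigeons supplied as a single ``CL`` category are partitioned on
    d13c into crop-foraging birds (``CLw``, lower d13c) and dovecote birds
    fed with corn (``CLd``, higher d13c), either by an exact 1-D two-means
    split (default) or by a fixed ``pigeon_threshold`` override.  Each
    resulting category needs at least two samples so the SD is defined.
    """
    df = samples.copy()
    if split_pigeons and (df["category"] == RAW_PIGEON_CATEGORY).any():
        pig = df["category"] == RAW_PIGEON_CATEGORY
        vals = df.loc[pig, "d13c"].to_numpy(dtype=float)
        if pigeon_threshold is not None:
            high = vals >= pigeon_threshold
        else:
            high = two_means_split_1d(vals)
        labels = np.where(high, "CLd", "CLw")
        df.loc[pig, "category"] = labels

    present = set(df["category"].unique())
    unknown = present - set(CATEGORIES)
    if unknown:
        raise SchemaError(f"unknown prey categories {sorted(unknown)}")
    if require_all:
        missing = [c for c in CATEGORIES if c not in present]
        if missing:
            raise SchemaError(f"missing prey categories {missing}")

    out = []
    for cat in CATEGORIES:
        sub = df[df["category"] == cat]
        if sub.empty:
            continue
        if len(sub) < 2:
            raise InvalidInputError(
                f"category {cat!r} has {len(sub)} sample(s); need >= 2 for an SD")
        out.append(SourceDistribution(
            category=cat,
            mu=(float(sub["d13c"].mean()), float(sub["d15n"].mean())),
            omega=(float(sub["d13c"].std(ddof=1)), float(sub["d15n"].std(ddof=1))),
            tdf_mu=tuple(float(v) for v in tdf_mu),
            tdf_sd=tuple(float(v) for v in tdf_sd),
            n_samples=len(sub)))
    logger.info("pooled %d prey samples into %d categories", len(df), len(out))
    return out
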