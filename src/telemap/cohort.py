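"""Cohort filters, use rates, rurality shares, trend test, diagnosis ranking.

The descriptive layer of the analysis: visit-level claims records are
filtered to the analytic cohort (complete records, in-range years, valid
area ids), aggregated into per-area-year telehealth use rates (unique
patients over population), summarised as annual telehealth-visit shares by
rurality class, tested for a monotone trend in proportions across years,
and ranked by diagnosis code frequency.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import VISIT_COLUMNS, AreaLattice

FILTER_STAGES = ("missing_fields", "year_range", "area_validity")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention of reported tables),
    not banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Filter ledger

@dataclass
class FilterLedger:
    """Record counts through each exclusion stage (the flow-diagram table)."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_dropped: int) -> None:
        n_out = n_in - n_dropped
        if n_out < 0:
            raise ValueError(f"stage {name!r} drops more records than it receives")
        if self.stages and self.stages[-1]["records_out"] != n_in:
            raise ValueError(
                f"stage {name!r} input ({n_in}) does not equal previous stage "
                f"output ({self.stages[-1]['records_out']})"
            )
        self.stages.append(
            {"stage": name, "records_in": n_in, "records_dropped": n_dropped,
             "records_out": n_out}
        )

    @property
    def records_in(self) -> int:
        return self.stages[0]["records_in"] if self.stages else 0

    @property
    def records_out(self) -> int:
        return self.stages[-1]["records_out"] if self.stages else 0

    def dropped_at(self, stage: str) -> int:
        for s in self.stages:
            if s["stage"] == stage:
                return s["records_dropped"]
        raise KeyError(stage)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.stages, fh, indent=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def apply_cohort_filters(
    records: pd.DataFrame,
    valid_area_ids: Iterable[str],
    study_years: Iterable[int],
) -> tuple[pd.DataFrame, FilterLedger]:
    """Apply the study-population exclusions in order, with full accounting.

    Stages: (1) drop records with any missing field; (2) drop records outside
    the study years; (3) drop records whose area id is not in the valid
    frame (out-of-state or unknown areas).  The ledger conserves counts at
    every stage (in - dropped = out) and stages compose.
    """
    valid = set(map(str, valid_area_ids))
    if not valid:
        raise ValueError("valid_area_ids must be non-empty")
    years = set(int(y) for y in study_years)
    ledger = FilterLedger()

    df = records.copy()
    n0 = len(df)
    complete = df[list(VISIT_COLUMNS)].notna().all(axis=1)
    for col in ("patient_id", "area_id", "modality", "diagnosis_code"):
        complete &= df[col].astype(object).apply(lambda s: s is not None and str(s) != "")
    df = df[complete]
    ledger.add("missing_fields", n0, n0 - len(df))

    n1 = len(df)
    df = df[df["year"].astype(int).isin(years)]
    ledger.add("year_range", n1, n1 - len(df))

    n2 = len(df)
    df = df[df["area_id"].astype(str).isin(valid)]
    ledger.add("area_validity", n2, n2 - len(df))

    return df.reset_index(drop=True), ledger


# ---------------------------------------------------------------------------
# Use rates

def compute_use_rates(records: pd.DataFrame, lattice: AreaLattice) -> pd.DataFrame:
    """Telehealth use rate per area-year: unique telehealth patients over
    area population.

    A patient with many telehealth visits in an area-year counts once in
    that numerator; all lattice areas appear for every year present in the
    records (rate 0 where nobody used telehealth).
    """
    known = set(lattice.area_ids)
    seen = set(records["area_id"].astype(str))
    unknown = sorted(seen - known)
    if unknown:
        raise ValueError(f"record area id(s) not in lattice: {unknown[:5]}")
    pop = lattice.population_map()
    if any(p < 1 for p in pop.values()):
        raise ValueError("zero population area in lattice")

    tele = records[records["modality"] == "telehealth"]
    counts = (
        tele.groupby(["area_id", "year"])["patient_id"].nunique().rename("unique_telehealth_patients")
    )
    years = sorted(records["year"].astype(int).unique())
    full = pd.MultiIndex.from_product(
        [list(lattice.area_ids), years], names=["area_id", "year"]
    )
    out = counts.reindex(full, fill_value=0).reset_index()
    out["population"] = out["area_id"].map(pop)
    out["rate"] = out["unique_telehealth_patients"] / out["population"]
    return out


# ---------------------------------------------------------------------------
# Rurality shares

def shares_from_counts(
    counts: Mapping[str, int], total: int | None = None
) -> dict[str, float]:
    """Percentage shares (one decimal, half-up) from class counts.

    ``total`` defaults to the sum of the counts but can be supplied
    explicitly to reproduce a published table's printed denominator.
    """
    denom = sum(counts.values()) if total is None else total
    if denom <= 0:
        raise ValueError("total must be positive")
    return {k: round_half_up(100.0 * c / denom, 1) for k, c in counts.items()}


def rurality_shares(records: pd.DataFrame, lattice: AreaLattice) -> pd.DataFrame:
    """Annual telehealth-visit shares by rurality class.

    share(class, year) = 100 * telehealth visits in class / total telehealth
    visits that year, to one decimal.  Years present in the records but with
    zero telehealth visits are flagged with a warning and omitted (a 0/0
    share is undefined, not zero).
    """
    rmap = lattice.rurality_map()
    missing = sorted(set(records["area_id"].astype(str)) - set(rmap))
    if missing:
        raise ValueError(f"area id(s) without rurality class: {missing[:5]}")
    df = records.copy()
    df["rurality"] = df["area_id"].map(rmap)
    tele = df[df["modality"] == "telehealth"]

    rows = []
    for year in sorted(df["year"].astype(int).unique()):
        ty = tele[tele["year"] == year]
        total = len(ty)
        if total == 0:
            warnings.warn(
                f"year {year} has no telehealth visits; shares undefined",
                UserWarning, stacklevel=2)
            continue
        by_class = ty.groupby("rurality").size().to_dict()
        shares = shares_from_counts(by_class, total=total)
        for cls, cnt in sorted(by_class.items()):
            rows.append({"year": year, "rurality": cls,
                         "telehealth_visits": int(cnt), "share": shares[cls]})
    return pd.DataFrame(rows, columns=["year", "rurality", "telehealth_visits", "share"])


# ---------------------------------------------------------------------------
# Trend test

@dataclass(frozen=True)
class TrendTestResult:
    statistic: float
    p_value: float
    direction: str  # increasing | decreasing | flat

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def _ca_statistic(x: np.ndarray, n: np.ndarray, scores: np.ndarray) -> float:
    N = n.sum()
    pbar = x.sum() / N
    t = float(scores @ (x - n * pbar))
    var = pbar * (1 - pbar) * (float(n @ scores ** 2) - float(n @ scores) ** 2 / N)
    if var <= 0:
        return 0.0
    return t / np.sqrt(var)


def trend_test(
    successes_by_year: Sequence[int],
    totals_by_year: Sequence[int],
    method: str = "asymptotic",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> TrendTestResult:
    """Cochran-Armitage test for a monotone trend in annual proportions.

    Years receive equally spaced scores; the two-sided p-value comes from
    the standard-normal reference (``method='asymptotic'``) or from a
    permutation null that reallocates successes across years with totals
    fixed (``method='permutation'``, for very small counts).
    """
    x = np.asarray(successes_by_year, dtype=float)
    n = np.asarray(totals_by_year, dtype=float)
    if x.shape != n.shape or len(x) < 3:
        raise ValueError("need >= 3 years with matching successes and totals")
    if np.any(n <= 0):
        raise ValueError("every yearly total must be positive")
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("successes must lie in [0, total] for every year")
    scores = np.arange(len(x), dtype=float)

    z = _ca_statistic(x, n, scores)
    if method == "asymptotic":
        p = float(2 * stats.norm.sf(abs(z)))
    elif method == "permutation":
        # permuting individual year labels with margins fixed is equivalent to
        # a multivariate hypergeometric reallocation of the successes
        rng = np.random.default_rng(seed)
        total_succ = int(x.sum())
        ni = n.astype(int)
        exceed = 0
        for _ in range(n_permutations):
            xs = rng.multivariate_hypergeometric(ni, total_succ).astype(float)
            if abs(_ca_statistic(xs, n, scores)) >= abs(z) - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown method {method!r}")

    if z > 0:
        direction = "increasing"
    elif z < 0:
        direction = "decreasing"
    else:
        direction = "flat"
    return TrendTestResult(statistic=float(z), p_value=min(p, 1.0), direction=direction)


# ---------------------------------------------------------------------------
# Diagnosis ranking

def rank_top_diagnoses(records: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k diagnosis codes among telehealth visits, per year.

    Ranks by descending visit count within each year, breaking ties
    lexicographically on the code (so the output is deterministic).  Returns
    a long-format frame (year, diagnosis_code, count, rank); years with
    fewer than k distinct codes return all their codes, no padding.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tele = records[records["modality"] == "telehealth"]
    rows = []
    for year, grp in tele.groupby(tele["year"].astype(int)):
        counts = grp.groupby("diagnosis_code").size()
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        for rank, (code, cnt) in enumerate(ordered, start=1):
            rows.append({"year": int(year), "diagnosis_code": code,
                         "count": int(cnt), "rank": rank})
    return pd.DataFrame(rows, columns=["year", "diagnosis_code", "count", "rank"])
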