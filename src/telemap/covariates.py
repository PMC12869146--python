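"""Covariate standardization and multicollinearity screening.

Area-level covariates enter the regression standardized (mean 0, sample sd
1), so coefficients are log relative risks per 1 SD.  Before fitting, the
covariate set is screened for multicollinearity with variance inflation
factors: VIF_j = 1/(1 - R^2_j) from regressing column j on all the others,
and covariates above a threshold (5.0 by default) are removed one at a
time, worst first, recomputing after each removal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VIF_THRESHOLD = 5.0
_INF_R2 = 1.0 - 1e-12  # R^2 at or above this is treated as exact collinearity


@dataclass
class StandardizationParams:
    """Per-column (mean, sample sd) retained for back-transformation."""

    means: dict[str, float]
    sds: dict[str, float]

    def invert(self, standardized: pd.DataFrame) -> pd.DataFrame:
        out = standardized.copy()
        for col in out.columns:
            out[col] = out[col] * self.sds[col] + self.means[col]
        return out

    def coefficient_per_unit(self, name: str, beta_per_sd: float) -> float:
        """Convert a per-1-SD coefficient back to the covariate's raw units."""
        return beta_per_sd / self.sds[name]


def standardize(covariates: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Center and scale every column to mean 0, sample sd 1 (ddof=1).

    Raises on constant columns (naming them) — they carry no information and
    would divide by zero.
    """
    if covariates.columns.duplicated().any():
        dup = covariates.columns[covariates.columns.duplicated()].tolist()
        raise ValueError(f"duplicate covariate name(s): {dup}")
    if covariates.isna().any().any():
        bad = covariates.columns[covariates.isna().any()].tolist()
        raise ValueError(f"missing values in covariate(s): {bad}")
    means, sds = {}, {}
    out = covariates.astype(float).copy()
    for col in out.columns:
        mu = float(out[col].mean())
        sd = float(out[col].std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"constant covariate column {col!r} cannot be standardized")
        out[col] = (out[col] - mu) / sd
        means[col], sds[col] = mu, sd
    return out, StandardizationParams(means=means, sds=sds)


def _vif_values(X: np.ndarray) -> np.ndarray:
    """VIF per column: 1/(1-R^2) from an intercept-included regression of
    each column on the rest; exact collinearity maps to +inf."""
    n, p = X.shape
    vifs = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.hstack([ones, others])
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            vifs[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        vifs[j] = np.inf if r2 >= _INF_R2 else 1.0 / (1.0 - r2)
    return vifs


@dataclass
class VifReport:
    """Outcome of iterative VIF screening.

    ``table`` has one row per original covariate: the VIF at its final
    evaluation (the value that triggered its removal, or its VIF in the
    retained set), a retained flag, the drop reason and drop order.
    """

    table: pd.DataFrame
    threshold: float
    retained: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "threshold": self.threshold,
            "retained": list(self.retained),
            "covariates": self.table.replace({np.inf: "inf"}).to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    def __str__(self) -> str:
        lines = [f"VIF screen (threshold {self.threshold:g})"]
        for _, row in self.table.iterrows():
            mark = "kept" if row["retained"] else f"dropped ({row['drop_reason']})"
            lines.append(f"  {row['covariate']:<28s} VIF={row['vif']:8.3f}  {mark}")
        return "\n".join(lines)


def vif_screen(
    covariates: pd.DataFrame,
    threshold: float = VIF_THRESHOLD,
    priority: Sequence[str] | None = None,
) -> VifReport:
    """Iteratively remove the worst-VIF covariate until all VIFs <= threshold.

    ``priority`` orders covariates by retention preference (earlier = keep);
    it defaults to the column order, so when two covariates tie for worst
    VIF — as an exactly collinear pair always does — the later-listed one is
    dropped.  This operationalises "retain the variable with stronger
    construct validity" as an explicit user-supplied ordering rather than a
    guess.
    """
    cols = list(covariates.columns)
    if len(cols) < 2:
        raise ValueError("VIF screening needs at least 2 covariates")
    if len(covariates) <= len(cols):
        raise ValueError("need more areas (rows) than covariates for VIF screening")
    prio = list(priority) if priority is not None else cols
    unknown = set(prio) - set(cols)
    if unknown:
        raise ValueError(f"priority names not in covariates: {sorted(unknown)}")
    rank = {c: prio.index(c) if c in prio else len(prio) for c in cols}

    active = cols.copy()
    final_vif: dict[str, float] = {}
    drop_reason: dict[str, str] = {}
    drop_order: dict[str, int] = {}
    step = 0
    while len(active) >= 2:
        X = covariates[active].to_numpy(dtype=float)
        vifs = _vif_values(X)
        worst = float(np.max(vifs))
        if worst <= threshold:
            for c, vif in zip(active, vifs):
                final_vif[c] = float(vif)
            break
        # ties (including several +inf) broken by retention priority:
        # among the worst offenders, drop the lowest-priority column
        tied = [c for c, vif in zip(active, vifs)
                if vif == worst or (np.isinf(vif) and np.isinf(worst))]
        victim = max(tied, key=lambda c: rank[c])
        step += 1
        final_vif[victim] = worst
        drop_reason[victim] = (
            "exact collinearity" if np.isinf(worst) else f"VIF {worst:.3f} > {threshold:g}"
        )
        drop_order[victim] = step
        active.remove(victim)
    else:
        # down to a single covariate: VIF is undefined/1 by convention
        final_vif.setdefault(active[0], 1.0)

    rows = []
    for c in cols:
        rows.append({
            "covariate": c,
            "vif": final_vif.get(c, np.nan),
            "retained": c in active,
            "drop_reason": drop_reason.get(c, ""),
            "drop_order": drop_order.get(c, 0),
        })
    return VifReport(table=pd.DataFrame(rows), threshold=threshold,
                     retained=tuple(c for c in cols if c in active))
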