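"""Synthetic claims/census structure for small-area telehealth analysis.

Real inputs for this kind of study are an all-payer claims extract (visit
level: patient, area, year, modality, diagnosis) and census-style area
tables (population, standardized socioeconomic covariates, rurality class).
Neither is public, so every downstream stage is exercised on simulated data
with the same statistical structure: a polygon lattice of areas, spatially
correlated (intrinsic CAR) and unstructured random effects, Poisson outcome
counts with a log-population offset, and visit-level records that aggregate
back to those counts exactly — including a controllable fraction of invalid
records to exercise the cohort filters.

The generated truth (beta, u, v, tau) is stored on the panel so parameter
recovery can be measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box, mapping

from .bym_model import RURALITY_CLASSES, AreaYearPanel
from .geo_adjacency import AdjacencyMatrix, connected_components, queen_adjacency

VISIT_COLUMNS = ("patient_id", "area_id", "year", "modality", "diagnosis_code")
MODALITIES = ("telehealth", "in_person")

#: A small ICD-10-like catalogue of primary-care codes used by default.
DEFAULT_ICD_CATALOG = (
    "I10", "E78.5", "E11.9", "F41.9", "F32.9", "J06.9", "M54.5",
    "K21.9", "E03.9", "Z00.00", "U07.1", "Z20.828",
)


@dataclass
class AreaLattice:
    """Planar areas standing in for ZCTAs: id, polygon, population, rurality."""

    area_ids: list[str]
    polygons: list[Polygon]
    population: np.ndarray
    rurality: list[str]

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=int)
        n = len(self.area_ids)
        if len(set(self.area_ids)) != n:
            raise ValueError("area ids must be unique")
        if len(self.polygons) != n or len(self.rurality) != n or len(self.population) != n:
            raise ValueError("all lattice fields must have one entry per area")
        if np.any(self.population < 1):
            raise ValueError("population must be >= 1 in every area")
        for aid, poly in zip(self.area_ids, self.polygons):
            if not poly.is_valid or poly.is_empty:
                raise ValueError(f"invalid polygon for area {aid!r}")
        bad = [r for r in self.rurality if r not in RURALITY_CLASSES]
        if bad:
            raise ValueError(f"unknown rurality class(es) {sorted(set(bad))!r}")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def rurality_map(self) -> dict[str, str]:
        return dict(zip(self.area_ids, self.rurality))

    def population_map(self) -> dict[str, int]:
        return {a: int(p) for a, p in zip(self.area_ids, self.population)}

    # -- I/O ---------------------------------------------------------------
    def to_geojson(self, path: str | Path) -> None:
        features = []
        for aid, poly, pop, rur in zip(
            self.area_ids, self.polygons, self.population, self.rurality
        ):
            features.append({
                "type": "Feature",
                "properties": {
                    "area_id": aid,
                    "population": int(pop),
                    "rurality": rur,
                },
                "geometry": mapping(poly),
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "AreaLattice":
        from shapely.geometry import shape

        with open(path) as fh:
            doc = json.load(fh)
        ids, polys, pops, rur = [], [], [], []
        for feat in doc["features"]:
            props = feat["properties"]
            ids.append(str(props["area_id"]))
            polys.append(shape(feat["geometry"]))
            pops.append(int(props["population"]))
            rur.append(props["rurality"])
        return cls(area_ids=ids, polygons=polys, population=np.array(pops), rurality=rur)

    def area_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "area_id": self.area_ids,
            "population": self.population,
            "rurality": self.rurality,
        })


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated study year.

    Defaults define the standard simulation conditions used throughout the
    test battery: a 20x20 lattice (400 areas), two covariates with
    log-relative-risks (0.3, -0.2) per 1 SD, intercept log(0.05) (a 5%
    baseline annual telehealth-use rate), random-effect precisions
    tau_u = tau_v = 4 (marginal sd ~ 0.5), area populations uniform on
    [500, 20000], and ~30% of all visits delivered by telehealth.
    """

    n_rows: int = 20
    n_cols: int = 20
    beta0: float = float(np.log(0.05))
    beta: tuple[float, ...] = (0.3, -0.2)
    tau_u: float = 4.0
    tau_v: float = 4.0
    population_range: tuple[int, int] = (500, 20000)
    telehealth_share: float = 0.3
    covariate_correlation: float = 0.0
    mean_visits_per_patient: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.tau_u <= 0 or self.tau_v <= 0:
            raise ValueError("precisions must be strictly positive")
        if not (0.0 <= self.telehealth_share <= 1.0):
            raise ValueError("telehealth_share must lie in [0, 1]")
        lo, hi = self.population_range
        if lo < 1 or hi < lo:
            raise ValueError("population_range must satisfy 1 <= min <= max")
        if not (-1.0 < self.covariate_correlation < 1.0):
            raise ValueError("covariate_correlation must lie in (-1, 1)")
        if self.mean_visits_per_patient < 1:
            raise ValueError("mean_visits_per_patient must be >= 1")


@dataclass
class EffectVector:
    """A structured spatial effect on the log-rate scale.

    Sums to zero within every connected component of the adjacency graph —
    the identifiability constraint of the intrinsic CAR distribution.
    """

    values: np.ndarray
    component_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.component_labels = np.asarray(self.component_labels, dtype=int)
        if self.values.shape != self.component_labels.shape:
            raise ValueError("values and component_labels must align")
        for c in np.unique(self.component_labels):
            s = self.values[self.component_labels == c].sum()
            if abs(s) > 1e-8:
                raise ValueError(f"component {c} violates sum-to-zero (sum={s:.3g})")


def generate_grid_lattice(
    n_rows: int,
    n_cols: int,
    seed: int,
    population_range: tuple[int, int] = (500, 20000),
) -> AreaLattice:
    """Rectangular lattice of unit-square areas.

    Populations are drawn uniformly from ``population_range``.  Rurality is
    assigned by row banding — rows are split into three horizontal bands,
    top-to-bottom city / suburban_town / rural — so all three classes occur
    whenever ``n_rows >= 3`` and assignment is deterministic given the grid.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = population_range
    ids, polys, rur = [], [], []
    for r in range(n_rows):
        band = (3 * r) // n_rows
        for c in range(n_cols):
            ids.append(f"A{r * n_cols + c:04d}")
            polys.append(box(c, r, c + 1, r + 1))
            rur.append(RURALITY_CLASSES[band])
    pops = rng.integers(lo, hi + 1, size=n_rows * n_cols)
    return AreaLattice(area_ids=ids, polygons=polys, population=pops, rurality=rur)


def simulate_icar_effects(
    adjacency: AdjacencyMatrix | np.ndarray,
    tau_u: float,
    seed: int | np.random.Generator,
) -> EffectVector:
    """Exact draw from the intrinsic CAR distribution with precision tau_u.

    The ICAR precision matrix is tau_u * L with L the graph Laplacian, which
    is rank-deficient (null space = component indicators).  A draw is built
    in the Laplacian eigenbasis: independent N(0, 1/(tau_u * lambda_k))
    coefficients on every eigendirection with lambda_k > 0, which lies in
    the per-component sum-to-zero subspace by construction.  Isolated areas
    get effect 0.
    """
    if isinstance(adjacency, np.ndarray):
        adjacency = AdjacencyMatrix.from_matrix(adjacency)  # validates symmetry
    if tau_u <= 0:
        raise ValueError("tau_u must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comps = connected_components(adjacency)
    n = adjacency.n_areas
    L = np.diag(adjacency.degrees.astype(float)) - adjacency.to_sparse().toarray()
    lam, vec = np.linalg.eigh(L)
    keep = lam > 1e-9 * max(1.0, float(lam.max(initial=1.0)))
    z = rng.standard_normal(int(keep.sum()))
    u = vec[:, keep] @ (z / np.sqrt(tau_u * lam[keep]))
    # exact recentring per component kills residual numerical drift
    for c in range(comps.n_components):
        idx = comps.members(c)
        u[idx] -= u[idx].mean()
    return EffectVector(values=u, component_labels=comps.labels)


def simulate_area_panel(
    lattice: AreaLattice,
    config: SimulationConfig,
    covariate_names: Sequence[str],
    adjacency: AdjacencyMatrix | None = None,
    year: int = 2020,
    rng: np.random.Generator | None = None,
) -> AreaYearPanel:
    """Simulate one study year of area-level outcome counts.

    Covariates are drawn (optionally equicorrelated) and standardized to
    sample mean 0 / sd 1; the linear predictor is
    eta_i = beta0 + x_i' beta + u_i + v_i with an ICAR draw u and iid normal
    v; counts are Y_i ~ Poisson(pop_i * exp(eta_i)).  The generating truth
    is attached to the returned panel.
    """
    if len(covariate_names) != len(config.beta):
        raise ValueError(
            f"{len(covariate_names)} covariate names but beta has "
            f"{len(config.beta)} entries"
        )
    rng = rng or np.random.default_rng(config.seed)
    n = lattice.n_areas
    p = len(config.beta)
    adjacency = adjacency or queen_adjacency(lattice)

    if p:
        rho = config.covariate_correlation
        cov = np.full((p, p), rho) + (1 - rho) * np.eye(p)
        X = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    else:
        X = np.zeros((n, 0))

    u = simulate_icar_effects(adjacency, config.tau_u, rng).values
    v = rng.standard_normal(n) / np.sqrt(config.tau_v)
    beta = np.asarray(config.beta, dtype=float)
    eta = config.beta0 + (X @ beta if p else 0.0) + u + v
    y = rng.poisson(lattice.population * np.exp(eta))

    return AreaYearPanel(
        area_ids=list(lattice.area_ids),
        y=y.astype(np.int64),
        offset=lattice.population.astype(float),
        X=X,
        covariate_names=tuple(covariate_names),
        year=year,
        truth={
            "beta0": config.beta0,
            "beta": beta.copy(),
            "u": u.copy(),
            "v": v.copy(),
            "tau_u": config.tau_u,
            "tau_v": config.tau_v,
        },
    )


def _year_icd_weights(year: int, n_codes: int) -> np.ndarray:
    """Deterministic year-dependent code weights: geometric profile whose
    ranking rotates with the year, so top-k tables differ across years."""
    ranks = (np.arange(n_codes) + year) % n_codes
    w = 0.75 ** ranks
    return w / w.sum()


def simulate_visit_records(
    panel: AreaYearPanel,
    config: SimulationConfig,
    icd_catalog: Sequence[str] = DEFAULT_ICD_CATALOG,
    invalid_fraction: float = 0.0,
    icd_weights: Mapping[int, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Visit-level records whose telehealth patients reproduce the panel.

    Every area gets exactly ``panel.y[i]`` distinct telehealth patients (ids
    are deterministic functions of area, year and index); each makes
    1 + Poisson(mean_visits_per_patient - 1) telehealth visits.  In-person
    visits are added so that telehealth makes up about
    ``config.telehealth_share`` of all visits.  Diagnosis codes are drawn
    from a year-dependent weight table.  Finally, an iid
    Bernoulli(``invalid_fraction``) subset of records has its area id
    corrupted (blanked or set to an out-of-frame id) to exercise the cohort
    validity filters.

    Returns a DataFrame with columns ``VISIT_COLUMNS``.
    """
    if not icd_catalog:
        raise ValueError("icd_catalog must be non-empty")
    if not (0.0 <= invalid_fraction <= 1.0):
        raise ValueError("invalid_fraction must lie in [0, 1]")
    rng = rng or np.random.default_rng(config.seed + 1)
    year = panel.year if panel.year is not None else 0
    codes = np.asarray(icd_catalog, dtype=object)
    if icd_weights is not None and year in icd_weights:
        w = np.asarray(icd_weights[year], dtype=float)
        w = w / w.sum()
    else:
        w = _year_icd_weights(year, len(codes))

    extra_mean = config.mean_visits_per_patient - 1.0
    share = config.telehealth_share

    pid, aid, modal = [], [], []
    for i, area in enumerate(panel.area_ids):
        k = int(panel.y[i])
        visits_per_patient = 1 + rng.poisson(extra_mean, size=k)
        n_tele = int(visits_per_patient.sum())
        for j in range(k):
            patient = f"{area}-y{year}-p{j:05d}"
            reps = int(visits_per_patient[j])
            pid.extend([patient] * reps)
            aid.extend([area] * reps)
        modal.extend(["telehealth"] * n_tele)
        # in-person volume keeps telehealth at ~`share` of all visits
        if share <= 0:
            n_inp = 0 if n_tele == 0 else int(rng.poisson(10 * max(n_tele, 1)))
        elif share >= 1:
            n_inp = 0
        else:
            n_inp = int(rng.poisson(n_tele * (1 - share) / share)) if n_tele else 0
        for j in range(n_inp):
            pid.append(f"{area}-y{year}-q{j:05d}")
            aid.append(area)
        modal.extend(["in_person"] * n_inp)

    m = len(pid)
    records = pd.DataFrame({
        "patient_id": pid,
        "area_id": aid,
        "year": np.full(m, year, dtype=int),
        "modality": modal,
        "diagnosis_code": rng.choice(codes, size=m, p=w) if m else np.array([], dtype=object),
    })

    if invalid_fraction > 0 and m:
        bad = rng.random(m) < invalid_fraction
        blank = rng.random(m) < 0.5
        records.loc[bad & blank, "area_id"] = None
        records.loc[bad & ~blank, "area_id"] = "ZZ-INVALID"

    return records[list(VISIT_COLUMNS)]


# ---------------------------------------------------------------------------
# Serialisation of simulation products

def write_truth(panel: AreaYearPanel, path: str | Path) -> None:
    if panel.truth is None:
        raise ValueError("panel carries no stored truth")
    t = panel.truth
    doc = {
        "beta0": float(t["beta0"]),
        "beta": np.asarray(t["beta"]).tolist(),
        "u": np.asarray(t["u"]).tolist(),
        "v": np.asarray(t["v"]).tolist(),
        "tau_u": float(t["tau_u"]),
        "tau_v": float(t["tau_v"]),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def write_visit_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_visit_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "area_id": str,
                                  "modality": str, "diagnosis_code": str})
    df["year"] = df["year"].astype(int)
    return df[list(VISIT_COLUMNS)]
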