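"""Queen-contiguity neighbourhood graphs over area polygons.

The spatial prior on area-level random effects needs a symmetric binary
neighbour relation: two areas are neighbours when their polygons share at
least one boundary point (an edge *or* a corner — "queen" contiguity, by
analogy with chess moves).  This module builds that graph from shapely
polygons, labels its connected components (needed to impose the
sum-to-zero identifiability constraint of the intrinsic CAR prior per
component), and reads/writes the standard interchange formats.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _cc
from shapely import STRtree
from shapely.geometry import shape as _shape
from shapely.geometry.base import BaseGeometry

DEFAULT_TOLERANCE = 1e-9  # coordinate units; absorbs GeoJSON round-trip jitter


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric binary contiguity graph over ``n_areas`` areas.

    ``pairs`` holds each unordered neighbour pair exactly once as
    ``(i, j)`` with ``i < j`` in 0-based area order.
    """

    n_areas: int
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        seen = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.n_areas):
                raise ValueError(
                    f"invalid neighbour pair ({i}, {j}) for {self.n_areas} areas; "
                    "pairs must satisfy 0 <= i < j < n_areas (no self-neighbours)"
                )
            if (i, j) in seen:
                raise ValueError(f"duplicate neighbour pair ({i}, {j})")
            seen.add((i, j))

    @classmethod
    def from_pairs(cls, n_areas: int, pairs: Iterable[tuple[int, int]]) -> "AdjacencyMatrix":
        """Build from any iterable of (possibly unordered) index pairs."""
        norm = sorted({(min(i, j), max(i, j)) for i, j in pairs})
        return cls(n_areas=n_areas, pairs=tuple(norm))

    @classmethod
    def from_matrix(cls, w: np.ndarray) -> "AdjacencyMatrix":
        w = np.asarray(w)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(w, w.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("adjacency matrix must have a zero diagonal")
        ii, jj = np.nonzero(np.triu(w, k=1))
        return cls(n_areas=w.shape[0], pairs=tuple(zip(ii.tolist(), jj.tolist())))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_areas, dtype=int)
        for i, j in self.pairs:
            d[i] += 1
            d[j] += 1
        return d

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two int arrays (each unordered pair once).

        Cached: the conversion is hot inside MCMC sweeps.
        """
        cached = self.__dict__.get("_edge_arrays")
        if cached is None:
            if not self.pairs:
                cached = (np.empty(0, dtype=int), np.empty(0, dtype=int))
            else:
                arr = np.asarray(self.pairs, dtype=int)
                cached = (arr[:, 0], arr[:, 1])
            object.__setattr__(self, "_edge_arrays", cached)
        return cached

    def to_sparse(self) -> sp.csr_matrix:
        ei, ej = self.edge_arrays()
        data = np.ones(2 * len(ei))
        rows = np.concatenate([ei, ej])
        cols = np.concatenate([ej, ei])
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n_areas, self.n_areas))

    def neighbor_lists(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_areas)]
        for i, j in self.pairs:
            out[i].append(j)
            out[j].append(i)
        return [sorted(v) for v in out]


@dataclass(frozen=True)
class ComponentLabels:
    """Connected-component labelling: contiguous integer ids from 0."""

    labels: np.ndarray
    n_components: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.size and (lab.min() != 0 or lab.max() != self.n_components - 1):
            raise ValueError("component labels must be contiguous integers from 0")

    def members(self, component: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == component)


def _polygons_of(lattice_or_polygons) -> tuple[Sequence[BaseGeometry], Sequence[str]]:
    if hasattr(lattice_or_polygons, "polygons"):
        polys = lattice_or_polygons.polygons
        ids = list(getattr(lattice_or_polygons, "area_ids", range(len(polys))))
    else:
        polys = list(lattice_or_polygons)
        ids = [str(k) for k in range(len(polys))]
    return polys, [str(a) for a in ids]


def queen_adjacency(lattice, tolerance: float = DEFAULT_TOLERANCE) -> AdjacencyMatrix:
    """Queen-contiguity graph: areas sharing any boundary point are neighbours.

    Parameters
    ----------
    lattice
        An object with ``polygons`` (and optionally ``area_ids``) attributes,
        or a plain sequence of shapely polygons.
    tolerance
        Two polygons within this distance of each other are treated as
        touching.  Nonnegative; the default absorbs coordinate jitter from
        GeoJSON round trips.

    Returns
    -------
    AdjacencyMatrix
        Symmetric, zero-diagonal.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    polys, ids = _polygons_of(lattice)
    for poly, aid in zip(polys, ids):
        if poly is None or poly.is_empty or not poly.is_valid:
            raise ValueError(f"invalid polygon for area {aid!r}")
    tree = STRtree(polys)
    pairs: set[tuple[int, int]] = set()
    for i, poly in enumerate(polys):
        if tolerance > 0:
            hits = tree.query(poly, predicate="dwithin", distance=tolerance)
        else:
            hits = tree.query(poly, predicate="intersects")
        for j in np.asarray(hits, dtype=int):
            if j != i:
                pairs.add((min(i, int(j)), max(i, int(j))))
    return AdjacencyMatrix(n_areas=len(polys), pairs=tuple(sorted(pairs)))


def connected_components(adjacency: AdjacencyMatrix) -> ComponentLabels:
    """Label graph components; isolated areas become singleton components."""
    if adjacency.n_areas == 0:
        return ComponentLabels(labels=np.empty(0, dtype=int), n_components=0)
    n_comp, labels = _cc(adjacency.to_sparse(), directed=False)
    # relabel so ids are contiguous in first-appearance order (scipy already
    # returns contiguous labels, but the order is an implementation detail)
    order = {int(l): k for k, l in enumerate(dict.fromkeys(labels.tolist()))}
    labels = np.array([order[int(l)] for l in labels], dtype=int)
    return ComponentLabels(labels=labels, n_components=n_comp)


def permute_adjacency(adjacency: AdjacencyMatrix, perm: Sequence[int]) -> AdjacencyMatrix:
    """Relabel areas: new index ``perm[i]`` corresponds to old index ``i``."""
    perm = list(perm)
    if sorted(perm) != list(range(adjacency.n_areas)):
        raise ValueError("perm must be a permutation of range(n_areas)")
    return AdjacencyMatrix.from_pairs(
        adjacency.n_areas, [(perm[i], perm[j]) for i, j in adjacency.pairs]
    )


# ---------------------------------------------------------------------------
# I/O

def write_edge_list(adjacency: AdjacencyMatrix, path: str | Path) -> None:
    """Two-column CSV of 0-based area indices, one unordered pair per row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["area_i", "area_j"])
        for i, j in adjacency.pairs:
            writer.writerow([i, j])


def read_edge_list(path: str | Path, n_areas: int) -> AdjacencyMatrix:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["area_i", "area_j"]:
            raise ValueError(f"unexpected edge-list header {header!r}")
        pairs = [(int(row[0]), int(row[1])) for row in reader if row]
    return AdjacencyMatrix.from_pairs(n_areas, pairs)


def write_matrix_market(adjacency: AdjacencyMatrix, path: str | Path) -> None:
    sp_mat = adjacency.to_sparse()
    from scipy.io import mmwrite

    mmwrite(str(path), sp_mat)


def read_geojson_polygons(path: str | Path) -> tuple[list[str], list[BaseGeometry]]:
    """Read a GeoJSON FeatureCollection; returns (area ids, shapely polygons).

    The area id is taken from the feature property ``area_id`` (falling back
    to ``id``), else the feature index.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    ids: list[str] = []
    polys: list[BaseGeometry] = []
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        ids.append(str(props.get("area_id", feat.get("id", k))))
        polys.append(_shape(feat["geometry"]))
    return ids, polys


def queen_adjacency_from_geojson(
    path: str | Path, tolerance: float = DEFAULT_TOLERANCE
) -> tuple[list[str], AdjacencyMatrix]:
    ids, polys = read_geojson_polygons(path)

    class _Frame:
        area_ids = ids
        polygons = polys

    return ids, queen_adjacency(_Frame, tolerance=tolerance)
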