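"""Isolation-by-distance analysis and mother-infant strain transmission.

Geographic separations between subspecies' representative locations are
approximated as great-circle distances on a sphere (optionally routed
through waypoints, e.g. forcing an overland path); a Mantel permutation
test relates them to genetic distances. Transmission between related
sample pairs is called by thresholding normalized genetic distances
(nGD, patristic distance over the tree's median branch length) at the
first percentile of the unrelated-pair distribution, which fixes the
false discovery rate at ~1%.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeoPoint",
    "EARTH_RADIUS_KM",
    "great_circle_km",
    "geographic_distance_matrix",
    "mantel_test",
    "ngd_from_tree",
    "transmission_threshold",
    "transmission_rate",
]

EARTH_RADIUS_KM = 6_371.0088


@dataclass
class GeoPoint:
    label: str
    latitude: float
    longitude: float
    waypoints: list["GeoPoint"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


def _haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def great_circle_km(
    p1: GeoPoint,
    p2: GeoPoint,
    waypoints: Sequence[GeoPoint] | None = None,
) -> float:
    """Haversine great-circle distance in km, summed over waypoint legs
    when a via-route is given (e.g. a path across a land bridge)."""
    route = [p1, *(waypoints or []), p2]
    return sum(
        _haversine_km(a.latitude, a.longitude, b.latitude, b.longitude)
        for a, b in zip(route[:-1], route[1:])
    )


def geographic_distance_matrix(
    points: Sequence[GeoPoint],
    waypoint_routes: Mapping[tuple[str, str], Sequence[GeoPoint]] | None = None,
) -> DistanceMatrix:
    """Pairwise great-circle distances, honoring per-pair waypoint routes
    keyed by (label_a, label_b) in either order."""
    routes = dict(waypoint_routes or {})
    n = len(points)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (points[i].label, points[j].label)
            way = routes.get(key) or routes.get(key[::-1])
            d = great_circle_km(points[i], points[j], way)
            out[i, j] = out[j, i] = d
    return DistanceMatrix([p.label for p in points], out)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("zero variance in distance matrix entries")
    return float((a * b).sum() / denom)


def mantel_test(
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    n_perm: int = 9999,
    method: str = "pearson",
    seed: int = 0,
    exact_max_n: int = 7,
) -> tuple[float, float]:
    """One-sided Mantel test for positive association of two distance
    matrices.

    r is the Pearson (or Spearman) correlation of the upper-triangle
    entries; p = (1 + #{permuted r >= observed}) / (1 + N) over random
    relabelings of one matrix. For n <= ``exact_max_n`` all n!
    permutations are enumerated instead and p is the exact tail
    proportion.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError("method must be 'pearson' or 'spearman'")
    if set(m1.labels) != set(m2.labels):
        raise ValueError("matrices cover different label sets")
    m2 = m2.reorder(m1.labels)
    n = len(m1.labels)
    if n < 3:
        raise ValueError("need at least 3 labels")
    iu = np.triu_indices(n, k=1)
    x = m1.values[iu]
    y = m2.values[iu]
    if method == "spearman":
        from scipy.stats import rankdata

        x = rankdata(x)
        y = rankdata(y)
    r_obs = _pearson(x, y)
    vals2 = m2.values

    def perm_r(order: np.ndarray) -> float:
        permuted = vals2[np.ix_(order, order)][iu]
        if method == "spearman":
            from scipy.stats import rankdata

            permuted = rankdata(permuted)
        return _pearson(x, permuted)

    if n <= exact_max_n:
        count = 0
        total = 0
        for order in permutations(range(n)):
            total += 1
            if perm_r(np.asarray(order)) >= r_obs - 1e-12:
                count += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if perm_r(rng.permutation(n)) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


def ngd_from_tree(
    tree: dendropy.Tree | str,
    pairs: Sequence[tuple[str, str]],
) -> dict[tuple[str, str], float]:
    """Patristic distance per pair, normalized by the median branch
    length over all edges of the tree."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    edge_lengths = [
        e.length for e in tree.preorder_edge_iter() if e.length is not None
    ]
    if not edge_lengths:
        raise ValueError("tree has no branch lengths")
    median_branch = float(np.median(edge_lengths))
    if median_branch <= 0:
        raise ValueError("median branch length is zero")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        if a not in taxa or b not in taxa:
            missing = [x for x in (a, b) if x not in taxa]
            raise KeyError(f"pair members not leaves of tree: {missing}")
        out[(a, b)] = pdm.patristic_distance(taxa[a], taxa[b]) / median_branch
    return out


def transmission_threshold(
    unrelated_ngds: Sequence[float],
    percentile: float = 1.0,
    interpolation: str = "linear",
) -> float:
    """nGD threshold at the given percentile of the unrelated-pair
    distribution (linear interpolation between order statistics by
    default), so that ~percentile% of unrelated pairs fall below it."""
    values = np.asarray(unrelated_ngds, dtype=float)
    if values.size < 100:
        logger.warning(
            "only %d unrelated nGD values; percentile threshold unstable",
            values.size,
        )
    if values.size == 0:
        raise ValueError("no unrelated nGD values")
    return float(np.percentile(values, percentile, method=interpolation))


def transmission_rate(
    pair_records: pd.DataFrame,
    threshold: float,
) -> float:
    """Fraction of related dyads sharing a strain at >= 1 timepoint.

    ``pair_records`` needs columns (sample_a, sample_b, relationship,
    ngd); rows with relationship 'mother-infant' are grouped into dyads
    by the (sample_a, sample_b) pair, and a dyad transmits when any of
    its timepoints has nGD below the threshold.
    """
    related = pair_records[pair_records.relationship == "mother-infant"]
    if related.empty:
        raise ValueError("no evaluable pairs")
    dyads = related.groupby(["sample_a", "sample_b"])["ngd"]
    transmitted = (dyads.min() < threshold).sum()
    return float(transmitted / dyads.ngroups)
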