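"""Subspecies delineation and abundance estimation.

Delineation uses partitioning around medoids (PAM, deterministic BUILD
initialization followed by best-improvement SWAP) on a genetic distance
matrix, with the optimal cluster number chosen by the prediction-strength
statistic: repeatedly split the data in half, cluster both halves, and
measure how well the training medoids predict the co-membership of test
pairs. Subspecies-diagnostic single-nucleotide variants (alignment
columns whose base is common inside one subspecies and rare outside it)
then support estimating per-sample subspecies relative abundances from
read pileups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import CoreAlignment, DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringResult",
    "SNVPanel",
    "AbundanceEstimate",
    "pam_cluster",
    "prediction_strength",
    "select_k",
    "density_balanced_subsample",
    "assign_to_medoids",
    "derive_subspecies_snvs",
    "estimate_subspecies_abundance",
]


@dataclass
class ClusteringResult:
    k: int
    medoids: list[str]
    labels: dict[str, int]  # genome -> medoid index
    objective: float


@dataclass
class SNVPanel:
    """Per-subspecies diagnostic (column, base) pairs on a core alignment."""

    positions: dict[str, list[tuple[int, str]]]
    in_frac: float = 0.9
    out_frac: float = 0.9

    def __post_init__(self) -> None:
        seen: dict[tuple[int, str], str] = {}
        for sub, sites in self.positions.items():
            for col, base in sites:
                key = (col, base)
                if key in seen and seen[key] != sub:
                    raise ValueError(
                        f"column {col} base {base} diagnostic for both "
                        f"{seen[key]} and {sub}"
                    )
                seen[key] = sub

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sub, col, base)
            for sub, sites in self.positions.items()
            for col, base in sites
        ]
        return pd.DataFrame(rows, columns=["subspecies", "column", "base"])


@dataclass
class AbundanceEstimate:
    abundances: dict[str, float | None]
    qc_flags: list[str]

    @property
    def passed(self) -> bool:
        return not self.qc_flags


def _pam_build(dist: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD initialization: first medoid minimizes total distance,
    each next maximizes the reduction of the objective."""
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    nearest = dist[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - dist, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        c = int(np.argmax(gains))
        medoids.append(c)
        nearest = np.minimum(nearest, dist[:, c])
    return medoids


def _pam_swap(dist: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Best-improvement SWAP until a local optimum."""
    n = dist.shape[0]
    medoids = list(medoids)
    while True:
        cols = dist[:, medoids]
        objective = cols.min(axis=1).sum()
        best_delta = -1e-12
        best_swap: tuple[int, int] | None = None
        non_medoids = [i for i in range(n) if i not in set(medoids)]
        if not non_medoids:
            return medoids, float(objective)
        for mi, m in enumerate(medoids):
            others = np.delete(cols, mi, axis=1)
            d_without = (
                others.min(axis=1) if others.size else np.full(n, np.inf)
            )
            cand_costs = np.minimum(
                d_without[:, None], dist[:, non_medoids]
            ).sum(axis=0)
            ci = int(np.argmin(cand_costs))
            delta = cand_costs[ci] - objective
            if delta < best_delta:
                best_delta = delta
                best_swap = (mi, non_medoids[ci])
        if best_swap is None:
            return medoids, float(objective)
        medoids[best_swap[0]] = best_swap[1]


def pam_cluster(
    dist: DistanceMatrix, k: int, seed: int = 0, n_restarts: int = 8
) -> ClusteringResult:
    """Partitioning around medoids on a distance matrix.

    Deterministic BUILD + SWAP; the objective (sum of distances to the
    nearest medoid) never increases across swaps and each run stops at a
    local optimum. Because best-improvement SWAP can occasionally stall
    short of the global optimum, ``n_restarts`` additional SWAP runs from
    seeded random initializations are performed and the best local
    optimum kept; the result is deterministic given the seed.
    """
    n = len(dist.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    medoid_idx, objective = _pam_swap(dist.values, _pam_build(dist.values, k))
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        init = list(rng.choice(n, size=k, replace=False))
        cand, cand_obj = _pam_swap(dist.values, init)
        if cand_obj < objective - 1e-15:
            medoid_idx, objective = cand, cand_obj
    assignment = np.argmin(dist.values[:, medoid_idx], axis=1)
    labels = {dist.labels[i]: int(assignment[i]) for i in range(n)}
    return ClusteringResult(
        k=k,
        medoids=[dist.labels[m] for m in medoid_idx],
        labels=labels,
        objective=objective,
    )


def _ps_one_division(
    dist: np.ndarray, k: int, rng: np.random.Generator
) -> float:
    """Prediction strength of one random half/half train-test division."""
    n = dist.shape[0]
    perm = rng.permutation(n)
    half = n // 2
    train, test = perm[:half], perm[half:]
    if len(train) < k or len(test) < k:
        raise ValueError(f"halves too small for k={k}")
    train_medoids, _ = _pam_swap(dist[np.ix_(train, train)], _pam_build(dist[np.ix_(train, train)], k))
    test_medoids, _ = _pam_swap(dist[np.ix_(test, test)], _pam_build(dist[np.ix_(test, test)], k))
    # test points: own clustering vs classification by training medoids
    test_labels = np.argmin(dist[np.ix_(test, test)][:, test_medoids], axis=1)
    train_global = train[train_medoids]
    transferred = np.argmin(dist[np.ix_(test, train_global)], axis=1)
    worst = 1.0
    for cluster in range(k):
        members = np.flatnonzero(test_labels == cluster)
        if members.size < 2:
            continue
        agree = 0
        total = 0
        for a, b in combinations(members, 2):
            total += 1
            if transferred[a] == transferred[b]:
                agree += 1
        worst = min(worst, agree / total)
    return worst


def prediction_strength(
    dist: DistanceMatrix,
    k_range: Sequence[int],
    n_subsamples: int = 50,
    internal_divisions: int = 20,
    subsample_rate: float = 0.5,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Prediction-strength distributions over random subsamples.

    For each subsample (each genome kept independently with probability
    ``subsample_rate``), the prediction strength at k is the mean over
    ``internal_divisions`` random 50/50 train/test splits of the minimum,
    over test clusters, of the fraction of within-cluster test pairs that
    the training medoids co-assign. k = 1 is 1 by definition. Returns
    ``{k: array of per-subsample means}``.
    """
    rng = np.random.default_rng(seed)
    n = len(dist.labels)
    out: dict[int, list[float]] = {k: [] for k in k_range}
    for _ in range(n_subsamples):
        keep = np.flatnonzero(rng.random(n) < subsample_rate)
        while keep.size < max(max(k_range) * 4, 8):
            keep = np.flatnonzero(rng.random(n) < subsample_rate)
        sub = dist.values[np.ix_(keep, keep)]
        for k in k_range:
            if k == 1:
                out[k].append(1.0)
                continue
            vals = [
                _ps_one_division(sub, k, rng) for _ in range(internal_divisions)
            ]
            out[k].append(float(np.mean(vals)))
    return {k: np.asarray(v) for k, v in out.items()}


def select_k(ps: Mapping[int, np.ndarray], cutoff: float = 0.8) -> int:
    """Largest k whose mean prediction strength exceeds the cutoff."""
    passing = [k for k, v in ps.items() if float(np.mean(v)) > cutoff]
    if not passing:
        raise ValueError(f"no k with mean prediction strength > {cutoff}")
    return max(passing)


def density_balanced_subsample(
    genome_groups: Mapping[str, str],
    subsample_groups: Sequence[str],
    rate: float = 0.5,
    seed: int = 0,
) -> list[str]:
    """Downsample listed (oversampled) groups to ``rate``; keep the rest.

    Evens out sample density before clustering so that PAM, which
    minimizes total distance to medoids, does not over-split dense clouds
    contributed by heavily sampled regions.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate outside [0, 1]")
    rng = np.random.default_rng(seed)
    targeted = set(subsample_groups)
    kept = []
    for genome in genome_groups:  # insertion order for reproducibility
        if genome_groups[genome] in targeted:
            if rng.random() < rate:
                kept.append(genome)
        else:
            kept.append(genome)
    return kept


def assign_to_medoids(
    dist_to_medoids: pd.DataFrame, medoids: Sequence[str]
) -> dict[str, str]:
    """Nearest-medoid labels; ties break to the lowest medoid id."""
    medoids = list(medoids)
    missing = [m for m in medoids if m not in dist_to_medoids.columns]
    if missing:
        raise ValueError(f"distances missing for medoids {missing}")
    labels: dict[str, str] = {}
    for genome, row in dist_to_medoids[medoids].iterrows():
        best = min(medoids, key=lambda m: (row[m], m))
        ties = [m for m in medoids if row[m] == row[best]]
        if len(ties) > 1:
            logger.info("genome %s equidistant to medoids %s; chose %s",
                        genome, ties, best)
        labels[str(genome)] = best
    return labels


def derive_subspecies_snvs(
    aln: CoreAlignment,
    labels: Mapping[str, str],
    in_frac: float = 0.9,
    out_frac: float = 0.9,
) -> SNVPanel:
    """Diagnostic alleles: base frequency > in_frac within a subspecies
    and < 1 - out_frac pooled across all other subspecies. Columns with
    gaps or N anywhere are skipped (diagnostic alleles must map onto
    unambiguous consensus coordinates)."""
    missing = [l for l in aln.labels if l not in labels]
    if missing:
        raise ValueError(f"labels missing for genomes {missing[:5]}")
    mat = aln.as_matrix()
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    clean_cols = np.flatnonzero(np.isin(mat, base_codes).all(axis=0))
    groups = sorted(set(labels[l] for l in aln.labels))
    idx_of = {g: [i for i, l in enumerate(aln.labels) if labels[l] == g] for g in groups}
    positions: dict[str, list[tuple[int, str]]] = {g: [] for g in groups}
    for g in groups:
        inside = mat[np.ix_(idx_of[g], clean_cols)]
        outside_rows = [i for i in range(len(aln.labels)) if i not in set(idx_of[g])]
        outside = mat[np.ix_(outside_rows, clean_cols)]
        for b_i, code in enumerate(base_codes):
            f_in = (inside == code).mean(axis=0)
            f_out = (outside == code).mean(axis=0) if len(outside_rows) else np.zeros(clean_cols.size)
            ok = (f_in > in_frac) & (f_out < 1.0 - out_frac)
            for col in clean_cols[ok]:
                positions[g].append((int(col), "ACGT"[b_i]))
    for g in groups:
        positions[g].sort()
        if not positions[g]:
            raise ValueError(f"no diagnostic positions for subspecies {g}")
    return SNVPanel(positions=positions, in_frac=in_frac, out_frac=out_frac)


def estimate_subspecies_abundance(
    column_counts: pd.DataFrame,
    panel: SNVPanel,
    min_mean_depth: float = 5.0,
    min_breadth: float = 0.75,
    breadth_depth: int = 3,
    sum_lo: float = 0.75,
    sum_hi: float = 1.25,
) -> AbundanceEstimate:
    """Subspecies relative abundances from diagnostic-allele coverage.

    ``column_counts`` holds per-core-alignment-column base counts with
    columns (column, A, C, G, T). Per subspecies, the estimate is the
    median over its panel positions (restricted to positions with nonzero
    total depth) of diagnostic-allele depth / total depth. The sample is
    rejected (all-null abundances plus qc flags) when the mean depth over
    all panel positions is < ``min_mean_depth``, when fewer than
    ``min_breadth`` of panel positions are covered >= ``breadth_depth``
    times, or when the raw estimates sum outside [sum_lo, sum_hi];
    otherwise estimates are rescaled to sum to 1.
    """
    counts = column_counts.set_index("column")[["A", "C", "G", "T"]]
    all_positions = sorted(
        {col for sites in panel.positions.values() for col, _ in sites}
    )
    missing = [c for c in all_positions if c not in counts.index]
    if missing:
        raise ValueError(f"pileup lacks panel columns {missing[:5]}")
    depth = counts.sum(axis=1)
    panel_depth = depth.loc[all_positions]
    flags: list[str] = []
    if panel_depth.mean() < min_mean_depth:
        flags.append("depth")
    if (panel_depth >= breadth_depth).mean() < min_breadth:
        flags.append("breadth")
    raw: dict[str, float] = {}
    for sub, sites in panel.positions.items():
        ratios = []
        for col, base in sites:
            d = depth.loc[col]
            if d > 0:
                ratios.append(counts.loc[col, base] / d)
        raw[sub] = float(np.median(ratios)) if ratios else np.nan
    total = float(np.nansum(list(raw.values())))
    if not flags and not sum_lo <= total <= sum_hi:
        flags.append("sum-range")
    if flags:
        return AbundanceEstimate(
            abundances={s: None for s in panel.positions}, qc_flags=flags
        )
    return AbundanceEstimate(
        abundances={s: (v / total if np.isfinite(v) else None) for s, v in raw.items()},
        qc_flags=[],
    )
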