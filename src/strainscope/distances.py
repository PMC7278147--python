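"""Core-gene definition, genetic and gene-content distances, functional
divergence rates, and differential prevalence testing."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CoreAlignment",
    "DistanceMatrix",
    "define_core_genes",
    "hamming_distance",
    "jaccard_gene_distance",
    "functional_divergence_rate",
    "differential_prevalence",
    "one_sample_per_subject",
]

_ALPHABET = set("ACGTN-")


@dataclass
class CoreAlignment:
    """Equal-length nucleotide rows over a shared genome set."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"unequal row lengths {sorted(lengths)}")
        for label, seq in zip(self.labels, self.sequences):
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"row {label}: illegal symbols {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.labels)

    def as_matrix(self) -> np.ndarray:
        """Rows as a byte matrix for vectorized column comparisons."""
        return np.frombuffer(
            "".join(s.upper() for s in self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.sequences), -1)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])


def define_core_genes(presence: pd.DataFrame, threshold: float = 0.95) -> list[str]:
    """Genes present in at least ``threshold`` of genomes (counts>0 = present)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    frac = (presence > 0).mean(axis=1)
    return list(presence.index[frac >= threshold])


def hamming_distance(aln: CoreAlignment, ignore_gaps: bool = True) -> DistanceMatrix:
    """Pairwise mismatch fraction over the concatenated alignment.

    With ``ignore_gaps`` (the default and the intended semantics), any
    column with a gap or N in either row of a pair is excluded from both
    numerator and denominator; N is treated as gap-equivalent because
    both are non-informative.
    """
    if len(aln) < 2:
        raise ValueError("need at least two rows")
    mat = aln.as_matrix()
    informative = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    n = len(aln)
    out = np.zeros((n, n))
    for i in range(n):
        rows_j = mat[i + 1 :]
        if ignore_gaps:
            ok = informative[i] & informative[i + 1 :]
        else:
            ok = np.ones_like(rows_j, dtype=bool)
        comparable = ok.sum(axis=1)
        mism = ((rows_j != mat[i]) & ok).sum(axis=1)
        for off, (c, m) in enumerate(zip(comparable, mism)):
            j = i + 1 + off
            if c == 0:
                raise ValueError(
                    f"no comparable columns between {aln.labels[i]} "
                    f"and {aln.labels[j]}"
                )
            out[i, j] = out[j, i] = m / c
    return DistanceMatrix(list(aln.labels), out)


def jaccard_gene_distance(
    presence: pd.DataFrame, excluded_genes: Iterable[str] = ()
) -> DistanceMatrix:
    """1 - |intersection| / |union| of binary gene sets, after removing
    ``excluded_genes`` (e.g. motility operon genes) from the matrix."""
    excluded = set(excluded_genes)
    unknown = excluded - set(presence.index)
    if unknown:
        raise ValueError(f"excluded genes not in matrix: {sorted(unknown)[:5]}")
    reduced = (presence.drop(index=list(excluded)) > 0).to_numpy()
    genomes = list(presence.columns)
    n = len(genomes)
    inter = reduced.T.astype(int) @ reduced.astype(int)
    sizes = reduced.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(genomes, dist)


def functional_divergence_rate(
    d_gene: DistanceMatrix,
    d_genetic: DistanceMatrix,
    labels: Mapping[str, str],
) -> pd.DataFrame:
    """Gene-content distance over genetic distance for inter-group pairs.

    Returns one row per inter-subspecies genome pair with the pair's
    subspecies combination, both distances, and their ratio. Pairs with
    zero genetic distance are skipped with a log message.
    """
    d_gene = d_gene.reorder(d_genetic.labels)
    rows = []
    names = d_genetic.labels
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            if labels[a] == labels[b]:
                continue
            dg = d_genetic.values[i, j]
            dj = d_gene.values[i, j]
            if dg == 0:
                logger.warning("zero genetic distance for inter pair (%s, %s); "
                               "skipped", a, b)
                continue
            pair = tuple(sorted((labels[a], labels[b])))
            rows.append((a, b, f"{pair[0]}|{pair[1]}", dj, dg, dj / dg))
    return pd.DataFrame(
        rows,
        columns=["genome_a", "genome_b", "subspecies_pair", "d_gene", "d_genetic", "rate"],
    )


def differential_prevalence(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    correction: str = "BH",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests per feature between two groups.

    ``counts`` is feature x genome (copy numbers); ``groups`` assigns each
    genome column to one of exactly two group labels. P-values use the
    exact rank-sum null when group sizes permit (scipy's exact method,
    automatic for small samples without ties) and the tie-corrected
    normal approximation otherwise. Effect is mean(group1) - mean(group2)
    with groups ordered lexicographically. Correction: 'BH'
    (Benjamini-Hochberg FDR) or 'Bonferroni'.
    """
    if correction not in {"BH", "Bonferroni"}:
        raise ValueError("correction must be 'BH' or 'Bonferroni'")
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValueError(f"need exactly two groups, got {group_names}")
    g1 = [c for c in counts.columns if groups.get(c) == group_names[0]]
    g2 = [c for c in counts.columns if groups.get(c) == group_names[1]]
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    pvals, effects = [], []
    x = counts[g1].to_numpy(dtype=float)
    y = counts[g2].to_numpy(dtype=float)
    small = max(len(g1), len(g2)) <= 10
    for k in range(len(counts)):
        if np.ptp(np.concatenate([x[k], y[k]])) == 0:
            pvals.append(1.0)
        else:
            res = stats.mannwhitneyu(
                x[k],
                y[k],
                alternative="two-sided",
                method="exact" if small else "asymptotic",
            )
            pvals.append(float(min(1.0, res.pvalue)))
        effects.append(float(x[k].mean() - y[k].mean()))
    pvals_arr = np.asarray(pvals)
    method = "fdr_bh" if correction == "BH" else "bonferroni"
    reject, qvals, *_ = multipletests(pvals_arr, alpha=alpha, method=method)
    return pd.DataFrame(
        {
            "feature": counts.index,
            "effect": effects,
            "p": pvals_arr,
            "q": qvals,
            "significant": reject,
        }
    ).set_index("feature")


def one_sample_per_subject(
    sample_subjects: Mapping[str, str], seed: int = 0
) -> list[str]:
    """Pick one sample per subject uniformly at random (dedup helper for
    feature testing across longitudinally sampled individuals)."""
    rng = np.random.default_rng(seed)
    by_subject: dict[str, list[str]] = {}
    for sample, subject in sample_subjects.items():
        by_subject.setdefault(subject, []).append(sample)
    chosen = []
    for subject in sorted(by_subject):
        samples = sorted(by_subject[subject])
        chosen.append(samples[int(rng.integers(len(samples)))])
    return chosen
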