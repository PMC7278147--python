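"""Quality control of reconstructed genomes.

Covers a simplified single-copy-marker completeness/contamination
estimator (an external CheckM summary can be parsed instead), the
polymorphism-based strain-heterogeneity statistic rho, the high-quality
genome classification rule, and the species-presence rule used for
prevalence analyses.

The heterogeneity statistic flags bins that mix reads from more than one
strain: per coding position the dominant and second-dominant alleles are
called from a quality-filtered pileup, the two implied gene sequences are
translated, and rho is the fraction of covered codons at which the two
translations differ. Single-strain samples give rho near zero; a 50/50
two-strain mixture recovers the strains' non-synonymous divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import align
from .binning import GenomeBin

logger = logging.getLogger(__name__)

__all__ = [
    "QCMetrics",
    "SiteCall",
    "estimate_completeness_contamination",
    "call_sites",
    "heterogeneity_rate",
    "classify_hq",
    "species_presence",
    "read_checkm_table",
]

_BASE_ORDER = ("A", "C", "G", "T")


@dataclass
class QCMetrics:
    completeness: float  # percent
    contamination: float  # percent
    genome_size: int
    n_contigs: int
    heterogeneity_rate: float  # fraction in [0, 1]
    n_rrna: int = 0  # informational only, never a filter

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"completeness {self.completeness} outside [0,100]")
        if self.contamination < 0.0:
            raise ValueError(f"negative contamination {self.contamination}")
        if not 0.0 <= self.heterogeneity_rate <= 1.0:
            raise ValueError(f"heterogeneity {self.heterogeneity_rate} outside [0,1]")


@dataclass
class SiteCall:
    gene_id: str
    position: int
    dominant_base: str
    second_base: str
    dominant_fraction: float
    depth: int
    is_variant: bool


def estimate_completeness_contamination(
    bin_: GenomeBin,
    marker_set: Mapping[str, str],
    min_identity: float = 95.0,
    min_length_fraction: float = 0.75,
) -> tuple[float, float]:
    """Single-copy-marker completeness/contamination of a bin.

    A marker is detected where it hits a bin contig over at least 75% of
    its length at >= 95% identity. Completeness is the percentage of
    markers found at least once; contamination the percentage of extra
    copies (a marker seen m times adds m - 1 extra copies).
    """
    if not marker_set:
        raise ValueError("empty marker set")
    if not bin_.contigs:
        return 0.0, 0.0
    hits = align.align_all(dict(marker_set), bin_.contigs)
    copies: dict[str, int] = {m: 0 for m in marker_set}
    for marker_id, marker_seq in marker_set.items():
        marker_hits = [
            h
            for h in hits
            if h.query_id == marker_id
            and h.percent_identity >= min_identity
            and h.alignment_length >= min_length_fraction * len(marker_seq)
        ]
        # one copy per distinct locus: dedupe hits overlapping on the query
        loci: list[tuple[str, int, int]] = []
        for h in sorted(marker_hits, key=lambda x: -x.bit_score):
            s_lo, s_hi = sorted((h.subject_start, h.subject_end))
            overlapping = any(
                sub == h.subject_id and s_lo < hi and s_hi > lo
                for sub, lo, hi in loci
            )
            if not overlapping:
                loci.append((h.subject_id, s_lo, s_hi))
        copies[marker_id] = len(loci)
    n = len(marker_set)
    found = sum(1 for c in copies.values() if c >= 1)
    extra = sum(max(0, c - 1) for c in copies.values())
    return 100.0 * found / n, 100.0 * extra / n


def read_checkm_table(path: str | Path) -> pd.DataFrame:
    """Parse a CheckM tab-separated summary into (bin, completeness,
    contamination); accepted as an alternative estimate source."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().replace(" ", "_"): c for c in df.columns}
    needed = {"bin_id", "completeness", "contamination"}
    if not needed <= set(cols):
        raise ValueError(f"CheckM table {path} lacks columns {needed - set(cols)}")
    out = df[[cols["bin_id"], cols["completeness"], cols["contamination"]]].copy()
    out.columns = ["bin_id", "completeness", "contamination"]
    return out


def call_sites(
    pileup: pd.DataFrame,
    min_depth: int = 10,
    dominant_cutoff: float = 0.8,
) -> list[SiteCall]:
    """Dominant/second-dominant allele calls from a base-count pileup.

    Positions below ``min_depth`` are excluded; a retained position is a
    variant iff the dominant allele constitutes no more than
    ``dominant_cutoff`` of its counted bases. Exact count ties are broken
    lexicographically (A < C < G < T) for determinism.
    """
    calls: list[SiteCall] = []
    counts = pileup[list(_BASE_ORDER)].to_numpy(dtype=np.int64)
    depth = counts.sum(axis=1)
    order = np.argsort(-counts, axis=1, kind="stable")  # stable => lexicographic ties
    for i in range(len(pileup)):
        d = int(depth[i])
        if d < min_depth:
            continue
        top, second = order[i, 0], order[i, 1]
        dom_frac = counts[i, top] / d
        calls.append(
            SiteCall(
                gene_id=str(pileup.iloc[i]["gene_id"]),
                position=int(pileup.iloc[i]["pos"]),
                dominant_base=_BASE_ORDER[top],
                second_base=_BASE_ORDER[second],
                dominant_fraction=float(dom_frac),
                depth=d,
                is_variant=bool(dom_frac <= dominant_cutoff),
            )
        )
    return calls


def heterogeneity_rate(
    calls: Sequence[SiteCall],
    gene_lengths: Mapping[str, int],
    denominator: str = "codons",
) -> float:
    """Strain-heterogeneity rho from per-site allele calls.

    Builds, per gene, the dominant sequence and the second-dominant
    sequence (differing only at variant sites), translates both in frame
    from the gene start, and returns non-synonymous codons divided by
    codons fully covered by retained positions. ``denominator='positions'``
    divides by retained nucleotide positions instead.
    """
    if denominator not in {"codons", "positions"}:
        raise ValueError("denominator must be 'codons' or 'positions'")
    by_gene: dict[str, list[SiteCall]] = {}
    for c in calls:
        by_gene.setdefault(c.gene_id, []).append(c)
    ns_codons = 0
    covered_codons = 0
    covered_positions = 0
    for gene_id, gene_calls in by_gene.items():
        length = gene_lengths.get(gene_id)
        if length is None:
            raise KeyError(f"unknown gene {gene_id}")
        n_codons = length // 3
        if length % 3:
            logger.warning("gene %s length %d not divisible by 3; trailing "
                           "bases ignored", gene_id, length)
        dom = ["N"] * length
        sec = ["N"] * length
        for c in sorted(gene_calls, key=lambda x: x.position):
            if not 0 <= c.position < length:
                raise ValueError(f"position {c.position} outside gene {gene_id}")
            dom[c.position] = c.dominant_base
            sec[c.position] = c.second_base if c.is_variant else c.dominant_base
        covered_positions += sum(1 for b in dom if b != "N")
        for ci in range(n_codons):
            cod_d = "".join(dom[3 * ci : 3 * ci + 3])
            cod_s = "".join(sec[3 * ci : 3 * ci + 3])
            if "N" in cod_d:
                continue
            covered_codons += 1
            if cod_d != cod_s and str(Seq(cod_d).translate()) != str(
                Seq(cod_s).translate()
            ):
                ns_codons += 1
    denom = covered_codons if denominator == "codons" else covered_positions
    return ns_codons / denom if denom else 0.0


# high-quality genome rule: completeness > 90%, contamination < 5%,
# 2.9 Mb < size < 3.89 Mb (95% of smallest / 105% of largest isolate
# genome), < 400 contigs, heterogeneity < 0.3%
_DEFAULT_SIZE_RANGE = (2_900_000, 3_890_000)


def classify_hq(
    metrics: QCMetrics,
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
    size_range: tuple[int, int] = _DEFAULT_SIZE_RANGE,
    max_contigs: int = 400,
    max_heterogeneity: float = 0.003,
) -> tuple[bool, list[str]]:
    """Pass/fail against the high-quality genome thresholds, with reasons."""
    reasons: list[str] = []
    if not metrics.completeness > min_completeness:
        reasons.append("completeness")
    if not metrics.contamination < max_contamination:
        reasons.append("contamination")
    if not size_range[0] < metrics.genome_size < size_range[1]:
        reasons.append("size")
    if not metrics.n_contigs < max_contigs:
        reasons.append("contigs")
    if not metrics.heterogeneity_rate < max_heterogeneity:
        reasons.append("heterogeneity")
    return (not reasons), reasons


def species_presence(
    relative_abundance: float,
    marker_hit_fraction: float,
    min_abundance: float = 0.001,
    min_marker_fraction: float = 0.2,
) -> bool:
    """Species counted present iff abundance > 0.1% and >= 20% of its
    marker genes are hit."""
    if not 0.0 <= relative_abundance <= 1.0:
        raise ValueError("relative_abundance outside [0, 1]")
    if not 0.0 <= marker_hit_fraction <= 1.0:
        raise ValueError("marker_hit_fraction outside [0, 1]")
    return relative_abundance > min_abundance and (
        marker_hit_fraction >= min_marker_fraction
    )
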