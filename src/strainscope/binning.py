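"""Reference-based contig binning and spike-in threshold tuning.

A contig is assigned to the target species when it aligns against the
conspecific reference set with a length-weighted mean identity of at
least ``min_identity`` over at least ``min_fraction`` of its length.
Because a contig commonly attracts several overlapping hits (multiple
conspecific references, repeated loci), evidence is aggregated by greedy
interval union: hits are taken in descending bit-score order, their query
intervals trimmed against what earlier hits already cover, and identity
averaged over the kept segment lengths. Hits against all references are
pooled, not per-genome, since the references are one species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import AlignmentHit
from .simulate import Assembly

logger = logging.getLogger(__name__)

__all__ = [
    "ContigAssignmentEvidence",
    "GenomeBin",
    "BinningEvaluation",
    "aggregate_contig_evidence",
    "bin_contigs",
    "evaluate_binning",
    "tune_parameters",
    "remove_low_coverage_contigs",
]


@dataclass
class ContigAssignmentEvidence:
    contig_id: str
    mean_identity: float  # length-weighted %, over merged segments
    fraction_aligned: float  # merged aligned bases / contig length
    best_subject_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_aligned <= 1.0:
            raise ValueError(f"fraction_aligned {self.fraction_aligned} outside [0,1]")
        if not 0.0 <= self.mean_identity <= 100.0:
            raise ValueError(f"mean_identity {self.mean_identity} outside [0,100]")


@dataclass
class GenomeBin:
    bin_id: str
    contigs: dict[str, str]
    coverage: dict[str, float]

    @property
    def size(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)


@dataclass
class BinningEvaluation:
    fp_bases: int
    fn_bases: int
    fp_scaled: float
    fn_scaled: float
    params: tuple[float, float]  # (identity, fraction)


def _interval_subtract(
    interval: tuple[int, int], covered: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Parts of ``interval`` not overlapped by any interval in ``covered``."""
    pieces = [interval]
    for lo, hi in covered:
        next_pieces = []
        for a, b in pieces:
            if hi <= a or lo >= b:
                next_pieces.append((a, b))
                continue
            if a < lo:
                next_pieces.append((a, lo))
            if hi < b:
                next_pieces.append((hi, b))
        pieces = next_pieces
        if not pieces:
            break
    return pieces


def aggregate_contig_evidence(
    hits: Sequence[AlignmentHit], contig_length: int
) -> ContigAssignmentEvidence:
    """Merge a contig's hits into one (identity, fraction) evidence pair.

    Greedy by descending bit score (ties: lower E-value, then input
    order); each hit contributes only the query bases not already covered
    by higher-scoring hits, and identity is the mean over kept segment
    lengths.
    """
    if contig_length <= 0:
        raise ValueError("contig_length must be positive")
    if not hits:
        return ContigAssignmentEvidence("", 0.0, 0.0, None)
    contig_ids = {h.query_id for h in hits}
    if len(contig_ids) != 1:
        raise ValueError(f"hits span multiple contigs: {sorted(contig_ids)}")
    order = sorted(
        range(len(hits)), key=lambda i: (-hits[i].bit_score, hits[i].e_value, i)
    )
    covered: list[tuple[int, int]] = []
    weighted = 0.0
    total = 0
    best_subject = hits[order[0]].subject_id
    for i in order:
        h = hits[i]
        kept = _interval_subtract(h.query_interval, covered)
        for a, b in kept:
            weighted += h.percent_identity * (b - a)
            total += b - a
            covered.append((a, b))
    mean_identity = weighted / total if total else 0.0
    return ContigAssignmentEvidence(
        contig_id=hits[0].query_id,
        mean_identity=mean_identity,
        fraction_aligned=min(1.0, total / contig_length),
        best_subject_id=best_subject,
    )


def bin_contigs(
    assembly: Assembly,
    evidence: Mapping[str, ContigAssignmentEvidence],
    min_identity: float = 95.0,
    min_fraction: float = 0.5,
    bin_id: str = "bin",
) -> GenomeBin:
    """Keep exactly the contigs meeting both decision thresholds."""
    kept: dict[str, str] = {}
    coverage: dict[str, float] = {}
    for name, seq in assembly.contigs.items():
        ev = evidence.get(name)
        if ev is None:
            continue
        if ev.mean_identity >= min_identity and ev.fraction_aligned >= min_fraction:
            kept[name] = seq
            if name in assembly.coverage:
                coverage[name] = assembly.coverage[name]
    return GenomeBin(bin_id=bin_id, contigs=kept, coverage=coverage)


def evaluate_binning(
    binned: GenomeBin,
    truth: Mapping[str, str],
    assembly: Assembly,
    avg_ref_genome_size: float,
) -> BinningEvaluation:
    """FP = background bases binned; FN = spiked bases left unbinned.

    Scaled values divide by the average reference genome size so that an
    error of 1.0 corresponds to a whole genome's worth of bases.
    """
    if avg_ref_genome_size <= 0:
        raise ValueError("avg_ref_genome_size must be positive")
    fp = fn = 0
    for name, seq in assembly.contigs.items():
        label = truth.get(name)
        if label is None:
            raise ValueError(f"contig {name} lacks a truth label")
        in_bin = name in binned.contigs
        if label == "background" and in_bin:
            fp += len(seq)
        elif label == "spike" and not in_bin:
            fn += len(seq)
    return BinningEvaluation(
        fp_bases=fp,
        fn_bases=fn,
        fp_scaled=fp / avg_ref_genome_size,
        fn_scaled=fn / avg_ref_genome_size,
        params=(float("nan"), float("nan")),
    )


def tune_parameters(
    spiked: Sequence[tuple[Assembly, Mapping[str, ContigAssignmentEvidence]]],
    identity_grid: Sequence[float],
    fraction_grid: Sequence[float],
    avg_ref_genome_size: float,
) -> dict:
    """Median scaled FP/FN per (identity, fraction) grid cell.

    The selected cell minimizes max(median FP, median FN); ties break
    toward higher identity, then higher fraction, for specificity.
    """
    if not spiked or not identity_grid or not fraction_grid:
        raise ValueError("need at least one spiked assembly and non-empty grids")
    surface: dict[tuple[float, float], tuple[float, float]] = {}
    for ident in identity_grid:
        for frac in fraction_grid:
            fps, fns = [], []
            for assembly, evidence in spiked:
                b = bin_contigs(assembly, evidence, ident, frac)
                ev = evaluate_binning(b, assembly.truth, assembly, avg_ref_genome_size)
                fps.append(ev.fp_scaled)
                fns.append(ev.fn_scaled)
            surface[(ident, frac)] = (float(np.median(fps)), float(np.median(fns)))
    best = min(
        surface.items(), key=lambda kv: (max(kv[1]), -kv[0][0], -kv[0][1])
    )
    return {"surface": surface, "selected": best[0], "selected_medians": best[1]}


def remove_low_coverage_contigs(
    bin_: GenomeBin, min_fraction_of_median: float = 0.2
) -> GenomeBin:
    """Drop contigs below 20% of the median genome-wide coverage.

    The median is the unweighted per-contig median, computed before any
    removal.
    """
    if not bin_.contigs:
        return bin_
    missing = [c for c in bin_.contigs if c not in bin_.coverage]
    if missing:
        raise ValueError(f"contigs without coverage: {missing[:5]}")
    median = float(np.median([bin_.coverage[c] for c in bin_.contigs]))
    cutoff = min_fraction_of_median * median
    kept = {c: s for c, s in bin_.contigs.items() if bin_.coverage[c] >= cutoff}
    return GenomeBin(
        bin_id=bin_.bin_id,
        contigs=kept,
        coverage={c: bin_.coverage[c] for c in kept},
    )
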