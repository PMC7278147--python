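"""Detection of mobile and deletable genomic elements: motility operons
and the glycosyltransferase-enriched genomic island.

Operon gene presence is called from filtered alignment hits of reference
gene sequences; operons can also be located physically by finding their
two bordering genes on one contig. The genomic island is detected from a
seed sequence (full call = a single hit covering >= 95% of the seed),
delimited by scanning outward from the insertion for the first genes
orthologous between island-bearing and island-free genomes, and profiled
for its GC signature with a rolling window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import align
from .distances import CoreAlignment, hamming_distance
from .geo import mantel_test
from .io import AlignmentHit

logger = logging.getLogger(__name__)

__all__ = [
    "OperonModel",
    "IslandCall",
    "detect_operon_genes",
    "operon_presence_matrix",
    "flag_lacking",
    "locate_operon_by_borders",
    "gc_profile",
    "extract_island",
    "discover_island_boundaries",
    "compare_island_core",
]


@dataclass
class OperonModel:
    """A reference operon: ordered gene sequences plus bordering genes."""

    operon_id: str
    genes: dict[str, str]  # ordered gene_id -> reference sequence
    border_upstream: tuple[str, str]  # (gene_id, sequence)
    border_downstream: tuple[str, str]
    reference_length: int  # bases spanned on the reference genome
    reference_cds_count: int

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("operon must contain at least one gene")
        if self.border_upstream[0] in self.genes or (
            self.border_downstream[0] in self.genes
        ):
            raise ValueError("bordering genes must be distinct from operon genes")

    @classmethod
    def from_reference(
        cls,
        operon_id: str,
        genome_sequence: str,
        gene_table: pd.DataFrame,
        gene_ids: Sequence[str],
        border_upstream: str,
        border_downstream: str,
    ) -> "OperonModel":
        """Build a model from a reference genome and its gene coordinate
        table (columns gene_id, start, end; 0-based half-open)."""
        coords = gene_table.set_index("gene_id")
        missing = [g for g in list(gene_ids) + [border_upstream, border_downstream]
                   if g not in coords.index]
        if missing:
            raise ValueError(f"genes absent from reference table: {missing[:5]}")
        genes = {
            g: genome_sequence[int(coords.loc[g].start) : int(coords.loc[g].end)]
            for g in gene_ids
        }
        span_start = int(min(coords.loc[g].start for g in gene_ids))
        span_end = int(max(coords.loc[g].end for g in gene_ids))
        return cls(
            operon_id=operon_id,
            genes=genes,
            border_upstream=(
                border_upstream,
                genome_sequence[
                    int(coords.loc[border_upstream].start) : int(
                        coords.loc[border_upstream].end
                    )
                ],
            ),
            border_downstream=(
                border_downstream,
                genome_sequence[
                    int(coords.loc[border_downstream].start) : int(
                        coords.loc[border_downstream].end
                    )
                ],
            ),
            reference_length=span_end - span_start,
            reference_cds_count=len(gene_ids),
        )


@dataclass
class IslandCall:
    genome_id: str
    contig_id: str | None
    span: tuple[int, int] | None  # 0-based half-open on the contig
    length: int
    gc_island: float | None
    gc_background: float | None
    completeness: str  # full | partial | absent


def _retained_hits(
    hits: Sequence[AlignmentHit],
    query_length: int,
    min_len_frac: float,
    min_identity: float,
    max_e: float,
) -> list[AlignmentHit]:
    """Length / identity / E-value filters plus redundancy removal (best
    hit per overlapping subject locus)."""
    passing = [
        h
        for h in hits
        if h.alignment_length >= min_len_frac * query_length
        and h.percent_identity >= min_identity
        and h.e_value < max_e
    ]
    kept: list[AlignmentHit] = []
    loci: list[tuple[str, int, int]] = []
    for h in sorted(passing, key=lambda x: -x.bit_score):
        lo, hi = sorted((h.subject_start, h.subject_end))
        if any(sub == h.subject_id and lo < e and hi > s for sub, s, e in loci):
            continue
        kept.append(h)
        loci.append((h.subject_id, lo, hi))
    return kept


def detect_operon_genes(
    contigs: Mapping[str, str],
    operon_genes: Mapping[str, str],
    min_len_frac: float = 0.75,
    min_identity: float = 95.0,
    max_e: float = 1e-44,
) -> dict[str, bool]:
    """Presence call per operon gene against a genome's contigs."""
    hits = align.align_all(dict(operon_genes), dict(contigs))
    presence: dict[str, bool] = {}
    for gene_id, seq in operon_genes.items():
        gene_hits = [h for h in hits if h.query_id == gene_id]
        retained = _retained_hits(gene_hits, len(seq), min_len_frac, min_identity, max_e)
        presence[gene_id] = bool(retained)
    return presence


def operon_presence_matrix(
    genomes: Mapping[str, Mapping[str, str]],
    operons: Sequence[OperonModel],
    **detect_kwargs,
) -> pd.DataFrame:
    """Gene x genome presence over all operon models."""
    all_genes = {g: s for op in operons for g, s in op.genes.items()}
    cols = {}
    for genome_id, contigs in genomes.items():
        presence = detect_operon_genes(contigs, all_genes, **detect_kwargs)
        cols[genome_id] = pd.Series(presence, dtype=bool)
    return pd.DataFrame(cols).astype(int)


def flag_lacking(presence: pd.DataFrame, threshold: float = 0.2) -> pd.Series:
    """Genomes lacking more than ``threshold`` of the operon genes
    (counted by genes, not bases)."""
    return (1.0 - presence.mean(axis=0)) > threshold


def locate_operon_by_borders(
    contigs: Mapping[str, str],
    operon: OperonModel,
    max_e: float = 1e-30,
) -> dict | None:
    """Operon interval between the inner ends of the two border-gene hits.

    Requires exactly two qualifying border hits, both on one contig (one
    per border); anything else is undetermined (returns None). Genes
    inside the interval are annotated by mapping against the operon's
    gene sequences.
    """
    borders = {
        operon.border_upstream[0]: operon.border_upstream[1],
        operon.border_downstream[0]: operon.border_downstream[1],
    }
    hits = [
        h
        for h in align.align_all(borders, dict(contigs))
        if h.e_value < max_e
    ]
    by_contig: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.subject_id, []).append(h)
    qualifying = [
        (contig, ch)
        for contig, ch in by_contig.items()
        if len(ch) == 2 and {h.query_id for h in ch} == set(borders)
    ]
    if len(hits) != 2 or len(qualifying) != 1:
        return None
    contig, (h1, h2) = qualifying[0]
    spans = sorted(
        [sorted((h.subject_start - 1, h.subject_end)) for h in (h1, h2)]
    )
    inner = (spans[0][1], spans[1][0])
    if inner[0] >= inner[1]:
        return None
    segment = contigs[contig][inner[0] : inner[1]]
    inside = detect_operon_genes({"segment": segment}, operon.genes, max_e=1e-10)
    return {
        "contig": contig,
        "interval": inner,
        "genes": inside,
    }


def gc_profile(
    contig: str,
    window: int = 20_000,
    step: int = 10,
    end_trim: int = 10_000,
) -> pd.DataFrame:
    """Rolling GC fraction along a contig.

    Full windows only; the reported position is the window center, so the
    first ``end_trim`` bases at either end are never queried (end_trim
    defaults to window/2, the minimum possible). Ambiguity codes are
    excluded from both numerator and denominator.
    """
    n = len(contig)
    if n <= window:
        logger.warning("contig length %d <= window %d; empty profile", n, window)
        return pd.DataFrame({"position": [], "gc": []})
    arr = np.frombuffer(contig.upper().encode("ascii"), dtype=np.uint8)
    is_gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8)).astype(np.int64)
    is_acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8)).astype(np.int64)
    cum_gc = np.concatenate(([0], np.cumsum(is_gc)))
    cum_ok = np.concatenate(([0], np.cumsum(is_acgt)))
    trim = max(end_trim, window // 2)
    centers = np.arange(trim, n - trim + 1, step)
    starts = centers - window // 2
    valid = starts[(starts >= 0) & (starts + window <= n)]
    gc_counts = cum_gc[valid + window] - cum_gc[valid]
    ok_counts = cum_ok[valid + window] - cum_ok[valid]
    with np.errstate(invalid="ignore"):
        gc = np.where(ok_counts > 0, gc_counts / np.maximum(ok_counts, 1), np.nan)
    return pd.DataFrame({"position": valid + window // 2, "gc": gc})


def _gc_fraction(seq: str) -> float:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    ok = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    gc = np.isin(arr, np.frombuffer(b"GC", dtype=np.uint8))
    return float(gc.sum() / ok.sum()) if ok.any() else float("nan")


def extract_island(
    genomes: Mapping[str, Mapping[str, str]],
    seed_sequence: str,
    min_len_frac: float = 0.95,
    max_e: float = 1e-30,
) -> tuple[dict[str, IslandCall], dict[str, str]]:
    """Per-genome island call from a seed element sequence.

    Full call iff there is exactly one qualifying hit covering at least
    ``min_len_frac`` of the seed; partial when only shorter hits exist;
    absent otherwise. Returns the calls and, for full calls, the
    extracted island sequences (suitable for alignment).
    """
    if not seed_sequence:
        raise ValueError("empty seed sequence")
    calls: dict[str, IslandCall] = {}
    extracted: dict[str, str] = {}
    for genome_id, contigs in genomes.items():
        hits = [
            h
            for h in align.ungapped_hits("seed", seed_sequence, contigs)
            if h.e_value < max_e
        ]
        full = [h for h in hits if h.alignment_length >= min_len_frac * len(seed_sequence)]
        if len(full) == 1:
            h = full[0]
            lo, hi = sorted((h.subject_start - 1, h.subject_end))
            contig = contigs[h.subject_id]
            background = contig[:lo] + contig[hi:]
            calls[genome_id] = IslandCall(
                genome_id=genome_id,
                contig_id=h.subject_id,
                span=(lo, hi),
                length=hi - lo,
                gc_island=_gc_fraction(contig[lo:hi]),
                gc_background=_gc_fraction(background) if background else None,
                completeness="full",
            )
            extracted[genome_id] = contig[lo:hi]
        elif hits:
            calls[genome_id] = IslandCall(
                genome_id, None, None, 0, None, None, "partial"
            )
        else:
            calls[genome_id] = IslandCall(
                genome_id, None, None, 0, None, None, "absent"
            )
    return calls, extracted


def _best_filtered_hit(
    query: str, subjects: Mapping[str, str], min_identity: float = 95.0,
    min_len_frac: float = 0.75
) -> AlignmentHit | None:
    hits = [
        h
        for h in align.ungapped_hits("q", query, subjects)
        if h.percent_identity >= min_identity
        and h.alignment_length >= min_len_frac * len(query)
    ]
    return hits[0] if hits else None


def _is_orthologous(
    gene_seq: str,
    gene_span: tuple[int, int],
    bearing_seq: str,
    free_contigs: Mapping[str, str],
) -> bool:
    """Reciprocal-best-hit orthology of one gene between the island-
    bearing genome and an island-free genome."""
    fwd = _best_filtered_hit(gene_seq, free_contigs)
    if fwd is None:
        return False
    lo, hi = sorted((fwd.subject_start - 1, fwd.subject_end))
    candidate = free_contigs[fwd.subject_id][lo:hi]
    back = _best_filtered_hit(candidate, {"bearing": bearing_seq})
    if back is None:
        return False
    b_lo, b_hi = sorted((back.subject_start - 1, back.subject_end))
    return b_lo < gene_span[1] and b_hi > gene_span[0]


def discover_island_boundaries(
    genomes: Mapping[str, Mapping[str, str]],
    gene_tables: Mapping[str, pd.DataFrame],
    seed_sequence: str,
    min_contig: int = 100_000,
    min_hit: int = 30_000,
    max_e: float = 1e-30,
) -> tuple[str, str]:
    """Bordering genes of the island insertion.

    Finds long (>= ``min_contig``) contigs carrying a single long
    (>= ``min_hit``) hit of the seed element, takes the genes flanking
    the hit, and walks outward until a flanking gene is orthologous
    (reciprocal best hit) to a locus in every island-free long contig's
    genome; returns that (upstream, downstream) gene pair.
    """
    bearing: list[tuple[str, str, tuple[int, int]]] = []  # genome, contig, span
    free: list[str] = []
    for genome_id, contigs in genomes.items():
        long_contigs = {c: s for c, s in contigs.items() if len(s) >= min_contig}
        if not long_contigs:
            continue
        hits = [
            h
            for h in align.ungapped_hits("seed", seed_sequence, long_contigs)
            if h.e_value < max_e and h.alignment_length >= min_hit
        ]
        if len(hits) == 1:
            h = hits[0]
            lo, hi = sorted((h.subject_start - 1, h.subject_end))
            bearing.append((genome_id, h.subject_id, (lo, hi)))
        elif not hits:
            free.append(genome_id)
    if not any(
        len(s) >= min_contig for cs in genomes.values() for s in cs.values()
    ):
        raise ValueError("no qualifying contigs (none reach the length cutoff)")
    if not bearing:
        raise ValueError("no island-bearing contigs found")
    if not free:
        raise ValueError("island-free contigs only on one side; cannot "
                         "polarize the insertion")
    genome_id, contig_id, (lo, hi) = bearing[0]
    table = gene_tables[genome_id].sort_values("start").reset_index(drop=True)
    bearing_seq = genomes[genome_id][contig_id]
    upstream = table[table.end <= lo].iloc[::-1]
    downstream = table[table.start >= hi]
    free_contig_sets = [dict(genomes[g]) for g in free]

    def first_orthologous(candidates: pd.DataFrame) -> str:
        for _, row in candidates.iterrows():
            seq = bearing_seq[int(row.start) : int(row.end)]
            span = (int(row.start), int(row.end))
            if all(
                _is_orthologous(seq, span, bearing_seq, fc)
                for fc in free_contig_sets
            ):
                return str(row.gene_id)
        raise ValueError("no orthologous flanking gene found")

    return first_orthologous(upstream), first_orthologous(downstream)


def compare_island_core(
    island_aln: CoreAlignment,
    core_aln: CoreAlignment,
    n_perm: int = 9999,
    seed: int = 0,
) -> dict:
    """Island vs core diversification: both hamming matrices plus a
    Mantel correlation between them (same genome set required)."""
    if set(island_aln.labels) != set(core_aln.labels):
        raise ValueError("island and core alignments cover different genomes")
    island_d = hamming_distance(island_aln)
    core_d = hamming_distance(core_aln).reorder(island_d.labels)
    r, p = mantel_test(island_d, core_d, n_perm=n_perm, seed=seed)
    return {
        "island_distances": island_d,
        "core_distances": core_d,
        "mantel_r": r,
        "mantel_p": p,
        "median_island": float(np.median(island_d.condensed())),
        "median_core": float(np.median(core_d.condensed())),
    }
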