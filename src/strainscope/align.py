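"""A small exact local aligner used as the bundled alignment backend.

The binning and element-detection stages consume BLAST-style tabular hits
through an adapter contract (FASTA pair in, ``AlignmentHit`` list out), so
any aligner producing outfmt-6 can stand behind them. This module provides
a self-contained backend suitable for desk-scale inputs: k-mer anchored,
ungapped, forward-strand local alignment. Anchors sharing a diagonal are
merged into a candidate band, the band is trimmed to its maximal-scoring
segment (match +2 / mismatch -3, the blastn defaults), and identity is
reported over the trimmed segment. Bit scores and E-values follow the
ungapped Karlin-Altschul form so that downstream E-value cutoffs behave
like their BLAST counterparts.

Gapped alignment is deliberately out of scope: the synthetic populations
this package ships diverge by substitution only, and real data should go
through blastn with the hits read back via ``io.read_tabular_hits``.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping

import numpy as np

from .io import AlignmentHit

__all__ = ["kmer_index", "ungapped_hits", "align_all"]

# ungapped blastn scoring (match +2, mismatch -3); Karlin-Altschul
# parameters for that scheme
_MATCH = 2
_MISMATCH = -3
_LAMBDA = 0.625
_K = 0.41
_LN2 = float(np.log(2.0))


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """Positions of every k-mer in ``seq`` (forward strand)."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        index[seq[i : i + k]].append(i)
    return dict(index)


def _best_segment(mismatch: np.ndarray) -> tuple[int, int, int]:
    """Maximal-scoring contiguous segment of a match/mismatch profile.

    Returns (start, stop, score) with a 0-based half-open interval;
    classic maximum-subarray on per-position scores.
    """
    scores = np.where(mismatch, _MISMATCH, _MATCH).astype(np.int64)
    cum = np.concatenate(([0], np.cumsum(scores)))
    running_min = np.minimum.accumulate(cum[:-1])
    gains = cum[1:] - running_min
    stop = int(np.argmax(gains))
    score = int(gains[stop])
    start = int(np.argmin(cum[: stop + 1]))
    return start, stop + 1, score


def _bit_score(raw: int) -> float:
    return (_LAMBDA * raw - np.log(_K)) / _LN2


def _e_value(bits: float, query_len: int, db_len: int) -> float:
    log10_e = np.log10(float(query_len)) + np.log10(float(db_len)) - bits * np.log10(2.0)
    return float(10.0**log10_e) if log10_e > -300 else 0.0


def ungapped_hits(
    query_id: str,
    query: str,
    subjects: Mapping[str, str],
    *,
    k: int = 15,
    min_anchors: int = 2,
    min_bits: float = 50.0,
    subject_indexes: Mapping[str, dict[str, list[int]]] | None = None,
    db_len: int | None = None,
) -> list[AlignmentHit]:
    """All ungapped local hits of one query against a subject collection.

    ``min_anchors`` suppresses spurious single-k-mer diagonals; ``min_bits``
    drops segments too weak to be meaningful. Precomputed
    ``subject_indexes`` avoid re-indexing when many queries share subjects.
    """
    qarr = _as_array(query)
    total_db = db_len if db_len is not None else sum(len(s) for s in subjects.values())
    hits: list[AlignmentHit] = []
    query_kmers = [(i, query[i : i + k]) for i in range(len(query) - k + 1)]
    for subject_id, subject in subjects.items():
        index = (
            subject_indexes[subject_id]
            if subject_indexes is not None
            else kmer_index(subject, k)
        )
        diagonals: dict[int, int] = defaultdict(int)
        for qpos, kmer in query_kmers:
            for spos in index.get(kmer, ()):
                diagonals[spos - qpos] += 1
        sarr = _as_array(subject)
        for diag, n_anchors in diagonals.items():
            if n_anchors < min_anchors:
                continue
            qlo = max(0, -diag)
            qhi = min(len(query), len(subject) - diag)
            if qhi - qlo < k:
                continue
            band_mismatch = qarr[qlo:qhi] != sarr[qlo + diag : qhi + diag]
            seg_start, seg_stop, raw = _best_segment(band_mismatch)
            bits = _bit_score(raw)
            if bits < min_bits:
                continue
            length = seg_stop - seg_start
            mism = int(band_mismatch[seg_start:seg_stop].sum())
            q_start0 = qlo + seg_start
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=subject_id,
                    percent_identity=100.0 * (length - mism) / length,
                    alignment_length=length,
                    mismatches=mism,
                    gap_opens=0,
                    query_start=q_start0 + 1,
                    query_end=q_start0 + length,
                    subject_start=q_start0 + diag + 1,
                    subject_end=q_start0 + diag + length,
                    e_value=_e_value(bits, len(query), total_db),
                    bit_score=round(float(bits), 1),
                )
            )
    hits.sort(key=lambda h: (-h.bit_score, h.e_value, h.subject_id))
    return hits


def align_all(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    *,
    k: int = 15,
    min_anchors: int = 2,
    min_bits: float = 50.0,
) -> list[AlignmentHit]:
    """Hits of every query against every subject, indexes built once."""
    indexes = {name: kmer_index(seq, k) for name, seq in subjects.items()}
    db_len = sum(len(s) for s in subjects.values())
    hits: list[AlignmentHit] = []
    for query_id, query in queries.items():
        hits.extend(
            ungapped_hits(
                query_id,
                query,
                subjects,
                k=k,
                min_anchors=min_anchors,
                min_bits=min_bits,
                subject_indexes=indexes,
                db_len=db_len,
            )
        )
    return hits
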