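"""Synthetic bacterial populations with the statistical structure the
downstream analyses assume.

The generator emulates, at desk scale, a gut commensal species that falls
into a small number of geographically stratified subspecies:

* a star-like topology (root -> subspecies ancestor -> genome) with
  Jukes-Cantor substitutions calibrated so that realized pairwise core
  distances match requested intra-/inter-subspecies divergences;
* a gene map (core / accessory / operon genes separated by intergenic
  spacers) with per-subspecies accessory presence rates, including the
  wholesale loss of a contiguous multi-gene operon in one subspecies;
* a genomic island of atypical GC content inserted at a fixed locus in a
  fraction of one subspecies' genomes, nearly identical across carriers
  (a recent horizontal acquisition);
* contig fragmentation and spike-in assembly construction for binning
  benchmarks, read pileups from strain mixtures, and mother-infant
  normalized-genetic-distance tables.

Everything is driven by a single seeded ``numpy`` generator per call, so
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSimSpec",
    "Genome",
    "SimulatedPopulation",
    "Assembly",
    "simulate_population",
    "fragment_genome",
    "spike_assembly",
    "simulate_pileup",
    "simulate_pair_table",
    "random_sequence",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_INT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_INT[_b] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _BASE_TO_INT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    """Random base array (ints 0..3 = ACGT) with expected GC fraction."""
    at = (1.0 - gc) / 2.0
    return rng.choice(4, size=length, p=[at, gc / 2.0, gc / 2.0, at]).astype(np.uint8)


def _jc_length(d: float) -> float:
    """Jukes-Cantor branch length giving expected pairwise difference d."""
    if d < 0 or d >= 0.75:
        raise ValueError(f"divergence {d} outside [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * d / 3.0)


def _jc_prob(t: float) -> float:
    """Per-site substitution probability along a JC branch of length t."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def _mutate(rng: np.random.Generator, arr: np.ndarray, p: float) -> np.ndarray:
    """Substitute each site with probability p to a uniform other base."""
    out = arr.copy()
    if p <= 0:
        return out
    hit = np.flatnonzero(rng.random(arr.size) < p)
    shift = rng.integers(1, 4, size=hit.size).astype(np.uint8)
    out[hit] = (out[hit] + shift) % 4
    return out


@dataclass
class PopulationSimSpec:
    """Parameters of a synthetic multi-subspecies population.

    Defaults are calibrated to the population structure this package is
    designed to analyze: four subspecies whose intra-subspecies core-gene
    divergences sit near 1.4-1.95% and inter-subspecies divergences near
    2.0-2.5%; one subspecies that has lost a contiguous 34-gene motility
    operon; and a ~50 kb genomic island at GC 0.377 against a 0.423
    background, present in ~21% of the operon-free subspecies.
    """

    ancestral_length: int = 260_000
    subspecies_names: tuple[str, ...] = ("ErEurope", "ErEurasia", "ErAsia", "ErAfrica")
    n_genomes_per_subspecies: tuple[int, ...] = (20, 20, 20, 20)
    intra_divergence: tuple[float, ...] = (0.0138, 0.014, 0.019, 0.0195)
    inter_divergence: tuple[tuple[float, ...], ...] | None = None
    n_genes: int = 220
    gene_length: int = 900
    core_fraction: float = 0.75
    operon_gene_ids: tuple[str, ...] | None = None  # default: genes 10..43
    operon_deleted_in: str | None = "ErEurope"
    operon_partial_loss_rate: float = 0.02
    island_length: int = 49_668
    island_gc: float = 0.377
    island_present_in: tuple[str, float] | None = ("ErEurope", 0.21)
    island_divergence: float = 0.004
    background_gc: float = 0.423
    n_marker_genes: int = 40
    # within-subspecies diversity: genomes are block mosaics over a pool
    # of founder lineages plus a private tip, giving the diffuse,
    # non-treelike intra-subspecies distance clouds seen in gut species
    n_lineages: int = 16
    block_length: int = 2_000
    lineage_tip_share: float = 0.2
    seed: int = 0

    @property
    def n_subspecies(self) -> int:
        return len(self.subspecies_names)

    def default_inter_matrix(self) -> np.ndarray:
        """Inter-subspecies divergences in the 2.0-2.5% band.

        Chosen to be additive on the star topology (so realized distances
        can match exactly): the first two subspecies are the most closely
        related pair and the first and third the most divergent, echoing
        the observed population structure.
        """
        n = self.n_subspecies
        tips = np.asarray(self.intra_divergence, dtype=float) / 2.0
        roots = np.asarray([0.0029, 0.0032, 0.00275, 0.0030][:n])
        if n > 4:
            roots = np.concatenate([roots, np.full(n - 4, 0.002)])
        base = tips[:, None] + tips[None, :] + roots[:, None] + roots[None, :]
        np.fill_diagonal(base, 0.0)
        return base

    def resolved_inter(self) -> np.ndarray:
        if self.inter_divergence is None:
            return self.default_inter_matrix()
        mat = np.asarray(self.inter_divergence, dtype=float)
        return mat

    def resolved_operon_genes(self) -> tuple[str, ...]:
        if self.operon_gene_ids is not None:
            return tuple(self.operon_gene_ids)
        if self.operon_deleted_in is None:
            return ()
        # 34 genes at full scale; shrink proportionally for tiny gene maps
        size = 34 if self.n_genes >= 180 else max(3, self.n_genes // 6)
        start = min(10, max(1, self.n_genes // 10))
        return tuple(_gene_id(i) for i in range(start, start + size))

    def validate(self) -> None:
        n = self.n_subspecies
        if len(self.n_genomes_per_subspecies) != n or len(self.intra_divergence) != n:
            raise ValueError("per-subspecies fields must match subspecies_names")
        for d in self.intra_divergence:
            if not 0.0 <= d <= 0.05:
                raise ValueError(f"intra divergence {d} outside [0, 0.05]")
        inter = self.resolved_inter()
        if inter.shape != (n, n) or not np.allclose(inter, inter.T):
            raise ValueError("inter_divergence must be a symmetric n x n matrix")
        for i in range(n):
            for j in range(i + 1, n):
                d = inter[i, j]
                if not 0.0 <= d <= 0.05:
                    raise ValueError(f"inter divergence {d} outside [0, 0.05]")
                if d < max(self.intra_divergence[i], self.intra_divergence[j]):
                    raise ValueError(
                        "inter divergence must be >= both intra divergences "
                        f"for pair ({self.subspecies_names[i]}, "
                        f"{self.subspecies_names[j]})"
                    )
        if self.island_present_in is not None:
            label, prev = self.island_present_in
            if label not in self.subspecies_names:
                raise ValueError(f"unknown island subspecies {label!r}")
            if not 0.0 <= prev <= 1.0:
                raise ValueError(f"island prevalence {prev} outside [0, 1]")
            if self.island_length <= 0:
                raise ValueError("island_length must be positive when island set")
        if self.operon_deleted_in is not None and (
            self.operon_deleted_in not in self.subspecies_names
        ):
            raise ValueError(f"unknown operon subspecies {self.operon_deleted_in!r}")
        if not 0.0 < self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in (0, 1]")
        genic = self.n_genes * self.gene_length
        if genic > self.ancestral_length:
            raise ValueError("genes do not fit in ancestral_length")


def _gene_id(i: int) -> str:
    return f"gene_{i:04d}"


@dataclass
class Genome:
    genome_id: str
    subspecies: str
    sequence: str
    genes: pd.DataFrame  # columns gene_id, start, end (0-based half-open)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene_sequence(self, gene_id: str) -> str:
        row = self.genes.loc[self.genes.gene_id == gene_id]
        if row.empty:
            raise KeyError(f"{gene_id} absent from {self.genome_id}")
        start, end = int(row.iloc[0].start), int(row.iloc[0].end)
        return self.sequence[start:end]


@dataclass
class SimulatedPopulation:
    spec: PopulationSimSpec
    genomes: list[Genome]
    subspecies_of: dict[str, str]
    core_genes: tuple[str, ...]
    operon_genes: tuple[str, ...]
    accessory_genes: tuple[str, ...]
    marker_genes: tuple[str, ...]
    presence: pd.DataFrame  # gene x genome 0/1, every gene class included
    operon_present: dict[str, bool]
    island_present: dict[str, bool]
    island_span: dict[str, tuple[int, int]]  # final coords per carrier
    island_border_genes: tuple[str, str]  # core genes flanking the locus
    operon_border_genes: tuple[str, str]

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    def genome(self, genome_id: str) -> Genome:
        for g in self.genomes:
            if g.genome_id == genome_id:
                return g
        raise KeyError(genome_id)

    def core_alignment(self) -> tuple[list[str], list[str]]:
        """Concatenated core-gene 'alignment' (no indels, so columns align)."""
        labels, rows = [], []
        for g in self.genomes:
            coords = g.genes.set_index("gene_id")
            parts = [
                g.sequence[int(coords.loc[gid].start) : int(coords.loc[gid].end)]
                for gid in self.core_genes
            ]
            labels.append(g.genome_id)
            rows.append("".join(parts))
        return labels, rows

    def gene_sequences(self, gene_id: str) -> dict[str, str]:
        out = {}
        for g in self.genomes:
            if (g.genes.gene_id == gene_id).any():
                out[g.genome_id] = g.gene_sequence(gene_id)
        return out


def _solve_root_branches(t_inter: np.ndarray, t_tip: np.ndarray) -> np.ndarray:
    """Least-squares per-subspecies root branch lengths q with
    q_i + q_j ~= t_inter[i,j] - t_tip[i] - t_tip[j] for every pair."""
    n = t_inter.shape[0]
    rows, rhs = [], []
    for i in range(n):
        for j in range(i + 1, n):
            row = np.zeros(n)
            row[i] = row[j] = 1.0
            rows.append(row)
            rhs.append(t_inter[i, j] - t_tip[i] - t_tip[j])
    if not rows:
        return np.zeros(n)
    q, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(rhs), rcond=None)
    return np.clip(q, 0.0, None)


def simulate_population(spec: PopulationSimSpec) -> SimulatedPopulation:
    """Simulate genomes, gene maps, and element truth per the spec.

    Substitutions follow a Jukes-Cantor process down a star-like topology;
    branch lengths are solved so that expected pairwise core distances
    equal the requested intra/inter divergences (the inter matrix is fit
    by least squares when it is not exactly additive).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = spec.subspecies_names
    operon_genes = spec.resolved_operon_genes()
    all_genes = [_gene_id(i) for i in range(spec.n_genes)]
    operon_idx = sorted(all_genes.index(g) for g in operon_genes)
    if operon_idx and operon_idx != list(range(operon_idx[0], operon_idx[-1] + 1)):
        raise ValueError("operon genes must form a contiguous block")

    # --- gene classes -------------------------------------------------
    n_core = int(round(spec.core_fraction * spec.n_genes))
    non_operon = [i for i in range(spec.n_genes) if i not in set(operon_idx)]
    forced_core: set[int] = set()
    if operon_idx:
        if operon_idx[0] - 1 >= 0:
            forced_core.add(operon_idx[0] - 1)
        if operon_idx[-1] + 1 < spec.n_genes:
            forced_core.add(operon_idx[-1] + 1)
    # island locus: between two genes around 70% of the map
    island_after = min(int(0.7 * spec.n_genes), spec.n_genes - 1)
    while island_after - 1 in set(operon_idx) or island_after in set(operon_idx):
        island_after += 1
    forced_core.update({island_after - 1, island_after})
    n_core = max(n_core, len(forced_core))
    n_core = min(n_core, len(non_operon))
    candidates = [i for i in non_operon if i not in forced_core]
    extra = rng.choice(
        len(candidates), size=max(0, n_core - len(forced_core)), replace=False
    )
    core_idx = sorted(forced_core | {candidates[i] for i in extra})
    core_genes = tuple(all_genes[i] for i in core_idx)
    accessory_idx = [
        i for i in non_operon if i not in set(core_idx) and i not in forced_core
    ]
    accessory_genes = tuple(all_genes[i] for i in accessory_idx)
    marker_pool = [g for g in core_genes]
    marker_sel = rng.choice(
        len(marker_pool), size=min(spec.n_marker_genes, len(marker_pool)), replace=False
    )
    marker_genes = tuple(marker_pool[i] for i in sorted(marker_sel))

    # --- ancestral layout ---------------------------------------------
    genic = spec.n_genes * spec.gene_length
    spacer = (spec.ancestral_length - genic) // (spec.n_genes + 1)
    layout: list[tuple[str, str | None, int]] = []  # (kind, gene_id, length)
    for i in range(spec.n_genes):
        layout.append(("spacer", None, spacer))
        layout.append(("gene", all_genes[i], spec.gene_length))
    layout.append(("spacer", None, spacer))
    total_len = sum(length for _, _, length in layout)
    root = random_sequence(rng, total_len, gc=spec.background_gc)

    # --- branch lengths ------------------------------------------------
    # expected intra-subspecies distance decomposes into two private tips
    # (share `lineage_tip_share`) plus two founder branches, of which a
    # random founder pair differs with probability 1 - 1/M
    m = max(1, spec.n_lineages)
    alpha = spec.lineage_tip_share if m > 1 else 1.0
    t_intra = np.array([_jc_length(d) for d in spec.intra_divergence])
    t_eps = alpha * t_intra / 2.0
    if m > 1:
        t_founder = (1.0 - alpha) * t_intra / (2.0 * (1.0 - 1.0 / m))
    else:
        t_founder = np.zeros_like(t_intra)
    t_tip = t_eps + t_founder
    inter = spec.resolved_inter()
    t_inter = np.zeros_like(inter)
    for i in range(spec.n_subspecies):
        for j in range(spec.n_subspecies):
            if i != j:
                t_inter[i, j] = _jc_length(inter[i, j])
    q = _solve_root_branches(t_inter, t_tip)

    # --- island material ----------------------------------------------
    island_root = (
        random_sequence(rng, spec.island_length, gc=spec.island_gc)
        if spec.island_present_in is not None
        else None
    )
    island_tip = _jc_length(spec.island_divergence) / 2.0 if island_root is not None else 0.0

    # --- accessory presence rates per (gene, subspecies) ---------------
    acc_rate = pd.DataFrame(
        rng.uniform(0.6, 1.0, size=(len(accessory_genes), spec.n_subspecies)),
        index=list(accessory_genes),
        columns=list(names),
    )
    if spec.operon_deleted_in is not None and accessory_genes:
        # the operon-free subspecies turns its accessory repertoire over
        # faster, mirroring accelerated functional divergence
        acc_rate[spec.operon_deleted_in] = rng.uniform(
            0.2, 1.0, size=len(accessory_genes)
        )

    # --- per-genome construction ---------------------------------------
    genomes: list[Genome] = []
    subspecies_of: dict[str, str] = {}
    presence_cols: dict[str, pd.Series] = {}
    operon_present: dict[str, bool] = {}
    island_present: dict[str, bool] = {}
    island_span: dict[str, tuple[int, int]] = {}
    island_label, island_prev = (
        spec.island_present_in if spec.island_present_in is not None else (None, 0.0)
    )

    n_blocks = (total_len + spec.block_length - 1) // spec.block_length
    block_edges = np.minimum(
        np.arange(n_blocks + 1) * spec.block_length, total_len
    )
    for s_idx, sname in enumerate(names):
        anc = _mutate(rng, root, _jc_prob(q[s_idx]))
        p_founder = _jc_prob(t_founder[s_idx])
        p_eps = _jc_prob(t_eps[s_idx])
        founders = [_mutate(rng, anc, p_founder) for _ in range(m)]
        for g_i in range(spec.n_genomes_per_subspecies[s_idx]):
            gid = f"{sname}_{g_i:03d}"
            subspecies_of[gid] = sname
            if m > 1:
                choice = rng.integers(m, size=n_blocks)
                garr = np.concatenate(
                    [
                        founders[choice[b]][block_edges[b] : block_edges[b + 1]]
                        for b in range(n_blocks)
                    ]
                )
            else:
                garr = founders[0]
            garr = _mutate(rng, garr, p_eps)
            has_operon = True
            if operon_genes:
                if sname == spec.operon_deleted_in:
                    has_operon = False
                elif rng.random() < spec.operon_partial_loss_rate:
                    has_operon = False
            operon_present[gid] = has_operon if operon_genes else False
            acc_present = {
                g: bool(rng.random() < acc_rate.loc[g, sname])
                for g in accessory_genes
            }
            has_island = bool(
                island_root is not None
                and sname == island_label
                and rng.random() < island_prev
            )
            island_present[gid] = has_island
            island_seq = (
                _mutate(rng, island_root, _jc_prob(island_tip))
                if has_island
                else None
            )

            parts: list[np.ndarray] = []
            coords: list[tuple[str, int, int]] = []
            pos = 0
            cursor = 0
            gene_counter = 0
            for kind, gene, length in layout:
                chunk = garr[cursor : cursor + length]
                cursor += length
                if kind == "gene":
                    keep = True
                    if gene in operon_genes:
                        keep = has_operon
                    elif gene in acc_present:
                        keep = acc_present[gene]
                    if keep:
                        parts.append(chunk)
                        coords.append((gene, pos, pos + length))
                        pos += length
                    gene_counter += 1
                else:
                    if has_island and gene_counter == island_after:
                        # island sits mid-spacer just before gene island_after
                        half = length // 2
                        parts.append(chunk[:half])
                        pos += half
                        parts.append(island_seq)
                        island_span[gid] = (pos, pos + len(island_seq))
                        pos += len(island_seq)
                        parts.append(chunk[half:])
                        pos += length - half
                        has_island = False  # placed once
                        island_present[gid] = True
                    else:
                        parts.append(chunk)
                        pos += length
            seq = _decode(np.concatenate(parts))
            genes_df = pd.DataFrame(coords, columns=["gene_id", "start", "end"])
            genomes.append(Genome(gid, sname, seq, genes_df))
            col = pd.Series(0, index=all_genes, dtype=int)
            present_ids = [c[0] for c in coords]
            col.loc[present_ids] = 1
            presence_cols[gid] = col

    presence = pd.DataFrame(presence_cols)
    border = (all_genes[island_after - 1], all_genes[island_after])
    op_border = (
        (all_genes[operon_idx[0] - 1], all_genes[operon_idx[-1] + 1])
        if operon_idx
        else ("", "")
    )
    return SimulatedPopulation(
        spec=spec,
        genomes=genomes,
        subspecies_of=subspecies_of,
        core_genes=core_genes,
        operon_genes=operon_genes,
        accessory_genes=accessory_genes,
        marker_genes=marker_genes,
        presence=presence,
        operon_present=operon_present,
        island_present=island_present,
        island_span=island_span,
        island_border_genes=border,
        operon_border_genes=op_border,
    )


def fragment_genome(
    sequence: str,
    min_len: int = 1000,
    max_len: int = 50_000,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Slice a genome into contigs with uniformly distributed lengths.

    Lengths are drawn uniformly in [min_len, max_len]; the final remainder
    is kept even when shorter than min_len so that the concatenation of
    the pieces reconstructs the input exactly.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if len(sequence) < min_len:
        logger.warning(
            "sequence shorter than min_len (%d < %d); returning one contig",
            len(sequence),
            min_len,
        )
        return [sequence]
    pieces: list[str] = []
    pos = 0
    n = len(sequence)
    while pos < n:
        size = int(rng.integers(min_len, max_len + 1))
        pieces.append(sequence[pos : pos + size])
        pos += size
    return pieces


@dataclass
class Assembly:
    """A contig set with optional per-contig coverage and truth labels."""

    contigs: dict[str, str]
    coverage: dict[str, float] = field(default_factory=dict)
    truth: dict[str, str] = field(default_factory=dict)  # spike | background

    @property
    def total_bases(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def spike_assembly(background: Assembly, target_pieces: Sequence[str]) -> Assembly:
    """Insert known target fragments into a target-free assembly.

    Every output contig carries a truth flag; id collisions between spike
    contigs and background contigs are resolved by suffixing.
    """
    contigs = dict(background.contigs)
    coverage = dict(background.coverage)
    truth = {name: "background" for name in contigs}
    for i, piece in enumerate(target_pieces):
        name = f"spike_{i:05d}"
        while name in contigs:
            logger.warning("contig id collision for %s; renaming", name)
            name = name + "_s"
        contigs[name] = piece
        truth[name] = "spike"
    return Assembly(contigs=contigs, coverage=coverage, truth=truth)


def simulate_pileup(
    mixture: Sequence[tuple[str, float]],
    genes: Mapping[str, Mapping[str, str]],
    depth: float = 50.0,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate quality-filtered base counts over coding genes.

    ``genes`` maps gene_id -> {genome_id: sequence}; every mixture member
    must have every gene, and sequences of a gene must have equal length.
    Per-site depth is Poisson(depth); reads are drawn from the mixture
    proportions, with sequencing errors substituting a uniform other base.
    Returns a table with columns (gene_id, pos, A, C, G, T, depth).
    """
    props = np.array([p for _, p in mixture], dtype=float)
    if props.size == 0 or abs(props.sum() - 1.0) > 1e-8 or (props < 0).any():
        raise ValueError("mixture proportions must be non-negative and sum to 1")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    member_ids = [m for m, _ in mixture]
    frames = []
    for gene_id, by_genome in genes.items():
        try:
            seqs = [_encode(by_genome[m]) for m in member_ids]
        except KeyError as exc:
            raise KeyError(f"genome {exc} lacks gene {gene_id}") from exc
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"gene {gene_id}: unequal sequence lengths")
        L = lengths.pop()
        site_depth = rng.poisson(depth, size=L)
        # reads per member per site
        alloc = rng.multinomial(site_depth, props)  # (L, n_members)
        counts = np.zeros((L, 4), dtype=np.int64)
        for m_idx, seq in enumerate(seqs):
            np.add.at(counts, (np.arange(L), seq), alloc[:, m_idx])
        if error_rate > 0:
            errs = rng.binomial(counts, error_rate)
            counts -= errs
            for b in range(4):
                redistribution = rng.multinomial(errs[:, b], [1 / 3.0] * 3)
                others = [x for x in range(4) if x != b]
                for j, ob in enumerate(others):
                    counts[:, ob] += redistribution[:, j]
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_id,
                    "pos": np.arange(L),
                    "A": counts[:, 0],
                    "C": counts[:, 1],
                    "G": counts[:, 2],
                    "T": counts[:, 3],
                    "depth": counts.sum(axis=1),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_pair_table(
    n_pairs: int,
    n_unrelated: int,
    related_ngd_dist: Callable[[np.random.Generator, int], np.ndarray],
    unrelated_ngd_dist: Callable[[np.random.Generator, int], np.ndarray],
    seed: int | np.random.Generator = 0,
    n_timepoints: int = 1,
) -> pd.DataFrame:
    """Mother-infant vs unrelated pair table with sampled nGD values.

    The distribution arguments are callables ``f(rng, size) -> array``
    (e.g. ``lambda rng, n: rng.uniform(0.5, 1.5, n)``). Related dyads get
    one row per timepoint.
    """
    if n_unrelated < 100:
        logger.warning(
            "only %d unrelated pairs; percentile threshold will be unstable",
            n_unrelated,
        )
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    rows = []
    related = np.asarray(related_ngd_dist(rng, n_pairs * n_timepoints), dtype=float)
    if (related < 0).any():
        raise ValueError("related nGD distribution produced negative values")
    for i in range(n_pairs):
        for t in range(n_timepoints):
            rows.append(
                (
                    f"mother_{i:04d}",
                    f"infant_{i:04d}",
                    "mother-infant",
                    t,
                    related[i * n_timepoints + t],
                )
            )
    unrelated = np.asarray(unrelated_ngd_dist(rng, n_unrelated), dtype=float)
    if (unrelated < 0).any():
        raise ValueError("unrelated nGD distribution produced negative values")
    for j in range(n_unrelated):
        rows.append((f"subj_{2 * j:05d}", f"subj_{2 * j + 1:05d}", "unrelated", 0, unrelated[j]))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "relationship", "timepoint", "ngd"]
    )
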