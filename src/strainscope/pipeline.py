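"""End-to-end desk-scale mini-study.

Runs the full flow on a fresh synthetic population: simulate -> fragment
and spike -> tune binning thresholds -> bin -> quality control ->
distances -> subspecies delineation -> diagnostic SNVs and abundance ->
operon and island analysis -> isolation by distance -> vertical
transmission. Every stage writes its table into the run directory so
each reported number is recomputable from persisted intermediates, and
the whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import align, binning, qc
from .distances import (
    CoreAlignment,
    DistanceMatrix,
    define_core_genes,
    functional_divergence_rate,
    hamming_distance,
    jaccard_gene_distance,
)
from .geo import (
    GeoPoint,
    geographic_distance_matrix,
    mantel_test,
    transmission_rate,
    transmission_threshold,
)
from .islands import (
    OperonModel,
    compare_island_core,
    discover_island_boundaries,
    extract_island,
    gc_profile,
    locate_operon_by_borders,
    operon_presence_matrix,
)
from .simulate import (
    Assembly,
    PopulationSimSpec,
    SimulatedPopulation,
    fragment_genome,
    random_sequence,
    simulate_pair_table,
    simulate_pileup,
    simulate_population,
    spike_assembly,
)
from .subspecies import (
    derive_subspecies_snvs,
    estimate_subspecies_abundance,
    pam_cluster,
    prediction_strength,
    select_k,
)

logger = logging.getLogger(__name__)

__all__ = ["MiniStudyConfig", "StudyReport", "run_mini_study"]

# representative subspecies locations: Germany, Kazakhstan, Eastern
# China, Tanzania; the Africa-Asia route crosses the Arabian peninsula
_DEFAULT_LOCATIONS = {
    "ErEurope": (51.0, 10.0),
    "ErEurasia": (48.0, 68.0),
    "ErAsia": (32.0, 114.0),
    "ErAfrica": (-6.0, 35.0),
}
_ARABIA = GeoPoint("arabia", 25.0, 45.0)


@dataclass
class MiniStudyConfig:
    population: PopulationSimSpec = field(default_factory=PopulationSimSpec)
    seed: int = 7
    # binning stage
    n_spike_assemblies: int = 3
    n_background_contigs: int = 40
    background_contig_len: tuple[int, int] = (2_000, 40_000)
    identity_grid: tuple[float, ...] = (90.0, 95.0, 98.0)
    fraction_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    min_identity: float = 95.0
    min_fraction: float = 0.5
    n_binned_samples: int = 3
    # clustering stage
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    ps_subsamples: int = 8
    ps_divisions: int = 5
    ps_cutoff: float = 0.8
    # abundance stage
    abundance_mixtures: tuple[tuple[float, ...], ...] = ((1.0, 0.0), (0.7, 0.3), (0.5, 0.5))
    abundance_depth: float = 60.0
    # island stage
    gc_window: int = 20_000
    gc_step: int = 200
    island_min_contig: int = 100_000
    # transmission stage
    n_mother_infant_pairs: int = 12
    n_transmitting: int = 3
    n_unrelated: int = 1_000


@dataclass
class StudyReport:
    tables: dict[str, pd.DataFrame]
    scalars: dict[str, float]
    provenance: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in sorted(self.tables.items()):
            table.to_csv(out / f"{name}.tsv", sep="\t", index=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {"scalars": self.scalars, "provenance": self.provenance},
                fh,
                indent=2,
                sort_keys=True,
            )
        lines = [f"{k}\t{v}" for k, v in sorted(self.scalars.items())]
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        return out


def _decode_seq(arr: np.ndarray) -> str:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[arr].tobytes().decode("ascii")


def _binning_stage(
    cfg: MiniStudyConfig,
    pop: SimulatedPopulation,
    refs: dict[str, str],
    rng: np.random.Generator,
) -> tuple[dict, pd.DataFrame, pd.DataFrame]:
    """Spike-in tuning plus per-sample binning with QC."""
    ref_index = {name: align.kmer_index(seq, 15) for name, seq in refs.items()}
    db_len = sum(len(s) for s in refs.values())
    avg_ref = db_len / len(refs)

    def evidence_for(assembly: Assembly):
        ev = {}
        for name, seq in assembly.contigs.items():
            hits = align.ungapped_hits(
                name, seq, refs, subject_indexes=ref_index, db_len=db_len
            )
            ev[name] = binning.aggregate_contig_evidence(hits, len(seq))
        return ev

    def background_assembly() -> Assembly:
        contigs = {}
        for i in range(cfg.n_background_contigs):
            length = int(
                rng.integers(cfg.background_contig_len[0], cfg.background_contig_len[1])
            )
            contigs[f"bg_{i:04d}"] = _decode_seq(
                random_sequence(rng, length, gc=0.45)
            )
        return Assembly(contigs=contigs)

    # ---- tuning on spiked assemblies ---------------------------------
    spike_sources = [g for g in pop.genomes if g.genome_id not in refs]
    spiked = []
    for i in range(cfg.n_spike_assemblies):
        src = spike_sources[i % len(spike_sources)]
        pieces = fragment_genome(src.sequence, 1000, 50_000, seed=rng)
        assembly = spike_assembly(background_assembly(), pieces)
        spiked.append((assembly, evidence_for(assembly)))
    tuning = binning.tune_parameters(
        spiked, cfg.identity_grid, cfg.fraction_grid, avg_ref
    )
    surface_rows = [
        (ident, frac, fp, fn)
        for (ident, frac), (fp, fn) in sorted(tuning["surface"].items())
    ]
    surface = pd.DataFrame(
        surface_rows, columns=["identity", "fraction", "median_fp_scaled", "median_fn_scaled"]
    )

    # ---- per-sample binning + QC -------------------------------------
    ref_sizes = [len(s) for s in refs.values()]
    size_range = (int(0.95 * min(ref_sizes)), int(1.05 * max(ref_sizes)))
    marker_set = {
        m: pop.genomes[0].gene_sequence(m) for m in pop.marker_genes
    }
    qc_rows = []
    for i in range(cfg.n_binned_samples):
        src = spike_sources[(i + cfg.n_spike_assemblies) % len(spike_sources)]
        pieces = fragment_genome(src.sequence, 1000, 50_000, seed=rng)
        assembly = spike_assembly(background_assembly(), pieces)
        base_cov = float(rng.uniform(20, 60))
        for name in assembly.contigs:
            if assembly.truth[name] == "spike":
                assembly.coverage[name] = base_cov * float(rng.uniform(0.8, 1.2))
            else:
                assembly.coverage[name] = float(rng.uniform(1, 80))
        ev = evidence_for(assembly)
        b = binning.bin_contigs(
            assembly, ev, cfg.min_identity, cfg.min_fraction, bin_id=src.genome_id
        )
        evaluation = binning.evaluate_binning(b, assembly.truth, assembly, avg_ref)
        b = binning.remove_low_coverage_contigs(b)
        completeness, contamination = qc.estimate_completeness_contamination(
            b, marker_set
        )
        core_subset = list(pop.core_genes[:10])
        pileup = simulate_pileup(
            [(src.genome_id, 1.0)],
            {g: {src.genome_id: src.gene_sequence(g)} for g in core_subset},
            depth=base_cov,
            error_rate=0.002,
            seed=rng,
        )
        calls = qc.call_sites(pileup)
        rho = qc.heterogeneity_rate(
            calls, {g: len(src.gene_sequence(g)) for g in core_subset}
        )
        metrics = qc.QCMetrics(
            completeness=completeness,
            contamination=contamination,
            genome_size=b.size,
            n_contigs=b.n_contigs,
            heterogeneity_rate=rho,
        )
        passed, reasons = qc.classify_hq(metrics, size_range=size_range)
        qc_rows.append(
            (
                src.genome_id,
                completeness,
                contamination,
                b.size,
                b.n_contigs,
                rho,
                evaluation.fp_scaled,
                evaluation.fn_scaled,
                passed,
                ";".join(reasons),
            )
        )
    qc_table = pd.DataFrame(
        qc_rows,
        columns=[
            "source_genome",
            "completeness",
            "contamination",
            "size",
            "n_contigs",
            "heterogeneity",
            "fp_scaled",
            "fn_scaled",
            "hq",
            "fail_reasons",
        ],
    ).set_index("source_genome")
    return tuning, surface.set_index(["identity", "fraction"]), qc_table


def run_mini_study(cfg: MiniStudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    rng = np.random.default_rng(cfg.seed)
    pop = simulate_population(cfg.population)
    names = cfg.population.subspecies_names

    # one reference per subspecies (the study's 'isolate genomes')
    refs = {}
    for s in names:
        gid = f"{s}_000"
        refs[gid] = pop.genome(gid).sequence

    tuning, surface, qc_table = _binning_stage(cfg, pop, refs, rng)

    # ---- distances ----------------------------------------------------
    labels_aln, rows = pop.core_alignment()
    core_aln = CoreAlignment(labels_aln, rows)
    d_genetic = hamming_distance(core_aln)
    core_called = define_core_genes(pop.presence, threshold=0.95)
    d_gene = jaccard_gene_distance(pop.presence, excluded_genes=pop.operon_genes)
    divergence = functional_divergence_rate(d_gene, d_genetic, pop.subspecies_of)

    # ---- subspecies ---------------------------------------------------
    ps = prediction_strength(
        d_genetic,
        cfg.k_range,
        n_subsamples=cfg.ps_subsamples,
        internal_divisions=cfg.ps_divisions,
        seed=int(rng.integers(2**31)),
    )
    ps_table = pd.DataFrame(
        {
            "k": list(ps),
            "mean_ps": [float(np.mean(v)) for v in ps.values()],
            "sd_ps": [float(np.std(v)) for v in ps.values()],
        }
    ).set_index("k")
    k_selected = select_k(ps, cutoff=cfg.ps_cutoff)
    clustering = pam_cluster(d_genetic, k_selected)
    cluster_table = pd.DataFrame(
        {
            "genome": list(clustering.labels),
            "cluster": [clustering.labels[g] for g in clustering.labels],
            "truth": [pop.subspecies_of[g] for g in clustering.labels],
        }
    ).set_index("genome")

    # ---- diagnostic SNVs and abundance recovery ----------------------
    panel = derive_subspecies_snvs(core_aln, pop.subspecies_of)
    aln_of = dict(zip(labels_aln, rows))
    mix_members = [f"{names[0]}_001", f"{names[1]}_001"]
    abundance_rows = []
    offsets = {}
    off = 0
    for g in pop.core_genes:
        offsets[g] = off
        off += cfg.population.gene_length
    for mix in cfg.abundance_mixtures:
        mixture = [
            (m, p) for m, p in zip(mix_members, mix) if p > 0
        ]
        pileup = simulate_pileup(
            mixture,
            {
                g: {m: pop.genome(m).gene_sequence(g) for m, _ in mixture}
                for g in pop.core_genes
            },
            depth=cfg.abundance_depth,
            error_rate=0.002,
            seed=rng,
        )
        pileup = pileup.assign(
            column=lambda df: df.gene_id.map(offsets) + df.pos
        )
        counts = pileup.groupby("column")[["A", "C", "G", "T"]].sum().reset_index()
        est = estimate_subspecies_abundance(counts, panel)
        truth_by_sub = {s: 0.0 for s in names}
        for (m, p) in mixture:
            truth_by_sub[pop.subspecies_of[m]] += p
        for s in names:
            est_v = est.abundances.get(s)
            abundance_rows.append(
                (
                    "/".join(f"{p:g}" for p in mix),
                    s,
                    truth_by_sub[s],
                    est_v if est_v is not None else np.nan,
                    ";".join(est.qc_flags),
                )
            )
    abundance_table = pd.DataFrame(
        abundance_rows, columns=["mixture", "subspecies", "truth", "estimate", "qc_flags"]
    )

    # ---- operon analysis ---------------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    scalars: dict[str, float] = {}
    if pop.operon_genes:
        ref_motile = pop.genome(f"{names[1]}_000")  # subspecies with operon
        model = OperonModel.from_reference(
            "operon_1",
            ref_motile.sequence,
            ref_motile.genes,
            pop.operon_genes,
            pop.operon_border_genes[0],
            pop.operon_border_genes[1],
        )
        genome_contigs = {
            g.genome_id: {g.genome_id: g.sequence} for g in pop.genomes
        }
        operon_presence = operon_presence_matrix(genome_contigs, [model])
        tables["operon_presence"] = operon_presence
        located = locate_operon_by_borders(
            {ref_motile.genome_id: ref_motile.sequence}, model
        )
        scalars["operon_located_genes"] = (
            float(sum(located["genes"].values())) if located else 0.0
        )
        truth_vec = pd.Series(
            {g.genome_id: pop.operon_present[g.genome_id] for g in pop.genomes}
        )
        called_vec = operon_presence.mean(axis=0) > 0.5
        scalars["operon_recovery"] = float(
            (called_vec == truth_vec[called_vec.index]).mean()
        )

    # ---- island analysis ---------------------------------------------
    carriers = [g for g, v in pop.island_present.items() if v]
    if carriers:
        seed_genome = pop.genome(carriers[0])
        span = pop.island_span[carriers[0]]
        seed_seq = seed_genome.sequence[span[0] : span[1]]
        genome_contigs = {
            g.genome_id: {g.genome_id: g.sequence} for g in pop.genomes
        }
        calls, extracted = extract_island(genome_contigs, seed_seq)
        island_table = pd.DataFrame(
            [
                (
                    c.genome_id,
                    c.completeness,
                    c.length,
                    c.gc_island if c.gc_island is not None else np.nan,
                    c.gc_background if c.gc_background is not None else np.nan,
                )
                for c in calls.values()
            ],
            columns=["genome", "completeness", "length", "gc_island", "gc_background"],
        ).set_index("genome")
        tables["island_calls"] = island_table
        full = island_table[island_table.completeness == "full"]
        scalars["island_prevalence_called"] = float(
            len(full) / len(island_table)
        )
        scalars["island_prevalence_truth"] = float(
            np.mean([pop.island_present[g] for g in pop.island_present])
        )
        if len(full):
            scalars["island_gc_contrast"] = float(
                (full.gc_background - full.gc_island).mean()
            )
        profile = gc_profile(
            seed_genome.sequence, window=cfg.gc_window, step=cfg.gc_step
        )
        tables["gc_profile_carrier"] = profile.set_index("position")
        if len(extracted) >= 3:
            island_aln = CoreAlignment(
                sorted(extracted), [extracted[g] for g in sorted(extracted)]
            )
            core_subset = CoreAlignment(
                sorted(extracted), [aln_of[g] for g in sorted(extracted)]
            )
            cmp = compare_island_core(island_aln, core_subset, n_perm=999, seed=cfg.seed)
            scalars["island_core_mantel_r"] = cmp["mantel_r"]
            scalars["island_core_mantel_p"] = cmp["mantel_p"]
            scalars["median_island_distance"] = cmp["median_island"]
            scalars["median_core_distance"] = cmp["median_core"]
        try:
            up, down = discover_island_boundaries(
                genome_contigs,
                {g.genome_id: g.genes for g in pop.genomes},
                seed_seq,
                min_contig=cfg.island_min_contig,
                min_hit=min(30_000, int(0.6 * len(seed_seq))),
            )
            scalars["island_borders_found"] = 1.0
            tables["island_borders"] = pd.DataFrame(
                {"side": ["upstream", "downstream"], "gene": [up, down]}
            ).set_index("side")
        except ValueError as exc:
            logger.warning("island boundary scan failed: %s", exc)
            scalars["island_borders_found"] = 0.0

    # ---- isolation by distance ---------------------------------------
    points = [
        GeoPoint(s, *_DEFAULT_LOCATIONS.get(s, (0.0, 0.0))) for s in names
    ]
    routes = {}
    if "ErAfrica" in names and "ErAsia" in names:
        routes[("ErAfrica", "ErAsia")] = [_ARABIA]
    d_geo = geographic_distance_matrix(points, routes)
    med = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i >= j:
                continue
            ids_a = [g for g, s in pop.subspecies_of.items() if s == a]
            ids_b = [g for g, s in pop.subspecies_of.items() if s == b]
            ia = [d_genetic.labels.index(x) for x in ids_a]
            ib = [d_genetic.labels.index(x) for x in ids_b]
            med[i, j] = med[j, i] = float(
                np.median(d_genetic.values[np.ix_(ia, ib)])
            )
    d_med = DistanceMatrix(list(names), med)
    mantel_r, mantel_p = mantel_test(d_med, d_geo)
    scalars["geo_mantel_r"] = mantel_r
    scalars["geo_mantel_p"] = mantel_p

    # ---- vertical transmission ----------------------------------------
    n_t = cfg.n_transmitting

    def related_dist(r: np.random.Generator, size: int) -> np.ndarray:
        per_pair = size // cfg.n_mother_infant_pairs or 1
        vals = r.uniform(0.5, 1.5, size)
        for i in range(n_t):
            vals[i * per_pair] = r.uniform(0.0, 0.005)
        return vals

    pair_table = simulate_pair_table(
        cfg.n_mother_infant_pairs,
        cfg.n_unrelated,
        related_dist,
        lambda r, size: r.uniform(0.5, 1.5, size),
        seed=rng,
    )
    unrelated_vals = pair_table.loc[
        pair_table.relationship == "unrelated", "ngd"
    ].to_numpy()
    threshold = transmission_threshold(unrelated_vals)
    rate = transmission_rate(pair_table, threshold)
    scalars["transmission_threshold"] = threshold
    scalars["transmission_rate"] = rate
    scalars["unrelated_below_threshold"] = float(
        (unrelated_vals < threshold).mean()
    )

    # ---- assemble report ----------------------------------------------
    scalars["k_selected"] = float(k_selected)
    scalars["n_core_genes_called"] = float(len(core_called))
    scalars["hq_count"] = float(qc_table.hq.sum())
    scalars["binning_selected_identity"] = float(tuning["selected"][0])
    scalars["binning_selected_fraction"] = float(tuning["selected"][1])
    tables.update(
        {
            "binning_surface": surface,
            "qc": qc_table,
            "prediction_strength": ps_table,
            "clusters": cluster_table,
            "functional_divergence": divergence.set_index(["genome_a", "genome_b"]),
            "abundance": abundance_table.set_index(["mixture", "subspecies"]),
            "pair_table": pair_table.set_index(["sample_a", "sample_b", "timepoint"]),
        }
    )
    report = StudyReport(
        tables=tables,
        scalars=scalars,
        provenance={
            "seed": cfg.seed,
            "population": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(cfg.population).items()
                if not isinstance(v, (dict,))
            },
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
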