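"""PAM clustering, prediction strength, diagnostic SNV panels, and
subspecies abundance estimation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from strainscope import CoreAlignment, simulate_population
from strainscope.distances import DistanceMatrix
from strainscope.simulate import PopulationSimSpec, simulate_pileup
from strainscope.subspecies import (
    SNVPanel,
    assign_to_medoids,
    density_balanced_subsample,
    derive_subspecies_snvs,
    estimate_subspecies_abundance,
    pam_cluster,
    prediction_strength,
    select_k,
)


def _two_blob_matrix(n_per=5, intra=0.0, inter=1.0):
    n = 2 * n_per
    m = np.full((n, n), inter)
    m[:n_per, :n_per] = intra
    m[n_per:, n_per:] = intra
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix([f"g{i}" for i in range(n)], m)


class TestPAM:
    def test_two_identical_groups_perfect_split(self):
        d = _two_blob_matrix()
        res = pam_cluster(d, 2)
        assert res.objective == 0.0
        first = {res.labels[f"g{i}"] for i in range(5)}
        second = {res.labels[f"g{i}"] for i in range(5, 10)}
        assert len(first) == len(second) == 1 and first != second

    def test_k_equals_n(self):
        d = _two_blob_matrix(3, intra=0.5)
        res = pam_cluster(d, 6)
        assert res.objective == 0.0
        assert len(set(res.medoids)) == 6

    def test_k_bounds(self):
        d = _two_blob_matrix(2)
        with pytest.raises(ValueError):
            pam_cluster(d, 0)
        with pytest.raises(ValueError):
            pam_cluster(d, 5)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_bruteforce_small_n(self, k, rng):
        """BUILD+SWAP reaches the exhaustive-search optimum for n <= 8."""
        for trial in range(8):
            n = 7
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            d = DistanceMatrix([f"g{i}" for i in range(n)], m)
            res = pam_cluster(d, k)
            best = min(
                m[:, list(medoids)].min(axis=1).sum()
                for medoids in combinations(range(n), k)
            )
            assert res.objective == pytest.approx(best)

    def test_labels_stable_under_permutation(self, rng):
        d = _two_blob_matrix(4, intra=0.1)
        res = pam_cluster(d, 2)
        perm = rng.permutation(len(d.labels))
        d2 = DistanceMatrix(
            [d.labels[i] for i in perm], d.values[np.ix_(perm, perm)]
        )
        res2 = pam_cluster(d2, 2)
        groups1 = {}
        for g, c in res.labels.items():
            groups1.setdefault(c, set()).add(g)
        groups2 = {}
        for g, c in res2.labels.items():
            groups2.setdefault(c, set()).add(g)
        assert set(map(frozenset, groups1.values())) == set(
            map(frozenset, groups2.values())
        )


class TestPredictionStrength:
    def test_k1_is_one(self, rng):
        m = rng.random((20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = DistanceMatrix([f"g{i}" for i in range(20)], m)
        ps = prediction_strength(d, [1], n_subsamples=3, internal_divisions=2, seed=0)
        assert (ps[1] == 1.0).all()

    def test_two_separated_clusters(self, rng):
        n_per = 12
        m = np.full((2 * n_per, 2 * n_per), 10.0) + rng.random((2 * n_per, 2 * n_per))
        m = (m + m.T) / 2
        m[:n_per, :n_per] = rng.random((n_per, n_per))
        m[n_per:, n_per:] = rng.random((n_per, n_per))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        d = DistanceMatrix([f"g{i}" for i in range(2 * n_per)], m)
        ps = prediction_strength(
            d, [2], n_subsamples=10, internal_divisions=5, subsample_rate=0.8, seed=1
        )
        assert float(np.mean(ps[2])) > 0.95

    def test_scale_invariance(self, clustered_distances):
        d = clustered_distances
        scaled = DistanceMatrix(d.labels, d.values * 7.5)
        kwargs = dict(n_subsamples=4, internal_divisions=3, seed=5)
        ps1 = prediction_strength(d, [2, 4], **kwargs)
        ps2 = prediction_strength(scaled, [2, 4], **kwargs)
        for k in (2, 4):
            np.testing.assert_allclose(ps1[k], ps2[k])

    def test_four_subspecies_recovered(self, clustered_distances):
        """ps(4) > 0.8 on four-subspecies data with the observed
        divergence structure, and higher k fails the cutoff."""
        ps = prediction_strength(
            clustered_distances,
            [1, 2, 3, 4, 5, 6],
            n_subsamples=10,
            internal_divisions=8,
            seed=0,
        )
        assert float(np.mean(ps[4])) > 0.8
        assert select_k(ps) == 4

    def test_k_recovery_across_replicates(self):
        """The standard largest-k rule recovers k=4 in >= 90% of
        replicate populations."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            spec = PopulationSimSpec(
                n_genomes_per_subspecies=(15, 15, 15, 15),
                n_genes=80,
                gene_length=600,
                ancestral_length=56_000,
                island_present_in=None,
                operon_deleted_in=None,
                block_length=1_000,
                seed=100 + rep,
            )
            pop = simulate_population(spec)
            labels, rows = pop.core_alignment()
            from strainscope import hamming_distance

            d = hamming_distance(CoreAlignment(labels, rows))
            ps = prediction_strength(
                d, [1, 2, 3, 4, 5, 6], n_subsamples=6, internal_divisions=5, seed=rep
            )
            hits += select_k(ps) == 4
        assert hits >= 0.9 * n_rep


class TestSubsampleAndAssignment:
    def test_rate_one_identity(self):
        groups = {f"g{i}": ("dense" if i % 2 else "sparse") for i in range(30)}
        assert density_balanced_subsample(groups, ["dense"], rate=1.0) == list(groups)

    def test_untagged_never_dropped(self):
        groups = {f"g{i}": ("dense" if i < 500 else "rare") for i in range(600)}
        kept = density_balanced_subsample(groups, ["dense"], rate=0.5, seed=1)
        assert all(g in kept for g in groups if groups[g] == "rare")

    def test_binomial_count(self):
        groups = {f"g{i}": "dense" for i in range(1000)}
        kept = density_balanced_subsample(groups, ["dense"], rate=0.5, seed=2)
        sd = np.sqrt(1000 * 0.25)
        assert abs(len(kept) - 500) < 3 * sd

    def test_assign_matches_argmin(self, rng):
        medoids = ["m1", "m2", "m3"]
        dist = pd.DataFrame(
            rng.random((40, 3)), index=[f"g{i}" for i in range(40)], columns=medoids
        )
        labels = assign_to_medoids(dist, medoids)
        for g in dist.index:
            assert labels[g] == dist.loc[g].idxmin()

    def test_tie_breaks_to_lowest_medoid_id(self):
        dist = pd.DataFrame(
            {"m2": [0.5], "m1": [0.5]}, index=["g0"]
        )
        assert assign_to_medoids(dist, ["m2", "m1"])["g0"] == "m1"


def _toy_alignment():
    # 6 genomes, 2 subspecies; column 0 fixed-diagnostic for s1,
    # column 1 at 2/3 within s1 (not diagnostic), column 2 fixed
    # everywhere, column 3 diagnostic for s2
    rows = {
        "a1": "ACGT",
        "a2": "ACGT",
        "a3": "AAGT",
        "b1": "CCGA",
        "b2": "CCGA",
        "b3": "CCGA",
    }
    labels = {"a1": "s1", "a2": "s1", "a3": "s1", "b1": "s2", "b2": "s2", "b3": "s2"}
    return CoreAlignment(list(rows), list(rows.values())), labels


class TestSNVPanel:
    def test_fixed_column_diagnostic(self):
        aln, labels = _toy_alignment()
        panel = derive_subspecies_snvs(aln, labels)
        assert (0, "A") in panel.positions["s1"]
        assert (0, "C") in panel.positions["s2"]
        assert (3, "A") in panel.positions["s2"]
        assert all(col != 2 for col, _ in panel.positions["s1"])

    def test_in_frequency_cutoff(self):
        # base at 2/3 < 0.9 within s1 is not diagnostic
        aln, labels = _toy_alignment()
        panel = derive_subspecies_snvs(aln, labels)
        assert all(col != 1 for col, _ in panel.positions["s1"])

    def test_out_frequency_cutoff(self):
        # column 0: A fixed in s1 but present in 1/4 = 25% of s2 ->
        # fails the "absent in more than 90% of the rest" rule;
        # columns 1 and 2 are cleanly diagnostic so panels stay non-empty
        rows = {
            "a1": "AGT",
            "a2": "AGT",
            "b1": "ACG",
            "b2": "CCG",
            "b3": "CCG",
            "b4": "CCG",
        }
        labels = {k: ("s1" if k.startswith("a") else "s2") for k in rows}
        panel = derive_subspecies_snvs(
            CoreAlignment(list(rows), list(rows.values())), labels
        )
        assert (0, "A") not in panel.positions["s1"]
        assert (1, "G") in panel.positions["s1"]
        assert (2, "G") in panel.positions["s2"]

    def test_gap_columns_skipped(self):
        rows = {"a1": "A-T", "a2": "A-T", "b1": "C-T", "b2": "C-T"}
        labels = {"a1": "s1", "a2": "s1", "b1": "s2", "b2": "s2"}
        panel = derive_subspecies_snvs(CoreAlignment(list(rows), list(rows.values())), labels)
        assert all(col != 1 for sites in panel.positions.values() for col, _ in sites)

    def test_column_unique_per_subspecies(self, small_alignment, small_population):
        panel = derive_subspecies_snvs(
            small_alignment, small_population.subspecies_of
        )
        seen = {}
        for sub, sites in panel.positions.items():
            for col, base in sites:
                assert seen.setdefault((col, base), sub) == sub


def _counts_from_fractions(panel, fractions, depth=200):
    """Synthesize per-column base counts implied by subspecies fractions."""
    rows = {}
    for sub, sites in panel.positions.items():
        for col, base in sites:
            row = rows.setdefault(col, {"A": 0, "C": 0, "G": 0, "T": 0})
            row[base] += int(round(depth * fractions.get(sub, 0.0)))
    for col, row in rows.items():
        total = sum(row.values())
        if total < depth:  # remainder on an allele no subspecies claims
            others = [b for b in "ACGT" if row[b] == 0]
            row[others[0] if others else "A"] += depth - total
    return pd.DataFrame(
        [{"column": col, **row} for col, row in sorted(rows.items())]
    )


@pytest.fixture()
def panel():
    return SNVPanel(
        positions={
            "s1": [(i, "A") for i in range(0, 120)],
            "s2": [(i, "C") for i in range(120, 240)],
        }
    )


class TestAbundance:

    def test_pure_sample(self, panel):
        counts = _counts_from_fractions(panel, {"s1": 1.0, "s2": 0.0})
        est = estimate_subspecies_abundance(counts, panel)
        assert est.passed
        assert est.abundances["s1"] == pytest.approx(1.0)
        assert est.abundances["s2"] == pytest.approx(0.0)

    def test_seventy_thirty(self, panel):
        counts = _counts_from_fractions(panel, {"s1": 0.7, "s2": 0.3})
        est = estimate_subspecies_abundance(counts, panel)
        assert est.abundances["s1"] == pytest.approx(0.7, abs=0.1)
        assert est.abundances["s2"] == pytest.approx(0.3, abs=0.1)

    def test_sum_out_of_range_rejected(self, panel):
        counts = _counts_from_fractions(panel, {"s1": 0.9, "s2": 0.4})
        est = estimate_subspecies_abundance(counts, panel)
        assert est.abundances["s1"] is None
        assert "sum-range" in est.qc_flags

    def test_low_depth_rejected(self, panel):
        counts = _counts_from_fractions(panel, {"s1": 1.0}, depth=3)
        est = estimate_subspecies_abundance(counts, panel)
        assert not est.passed and "depth" in est.qc_flags

    def test_breadth_flag(self, panel):
        counts = _counts_from_fractions(panel, {"s1": 1.0, "s2": 0.0}, depth=40)
        # zero out coverage at 30% of positions
        counts.loc[counts.index[:72], ["A", "C", "G", "T"]] = 0
        est = estimate_subspecies_abundance(counts, panel)
        assert "breadth" in est.qc_flags

    def test_mixture_recovery_mae(self, small_population, small_alignment):
        """MAE < 0.05 across (1.0, 0.7/0.3, 0.5/0.5) mixtures at depth 60
        simulated from genome sequences (50 replicates)."""
        pop = small_population
        panel = derive_subspecies_snvs(small_alignment, pop.subspecies_of)
        g1, g2 = "ErAsia_001", "ErAfrica_001"
        offsets, off = {}, 0
        for g in pop.core_genes:
            offsets[g] = off
            off += pop.spec.gene_length
        genes = {
            g: {m: pop.genome(m).gene_sequence(g) for m in (g1, g2)}
            for g in pop.core_genes
        }
        errors = []
        rng = np.random.default_rng(17)
        for rep in range(50):
            target = [(1.0, 0.0), (0.7, 0.3), (0.5, 0.5)][rep % 3]
            mixture = [(m, p) for m, p in zip((g1, g2), target) if p > 0]
            pileup = simulate_pileup(
                mixture,
                {g: genes[g] for g in pop.core_genes},
                depth=60,
                error_rate=0.002,
                seed=rng,
            )
            pileup = pileup.assign(column=pileup.gene_id.map(offsets) + pileup.pos)
            counts = pileup.groupby("column")[["A", "C", "G", "T"]].sum().reset_index()
            est = estimate_subspecies_abundance(counts, panel)
            assert est.passed, est.qc_flags
            truth = {pop.subspecies_of[g1]: target[0], pop.subspecies_of[g2]: target[1]}
            for sub, val in est.abundances.items():
                errors.append(abs(val - truth.get(sub, 0.0)))
        assert float(np.mean(errors)) < 0.05
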