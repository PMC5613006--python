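"""Unit and property tests for the synthetic two-strain generator."""

import numpy as np
import pytest

from strainpair import sim
from strainpair._util import revcomp


def hamming_frac(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / max(len(a), 1)


class TestAncestor:
    def test_gc_and_length(self):
        anc = sim.simulate_ancestor([100_000], gc_content=0.36, seed=1)
        seq = anc.sequences["chr1"]
        assert len(seq) == 100_000
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.36) < 0.02

    def test_degenerate_composition(self):
        anc = sim.simulate_ancestor([1000], gc_content=0.0, seed=7)
        assert set(anc.sequences["chr1"]) <= {"A", "T"}

    def test_deterministic(self):
        a = sim.simulate_ancestor([2000], gc_content=0.4, seed=5)
        b = sim.simulate_ancestor([2000], gc_content=0.4, seed=5)
        assert a.sequences == b.sequences

    @pytest.mark.parametrize("bad", [[0], [500], [-10]])
    def test_rejects_short_chromosomes(self, bad):
        with pytest.raises(ValueError):
            sim.simulate_ancestor(bad, seed=1)


class TestDiverge:
    def test_identity_when_all_rates_zero(self):
        anc = sim.simulate_ancestor([5000], seed=2)
        model = sim.DivergenceModel(snp_rate=0.0, small_indel_rate=0.0, sv_counts={}, seed=3)
        C, R, truth = sim.diverge(anc, model)
        assert C.sequences == anc.sequences == R.sequences
        assert truth.records == []

    def test_insertion_length_bookkeeping(self):
        anc = sim.simulate_ancestor([60_000], seed=4)
        model = sim.DivergenceModel(
            snp_rate=0.0, small_indel_rate=0.0, sv_counts={"insertion": 5}, seed=5
        )
        C, R, truth = sim.diverge(anc, model)
        ins_C = sum(r.end - r.start for r in truth.records if r.branch == "C")
        ins_R = sum(r.end - r.start for r in truth.records if r.branch == "R")
        assert len(C.sequences["chr1"]) - len(anc.sequences["chr1"]) == ins_C
        assert len(R.sequences["chr1"]) - len(anc.sequences["chr1"]) == ins_R

    def test_snp_rate_within_binomial_ci(self):
        anc = sim.simulate_ancestor([100_000], seed=6)
        model = sim.DivergenceModel(snp_rate=0.01, small_indel_rate=0.0, sv_counts={}, seed=7)
        C, R, _ = sim.diverge(anc, model)
        # no structural edits: alignment is positional
        p = hamming_frac(C.sequences["chr1"], R.sequences["chr1"])
        # two branches at rate/2 each; coincident hits negligible; 99% CI
        n = 100_000
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(p - 0.01) < 2.58 * se + 1e-4

    def test_truth_coordinates_match_sequence_content(self, diverged_pair):
        C, R, truth = diverged_pair
        strains = {"C": C, "R": R}
        for r in truth.records:
            seg = strains[r.strain].sequences[r.chrom][r.start : r.end]
            if r.event_class == "deletion":
                # surviving copy equals ancestor segment modulo its branch SNPs
                assert len(seg) == r.anc_end - r.anc_start
            elif r.event_class == "tandem_duplication":
                half = len(seg) // 2
                assert seg[:half] == seg[half:]
            elif r.event_class == "inversion":
                partner = strains[r.partner_strain].sequences[r.chrom][
                    r.partner_start : r.partner_end
                ]
                assert hamming_frac(seg, revcomp(partner)) < 0.03
            elif r.event_class == "transposition":
                partner = strains[r.partner_strain].sequences[r.chrom][
                    r.partner_start : r.partner_end
                ]
                assert hamming_frac(seg, partner) < 0.03

    def test_bit_reproducible(self, small_ancestor):
        model = sim.DivergenceModel(
            snp_rate=0.004, sv_counts={"insertion": 2, "inversion": 1}, seed=9
        )
        out1 = sim.diverge(small_ancestor, model)
        out2 = sim.diverge(small_ancestor, model)
        assert out1[0].sequences == out2[0].sequences
        assert out1[1].sequences == out2[1].sequences
        assert out1[2].records == out2[2].records

    def test_unplaceable_svs_raise(self):
        anc = sim.simulate_ancestor([3000], seed=1)
        model = sim.DivergenceModel(
            sv_counts={"deletion": 50}, sv_size_dist={"deletion": (500, 600)}, seed=2
        )
        with pytest.raises((ValueError, RuntimeError)):
            sim.diverge(anc, model)


class TestFragment:
    def test_single_piece_is_identity(self):
        anc = sim.simulate_ancestor([5000], seed=3)
        frag = sim.fragment(anc, 1, min_piece=1000, seed=4)
        assert list(frag.sequences.values()) == [anc.sequences["chr1"]]
        assert frag.adjacencies == []

    def test_conservation_and_adjacency_count(self):
        anc = sim.simulate_ancestor([10_000], seed=5)
        frag = sim.fragment(anc, 4, min_piece=1000, seed=6)
        assert sum(len(s) for s in frag.sequences.values()) == 10_000
        assert len(frag.adjacencies) == 3
        # reconstruct from source table
        rows = sorted(frag.source, key=lambda r: r[5])
        rebuilt = "".join(
            frag.sequences[sid] if o == "+" else revcomp(frag.sequences[sid])
            for sid, _, _, _, o, _ in rows
        )
        assert rebuilt == anc.sequences["chr1"]

    def test_deterministic(self):
        anc = sim.simulate_ancestor([8000], seed=7)
        f1 = sim.fragment(anc, (2, 5), min_piece=500, seed=8)
        f2 = sim.fragment(anc, (2, 5), min_piece=500, seed=8)
        assert f1.sequences == f2.sequences and f1.adjacencies == f2.adjacencies

    def test_min_piece_too_large(self):
        anc = sim.simulate_ancestor([2000], seed=9)
        with pytest.raises(ValueError):
            sim.fragment(anc, 4, min_piece=1000, seed=1)


class TestDepth:
    def test_flat_depth_without_svs(self, snp_only_pair):
        _, C, _, truth = snp_only_pair
        t = sim.simulate_depth(C, truth, "C", mean_depth=30, noise_sd=2, window=100, seed=1)
        v = t.values["chr1"]
        assert np.all(np.abs(v - 30) < 4 * 2 + 1)

    def test_cross_strain_depth_zero_in_specific_sequence(self, diverged_pair):
        C, R, truth = diverged_pair
        t = sim.simulate_depth(C, truth, "R", mean_depth=30, noise_sd=2, window=100, seed=2)
        for r in truth.by_class("insertion"):
            if r.strain == "C":
                assert t.median_over(r.chrom, r.start, r.end) < 1.0

    def test_duplication_depth_conserved(self, diverged_pair):
        C, R, truth = diverged_pair
        strains = {"C": C, "R": R}
        for r in truth.by_class("tandem_duplication"):
            t = sim.simulate_depth(
                strains[r.strain], truth, r.strain, mean_depth=30, noise_sd=2, window=100, seed=3
            )
            m = float(np.mean(t.window_depths(r.chrom, r.start, r.end)))
            assert abs(m - t.genome_median()) < 0.2 * t.genome_median()

    def test_collapsed_decoy_doubles_depth(self, diverged_pair):
        C, R, truth = diverged_pair
        strains = {"C": C, "R": R}
        for r in truth.by_class("collapsed_duplication"):
            t = sim.simulate_depth(
                strains[r.strain], truth, r.strain, mean_depth=30, noise_sd=2, window=100, seed=4
            )
            m = float(np.mean(t.window_depths(r.chrom, r.start, r.end)))
            assert m > 1.6 * t.genome_median()

    def test_bad_window_rejected(self, snp_only_pair):
        _, C, _, truth = snp_only_pair
        with pytest.raises(ValueError):
            sim.simulate_depth(C, truth, "C", window=0)


class TestPopulations:
    def test_zero_divergence_fst_near_zero(self):
        from strainpair import popgen

        gm = sim.simulate_populations(
            sim.PopulationSimSpec(n_individuals_per_pop=9, n_sites=5000,
                                  between_pop_divergence=0.0, seed=1)
        )
        assert -0.05 < popgen.weighted_fst(gm).genome_wide < 0.05

    def test_mt_vs_nuclear_contrast(self):
        from strainpair import popgen

        gm = sim.simulate_populations(
            sim.PopulationSimSpec(
                n_individuals_per_pop=9, n_sites=4000, between_pop_divergence=0.02,
                mt_locus=sim.MtLocusSpec(n_sites=40, n_fixed=30), seed=2,
            )
        )
        mt = popgen.weighted_fst(gm.subset_sites(gm.chrom == "mt")).genome_wide
        nuc = popgen.weighted_fst(gm.subset_sites(gm.chrom != "mt")).genome_wide
        assert mt > 0.8
        assert nuc < 0.1
        assert mt > 10 * max(nuc, 1e-6)

    def test_divergence_out_of_range(self):
        with pytest.raises(ValueError):
            sim.PopulationSimSpec(between_pop_divergence=1.5)

    def test_positions_strictly_increasing_required(self):
        with pytest.raises(ValueError):
            sim.PopulationSimSpec(n_sites=3, site_positions=np.array([10, 10, 30]))


class TestPlantGenes:
    CATS = {"detox": 0.15, "digestion": 0.15, "other": 0.7}

    def test_no_genes(self):
        genes = sim.plant_genes({"chr1": 50_000}, 0, self.CATS, seed=1)
        assert genes == []

    def test_too_many_genes_raise(self):
        with pytest.raises(RuntimeError):
            sim.plant_genes({"chr1": 2000}, 50, self.CATS, seed=2)

    def test_null_factor_balanced_categories(self):
        regions = {"chr1": [(0, 200_000)]}
        genes = sim.plant_genes(
            {"chr1": 400_000}, 300, self.CATS, sv_enrichment_factor=1.0,
            truth=regions, gene_size=(300, 900), seed=3,
        )
        inside = [g for g in genes if g.start < 200_000]
        outside = [g for g in genes if g.start >= 200_000]
        f_in = sum(g.category == "detox" for g in inside) / max(len(inside), 1)
        f_out = sum(g.category == "detox" for g in outside) / max(len(outside), 1)
        assert abs(f_in - f_out) < 0.12

    def test_genes_do_not_overlap(self):
        genes = sim.plant_genes({"chr1": 100_000}, 100, self.CATS, seed=4)
        genes.sort(key=lambda g: g.start)
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start
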