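"""Diversity, Fst, permutation, tree and dN/dS tests with independent oracles."""

import itertools
import math

import numpy as np
import pytest

from strainpair import popgen, sim
from strainpair.sim import GenotypeMatrix


def gm_from_dosage(dosage, pops, chrom="n", pos=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    return GenotypeMatrix(
        samples=[f"i{k}" for k in range(n_samples)],
        pops=np.asarray(pops, dtype=object),
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, n_sites + 1)),
        dosage=dosage,
    )


# ---------------------------------------------------------------------------
# oracle: scalar transcription of the Weir & Cockerham (1984) two-pop formulas


def wc_fst_oracle(dosage, pops):
    a_sum = d_sum = 0.0
    labels = sorted(set(pops))
    r = 2
    for site in np.asarray(dosage):
        n, p, h = [], [], []
        for lab in labels:
            g = [x for x, pp in zip(site, pops) if pp == lab and x >= 0]
            if len(g) < 2:
                break
            n.append(len(g))
            p.append(sum(g) / (2 * len(g)))
            h.append(sum(1 for x in g if x == 1) / len(g))
        else:
            n1, n2 = n
            pbar = (n1 * p[0] + n2 * p[1]) / (n1 + n2)
            if pbar <= 0 or pbar >= 1:
                continue
            nbar = (n1 + n2) / 2
            nc = (n1 + n2) - (n1 * n1 + n2 * n2) / (n1 + n2)
            s2 = (n1 * (p[0] - pbar) ** 2 + n2 * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h[0] + n2 * h[1]) / (n1 + n2)
            a = (nbar / nc) * (
                s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            a_sum += a
            d_sum += a + b + c
    return a_sum / d_sum if d_sum else float("nan")


# ---------------------------------------------------------------------------
# oracle: NG86 site/difference counting by explicit enumeration

_BASES = "TCAG"


def ng86_oracle(c1, c2, table):
    syn_sites = []
    for codon in (c1, c2):
        s = 0.0
        for pos in range(3):
            for b in _BASES:
                if b != codon[pos]:
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if table[alt] == table[codon]:
                        s += 1 / 3
        syn_sites.append(s)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if table[nxt] == "*" and step < len(order) - 1:
                ok = False
            sd, nd = sd + (table[nxt] == table[cur]), nd + (table[nxt] != table[cur])
            cur = nxt
        paths.append((ok, sd, nd))
    valid = [(s, n) for ok, s, n in paths if ok] or [(s, n) for _, s, n in paths]
    return (
        (syn_sites[0] + syn_sites[1]) / 2,
        sum(s for s, _ in valid) / len(valid),
        sum(n for _, n in valid) / len(valid),
    )


class TestDiversity:
    def test_monomorphic_zero(self):
        gm = gm_from_dosage(np.zeros((5, 4)), ["C"] * 2 + ["R"] * 2)
        st = popgen.diversity(gm, "total", 100)
        assert st.theta_w == 0 and st.pi == 0

    def test_hand_fixture_two_diploids(self):
        # 2 diploids -> n = 4 chromosomes, a_4 = 1 + 1/2 + 1/3 = 11/6
        dosage = np.zeros((11, 2), dtype=np.int8)
        dosage[:, 0] = 1
        gm = gm_from_dosage(dosage, ["C", "C"])
        st = popgen.diversity(gm, "total", 1000)
        assert st.S == 11
        assert st.theta_w == pytest.approx(11 / ((11 / 6) * 1000))
        assert st.theta_w == pytest.approx(0.006)

    def test_empty_group_rejected(self):
        gm = gm_from_dosage(np.zeros((3, 2)), ["C", "C"])
        with pytest.raises(ValueError):
            popgen.diversity(gm, "R", 100)

    def test_neutral_coalescent_calibration(self):
        """theta_w and pi track the scaled mutation rate of neutral coalescent sims."""
        msprime = pytest.importorskip("msprime")
        theta = 0.01
        L = 20_000
        tw, pp = [], []
        for seed in range(1, 31):
            ts = msprime.sim_ancestry(
                samples=9, ploidy=2, population_size=1000, sequence_length=L,
                random_seed=seed,
            )
            mts = msprime.sim_mutations(
                ts, rate=theta / (4 * 1000), random_seed=seed + 1000,
                model=msprime.BinaryMutationModel(), discrete_genome=False,
            )
            gmat = mts.genotype_matrix()  # sites x (2*9) haplotypes
            dosage = (gmat[:, ::2] + gmat[:, 1::2]).astype(np.int8)
            gm = gm_from_dosage(dosage, ["C"] * 9)
            st = popgen.diversity(gm, "C", L)
            tw.append(st.theta_w)
            pp.append(st.pi)
        for est in (tw, pp):
            se = np.std(est, ddof=1) / math.sqrt(len(est))
            assert abs(np.mean(est) - theta) < 3 * se + 1e-4


class TestWeightedFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(1)
        dosage = rng.binomial(2, 0.4, size=(5000, 18)).astype(np.int8)
        gm = gm_from_dosage(dosage, ["C"] * 9 + ["R"] * 9)
        assert -0.05 < popgen.weighted_fst(gm).genome_wide < 0.05

    def test_fixed_differences_fst_one(self):
        dosage = np.zeros((50, 18), dtype=np.int8)
        dosage[:, 9:] = 2
        gm = gm_from_dosage(dosage, ["C"] * 9 + ["R"] * 9)
        assert popgen.weighted_fst(gm).genome_wide == pytest.approx(1.0)

    def test_printed_toy_matches_oracle(self):
        # 2 pops x 4 diploids, 3 sites, dosages written out explicitly
        dosage = np.array(
            [
                [0, 1, 2, 1, 2, 2, 1, 2],
                [0, 0, 1, 0, 1, 2, 2, 1],
                [1, 1, 0, 0, 0, 1, 0, 0],
            ],
            dtype=np.int8,
        )
        pops = ["C"] * 4 + ["R"] * 4
        gm = gm_from_dosage(dosage, pops)
        got = popgen.weighted_fst(gm).genome_wide
        assert got == pytest.approx(wc_fst_oracle(dosage, pops), abs=1e-12)

    def test_random_instances_match_oracle_with_missingness(self, rng):
        for _ in range(5):
            dosage = rng.binomial(2, rng.uniform(0.1, 0.9, size=(40, 1)), size=(40, 12)).astype(
                np.int8
            )
            dosage[rng.random(dosage.shape) < 0.1] = -1
            pops = ["C"] * 6 + ["R"] * 6
            gm = gm_from_dosage(dosage, pops)
            got = popgen.weighted_fst(gm).genome_wide
            want = wc_fst_oracle(dosage, pops)
            assert got == pytest.approx(want, abs=1e-10)

    def test_bad_window(self, pop_matrix):
        with pytest.raises(ValueError):
            popgen.weighted_fst(pop_matrix, window=0)

    def test_windows_are_ratio_of_sums(self, pop_matrix):
        res = popgen.weighted_fst(pop_matrix, window=1000)
        a, b, c, keep = res.a, res.b, res.c, res.keep
        tot = (a + b + c)[keep].sum()
        assert res.genome_wide == pytest.approx(a[keep].sum() / tot)
        assert (res.windows["end"] - res.windows["start"] == 1000).all()


class TestRandomization:
    def test_strong_structure_minimal_p(self):
        gm = sim.simulate_populations(
            sim.PopulationSimSpec(n_individuals_per_pop=9, n_sites=800,
                                  between_pop_divergence=0.2, seed=5)
        )
        p, obs, perms = popgen.fst_randomization(gm, n_reps=200, seed=1)
        assert p == pytest.approx(1 / 201)
        assert obs > max(perms)

    def test_invariant_to_global_relabel(self, pop_matrix):
        p1, _, _ = popgen.fst_randomization(pop_matrix, n_reps=30, seed=9)
        swapped = pop_matrix.relabel(
            np.array(["C" if p == "R" else "R" for p in pop_matrix.pops], dtype=object)
        )
        p2, _, _ = popgen.fst_randomization(swapped, n_reps=30, seed=9)
        assert p1 == p2

    def test_default_replicates(self):
        import inspect

        assert inspect.signature(popgen.fst_randomization).parameters["n_reps"].default == 200


class TestDistanceAndTree:
    def test_identical_and_opposite(self):
        dosage = np.array([[0, 0, 2], [2, 2, 0], [1, 1, 1]], dtype=np.int8)
        gm = gm_from_dosage(dosage, ["C", "C", "R"])
        ids, mat = popgen.genotype_distance(gm)
        assert mat[0, 1] == 0.0
        # sites (|0-2|/2, |2-0|/2, |1-1|/2) -> mean 2/3
        assert mat[0, 2] == pytest.approx(2 / 3)

    def test_hand_toy(self):
        dosage = np.array([[0, 1, 2], [0, 2, 2], [-1, 0, 0]], dtype=np.int8)
        gm = gm_from_dosage(dosage, ["C", "C", "R"])
        _, mat = popgen.genotype_distance(gm)
        # pair (0,1): |0-1|/2 and |0-2|/2, third site missing for sample 0
        assert mat[0, 1] == pytest.approx((0.5 + 1.0) / 2)
        # pair (1,2): |1-2|/2, |2-2|/2, |0-0|/2 over three shared sites
        assert mat[1, 2] == pytest.approx(0.5 / 3)

    def test_zero_shared_sites_error_names_pair(self):
        dosage = np.array([[0, -1], [-1, 2]], dtype=np.int8)
        gm = gm_from_dosage(dosage, ["C", "R"])
        with pytest.raises(ValueError, match="i0.*i1"):
            popgen.genotype_distance(gm)

    def test_nj_recovers_additive_tree(self):
        # additive 4-taxon matrix with split (a,b)|(c,d); verify four-point condition
        ids = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0.0, 0.3, 1.1, 1.2],
                [0.3, 0.0, 1.0, 1.1],
                [1.1, 1.0, 0.0, 0.3],
                [1.2, 1.1, 0.3, 0.0],
            ]
        )
        assert d[0, 1] + d[2, 3] < min(d[0, 2] + d[1, 3], d[0, 3] + d[1, 2])
        tree = popgen.nj_tree(ids, d)
        splits = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            popgen.nj_tree(["a", "b"], np.zeros((2, 2)))

    def test_bootstrap_supports_strain_split(self):
        gm = sim.simulate_populations(
            sim.PopulationSimSpec(n_individuals_per_pop=6, n_sites=1500,
                                  between_pop_divergence=0.1, seed=8)
        )
        dt = popgen.bootstrap_consensus(gm, n_boot=100, seed=2)
        C_ids = [s for s, p in zip(gm.samples, gm.pops) if p == "C"]
        assert dt.has_clade(C_ids)
        assert dt.clade_support(C_ids) >= 0.9
        assert all(0.0 <= v <= 1.0 for v in dt.supports.values())

    def test_default_bootstrap_count(self):
        import inspect

        assert inspect.signature(popgen.bootstrap_consensus).parameters["n_boot"].default == 1000


class TestDnDs:
    def test_identical_sequences(self):
        r = popgen.pairwise_dnds("ATGGCTAAA", "ATGGCTAAA")
        assert r.dN == 0 and r.dS == 0 and math.isnan(r.ratio)

    def test_single_synonymous_change(self):
        a = "ATG" + "GCT" * 28 + "TTT"
        b = "ATG" + "GCT" * 28 + "TTC"
        r = popgen.pairwise_dnds(a, b)
        assert r.dN == 0 and r.dS > 0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            popgen.pairwise_dnds("ATGA", "ATGC")
        with pytest.raises(ValueError):
            popgen.pairwise_dnds("ATG", "ATGGCT")
        with pytest.raises(ValueError):
            popgen.pairwise_dnds("TAAGCT", "TAAGCT")  # internal stop

    def test_counts_match_enumeration_oracle(self, rng):
        codons = [c for c in popgen.CODON_TABLE if popgen.CODON_TABLE[c] != "*"]
        for _ in range(100):
            n = 30
            ca = [codons[i] for i in rng.integers(0, len(codons), size=n)]
            cb = [
                codons[int(rng.integers(0, len(codons)))] if rng.random() < 0.3 else x
                for x in ca
            ]
            a, b = "".join(ca), "".join(cb)
            r = popgen.pairwise_dnds(a, b)
            S = Sd = Nd = 0.0
            for i in range(n):
                s, sd, nd = ng86_oracle(a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3],
                                        popgen.CODON_TABLE)
                S += s
                Sd += sd
                Nd += nd
            assert r.S == pytest.approx(S)
            assert r.Sd == pytest.approx(Sd)
            assert r.Nd == pytest.approx(Nd)
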