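"""Anchor finding, chain DP (vs exhaustive oracle) and netting tests."""

import itertools

import numpy as np
import pytest

from strainpair import align
from strainpair._util import revcomp


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# oracles


def brute_force_best_chain_score(anchors, gap_open, gap_per_bp, max_gap):
    """Best colinear-subset score by exhaustive enumeration (<= ~12 anchors)."""
    best = 0.0
    n = len(anchors)
    for mask in range(1, 1 << n):
        subset = [anchors[i] for i in range(n) if mask >> i & 1]
        subset.sort(key=lambda a: a.q_start)
        ok = True
        score = subset[0].length
        for a, b in zip(subset, subset[1:]):
            qg = b.q_start - a.q_end
            if a.strand == "+":
                tg = b.t_start - a.t_end
            else:
                tg = a.t_start - b.t_end
            if qg < 0 or tg < 0 or qg > max_gap or tg > max_gap:
                ok = False
                break
            cost = 0.0 if (qg == 0 and tg == 0) else gap_open + gap_per_bp * (qg + tg)
            score += b.length - cost
        if ok and score > best:
            best = score
    return best


def net_reference(chains, target_lengths, overlap_tol=50):
    """Independent re-statement of the greedy netting rule (brute force scans)."""
    order = sorted(chains, key=lambda c: (-c.score, c.q_chrom, c.q_start, c.id))
    levels = {}
    placed = []
    for c in order:
        ts, te = c.t_span
        lvl1 = [p for p in placed if levels[p.id] == 1 and p.t_chrom == c.t_chrom]
        if all(min(te, p.t_end) - max(ts, p.t_start) <= overlap_tol for p in lvl1):
            levels[c.id] = 1
            placed.append(c)
            continue
        for p in placed:
            if p.t_chrom != c.t_chrom:
                continue
            if any(gs <= ts and te <= ge for gs, ge in p.t_gaps()):
                levels[c.id] = levels[p.id] + 1
                placed.append(c)
                break
    return levels


def make_anchor(q0, q1, t0, t1, strand="+", q_chrom="q", t_chrom="t"):
    return align.Anchor(q_chrom, q0, q1, t_chrom, t0, t1, strand)


# ---------------------------------------------------------------------------
# find_anchors


class TestFindAnchors:
    def test_identical_sequences_single_anchor(self, rng):
        s = random_seq(rng, 5000)
        anchors = align.find_anchors({"a": s}, {"b": s}, k=15)
        assert len(anchors) == 1
        a = anchors[0]
        assert a.strand == "+"
        assert a.length >= 4990  # whole length up to rare non-unique k-mers

    def test_reverse_complement_minus_anchor(self, rng):
        s = random_seq(rng, 4000)
        anchors = align.find_anchors({"a": s}, {"b": revcomp(s)}, k=15)
        assert len(anchors) == 1
        assert anchors[0].strand == "-"
        assert anchors[0].q_start == 0 and anchors[0].t_start == 0

    def test_tandem_repeat_excluded_by_uniqueness(self, rng):
        k = 15
        unit = random_seq(rng, 1000)
        left, right = random_seq(rng, 2000), random_seq(rng, 2000)
        s = left + unit + unit + right
        anchors = align.find_anchors({"a": s}, {"b": s}, k=k)
        # brute-force census: k-mers occurring more than once must not be anchored
        census = {}
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            census[min(km, revcomp(km))] = census.get(min(km, revcomp(km)), 0) + 1
        repeat_pos = {
            i for i in range(len(s) - k + 1) if census[min(s[i : i + k], revcomp(s[i : i + k]))] > 1
        }
        covered = set()
        for a in anchors:
            covered.update(range(a.q_start, a.q_end - k + 1))
        assert not (covered & repeat_pos)

    @pytest.mark.parametrize("k", [10, 12, 20])
    def test_even_or_small_k_rejected(self, k):
        with pytest.raises(ValueError):
            align.find_anchors({"a": "ACGT" * 100}, {"b": "ACGT" * 100}, k=k)

    def test_k_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            align.find_anchors({"a": "ACGTACGTACGTA"}, {"b": "ACGTACGTACGTA"}, k=15)


# ---------------------------------------------------------------------------
# chain_anchors


class TestChainAnchors:
    def test_single_anchor_chain(self):
        chains = align.chain_anchors([make_anchor(0, 100, 0, 100)])
        assert len(chains) == 1
        assert chains[0].score == 100

    def test_crossing_anchors_split(self):
        a = make_anchor(0, 100, 1000, 1100)
        b = make_anchor(200, 300, 0, 100)  # target goes backwards on + strand
        chains = align.chain_anchors([a, b])
        assert len(chains) == 2

    def test_empty_input(self):
        assert align.chain_anchors([]) == []

    def test_matches_exhaustive_oracle_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 11))
            anchors = []
            for _ in range(n):
                q0 = int(rng.integers(0, 5000))
                ln = int(rng.integers(20, 200))
                t0 = int(rng.integers(0, 5000))
                anchors.append(make_anchor(q0, q0 + ln, t0, t0 + ln))
            chains = align.chain_anchors(anchors, gap_open=50, gap_per_bp=0.5, max_gap=2000)
            got = max(c.score for c in chains)
            want = brute_force_best_chain_score(anchors, 50, 0.5, 2000)
            assert got == pytest.approx(want)


# ---------------------------------------------------------------------------
# netting


class TestNet:
    def test_two_disjoint_chains_level1(self):
        c1 = align.Chain(1, "q", "t", "+", [make_anchor(0, 100, 0, 100)], 100)
        c2 = align.Chain(2, "q", "t", "+", [make_anchor(0, 100, 500, 600)], 100)
        net = align.build_net([c1, c2], {"t": 1000})
        assert {e.level for e in net.entries} == {1}

    def test_contained_low_score_not_in_gap_discarded(self):
        big = align.Chain(
            1, "q", "t", "+",
            [make_anchor(0, 400, 0, 400), make_anchor(500, 900, 500, 900)], 800,
        )
        # overlaps big's covered target, not inside its (400,500) gap
        low = align.Chain(2, "q2", "t", "+", [make_anchor(0, 200, 100, 300)], 200)
        net = align.build_net([big, low], {"t": 1000})
        assert net.entry(2) is None

    def test_gap_nesting_level2(self):
        big = align.Chain(
            1, "q", "t", "+",
            [make_anchor(0, 400, 0, 400), make_anchor(500, 900, 500, 900)], 800,
        )
        nested = align.Chain(2, "q2", "t", "+", [make_anchor(0, 80, 410, 490)], 80)
        net = align.build_net([big, nested], {"t": 1000})
        e = net.entry(2)
        assert e.level == 2 and e.parent_chain_id == 1

    def test_target_outside_lengths_rejected(self):
        c = align.Chain(1, "q", "t", "+", [make_anchor(0, 100, 900, 1000)], 100)
        with pytest.raises(ValueError):
            align.build_net([c], {"t": 500})

    def test_matches_reference_implementation_on_random_chains(self, rng):
        for rep in range(20):
            chains = []
            for i in range(20):
                t0 = int(rng.integers(0, 3000))
                ln = int(rng.integers(50, 600))
                n_anch = int(rng.integers(1, 4))
                anchors = []
                step = ln // n_anch
                for j in range(n_anch):
                    s = t0 + j * step
                    e = s + max(step - int(rng.integers(0, step // 2 + 1)), 10)
                    anchors.append(make_anchor(s, e, s, e))
                chains.append(
                    align.Chain(i + 1, "q", "t", "+", anchors, float(rng.integers(10, 1000)))
                )
            net = align.build_net(chains, {"t": 5000})
            got = {e.chain_id: e.level for e in net.entries}
            want = net_reference(chains, {"t": 5000})
            assert got == want


class TestReciprocalBest:
    def test_single_chain_kept(self):
        c = align.Chain(1, "q", "t", "+", [make_anchor(0, 100, 0, 100)], 100)
        netB = align.build_net([c], {"t": 200})
        netA = align.build_net([c.swapped()], {"q": 200})
        assert align.reciprocal_best(netB, netA) == {1}

    def test_empty_nets(self):
        netB = align.build_net([], {"t": 100})
        netA = align.build_net([], {"q": 100})
        assert align.reciprocal_best(netB, netA) == set()

    def test_duplication_resolved_to_single_pair(self):
        # two query regions chain to one target region; only the higher-scoring
        # chain is top-level in the target-referenced net
        c1 = align.Chain(1, "q", "t", "+", [make_anchor(0, 300, 0, 300)], 300)
        c2 = align.Chain(2, "q", "t", "+", [make_anchor(1000, 1200, 0, 200)], 200)
        netB = align.build_net([c1, c2], {"t": 400})
        netA = align.build_net([c1.swapped(), c2.swapped()], {"q": 2000})
        rb = align.reciprocal_best(netB, netA)
        assert rb == {1}

    def test_id_mismatch_rejected(self):
        c1 = align.Chain(1, "q", "t", "+", [make_anchor(0, 100, 0, 100)], 100)
        c2 = align.Chain(2, "q", "t", "+", [make_anchor(0, 100, 0, 100)], 100)
        netB = align.build_net([c1], {"t": 200})
        netA = align.build_net([c2.swapped()], {"q": 200})
        with pytest.raises(ValueError):
            align.reciprocal_best(netB, netA)


class TestSymmetryAndCoverage:
    def test_reciprocal_best_symmetric_under_role_swap(self, snp_only_pair):
        _, C, R, _ = snp_only_pair
        ga1 = align.align_genomes(C, R)
        ga2 = align.align_genomes(R, C)
        spans1 = sorted(
            (c.q_chrom, c.q_start, c.t_start, c.strand) for c in ga1.rbest_chains()
        )
        spans2 = sorted(
            (c.t_chrom, c.t_start, c.q_start, c.strand) for c in ga2.rbest_chains()
        )
        assert spans1 == spans2

    def test_snp_only_divergence_covered_by_rbest(self, snp_only_pair):
        _, C, R, _ = snp_only_pair
        ga = align.align_genomes(C, R)
        cov = np.zeros(len(C.sequences["chr1"]), dtype=bool)
        for c in ga.rbest_chains():
            for a in c.anchors:
                cov[a.q_start : a.q_end] = True
        assert cov.mean() >= 0.95
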