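"""Study-condition benchmark experiments with ground-truth scoring.

Each function generates synthetic data under the package's standard study
conditions, runs the corresponding pipeline stage, and measures recovery or
calibration against planted truth or an independent reference enumeration.
The reference implementations here (exhaustive chain enumeration, explicit
hypergeometric tail, per-codon pathway enumeration) are deliberately naive
re-statements used only for comparison, never by the pipeline itself.
"""

from __future__ import annotations

import itertools
import math
from math import comb

import numpy as np

from . import align, enrich, popgen, scaffold, sim, sv
from ._util import substream

# ---------------------------------------------------------------------------
# 1. chain DP vs exhaustive colinear-subset enumeration


def _exhaustive_best_chain(anchors, gap_open, gap_per_bp, max_gap):
    best = 0.0
    n = len(anchors)
    for mask in range(1, 1 << n):
        subset = sorted(
            (anchors[i] for i in range(n) if mask >> i & 1), key=lambda a: a.q_start
        )
        score = subset[0].length
        ok = True
        for x, y in zip(subset, subset[1:]):
            qg = y.q_start - x.q_end
            tg = (y.t_start - x.t_end) if x.strand == "+" else (x.t_start - y.t_end)
            if qg < 0 or tg < 0 or qg > max_gap or tg > max_gap:
                ok = False
                break
            score += y.length - (
                0.0 if (qg == 0 and tg == 0) else gap_open + gap_per_bp * (qg + tg)
            )
        if ok:
            best = max(best, score)
    return best


def chaining_oracle_check(seed: int, n_instances: int = 100, max_anchors: int = 12) -> dict:
    rng = substream(seed, "chain_oracle")
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, max_anchors + 1))
        anchors = []
        for _ in range(n):
            q0 = int(rng.integers(0, 6000))
            ln = int(rng.integers(20, 250))
            t0 = int(rng.integers(0, 6000))
            anchors.append(align.Anchor("q", q0, q0 + ln, "t", t0, t0 + ln, "+"))
        chains = align.chain_anchors(anchors, gap_open=50, gap_per_bp=0.5, max_gap=2500)
        got = max(c.score for c in chains)
        want = _exhaustive_best_chain(anchors, 50, 0.5, 2500)
        agree += int(abs(got - want) < 1e-9)
    return {"agreement": agree / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# 2. reference-guided scaffolder recovery


def scaffolder_recovery(
    seed: int, n_seeds: int = 20, chrom_len: int = 1_000_000, n_pieces: int = 4
) -> dict:
    hits = total = 0
    conserved = 0
    for i in range(n_seeds):
        srng = substream(seed, "scaffold", i)
        s0 = int(srng.integers(0, 2**31 - 4))
        anc = sim.simulate_ancestor([chrom_len], seed=s0)
        model = sim.DivergenceModel(snp_rate=0.005, sv_counts={}, seed=s0 + 1)
        C, R, _ = sim.diverge(anc, model)
        frag = sim.fragment(C, n_pieces, min_piece=50_000, seed=s0 + 2)
        ga = align.align_genomes(frag, R)
        fc = scaffold.filter_chains(ga.chains, ga.rbest, min_span=800)
        plan = scaffold.plan_joins(fc, frag, R)
        h, t = scaffold.score_adjacencies(plan, frag.adjacencies)
        hits += h
        total += t
        out, _ = scaffold.emit_pseudoscaffolds(plan, frag)
        non_n = sum(len(s) - s.count("N") for s in out.values())
        conserved += int(non_n == sum(len(s) for s in frag.sequences.values()))
    return {
        "adjacency_recovery": hits / total,
        "n_adjacencies": total,
        "bp_conserved_fraction": conserved / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# 3. structural-variant recovery with depth validation


def sv_recovery(
    seed: int,
    chrom_lengths=(1_000_000, 1_000_000),
    events_per_class: int = 10,
    decoys: int = 4,
    mean_depth: float = 30.0,
) -> dict:
    rng = substream(seed, "sv_recovery")
    s0 = int(rng.integers(0, 2**31 - 4))
    anc = sim.simulate_ancestor(list(chrom_lengths), seed=s0)
    model = sim.DivergenceModel(
        snp_rate=0.005,
        small_indel_rate=0.0002,
        sv_counts={c: events_per_class for c in sim.SV_CLASSES},
        sv_size_dist={c: (500, 2000) for c in sim.SV_CLASSES},
        decoy_collapsed=decoys,
        seed=s0 + 1,
    )
    C, R, truth = sim.diverge(anc, model)
    tracks = sim.depth_track_set(C, R, truth, mean_depth=mean_depth, seed=s0 + 2)
    res = sv.scan_structural_variants(C, R, tracks)
    score = sv.score_sv_recovery(res, truth, min_ro=0.5)
    per = score["per_class"]
    return {
        "per_class": per,
        "precision_min": min(d["precision"] for d in per.values()),
        "recall_min": min(d["recall"] for d in per.values()),
        "decoy_rejection": score.get("decoy_rejection", float("nan")),
        "n_events": events_per_class * len(sim.SV_CLASSES),
    }


# ---------------------------------------------------------------------------
# 4. estimator calibration


def diversity_calibration(seed: int, n_reps: int = 50, theta: float = 0.01) -> dict:
    """theta_w / pi on neutral coalescent simulations (msprime as the
    independent generator)."""
    import msprime

    L = 20_000
    tw, pp = [], []
    rng = substream(seed, "theta")
    for _ in range(n_reps):
        s = int(rng.integers(1, 2**31 - 2))
        ts = msprime.sim_ancestry(
            samples=9, ploidy=2, population_size=1000, sequence_length=L, random_seed=s
        )
        mts = msprime.sim_mutations(
            ts,
            rate=theta / (4 * 1000),
            random_seed=s + 1,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
        g = mts.genotype_matrix()
        dosage = (g[:, ::2] + g[:, 1::2]).astype(np.int8)
        gm = sim.GenotypeMatrix(
            samples=[f"i{k}" for k in range(9)],
            pops=np.array(["C"] * 9, dtype=object),
            chrom=np.full(dosage.shape[0], "n", dtype=object),
            pos=np.arange(1, dosage.shape[0] + 1),
            dosage=dosage,
        )
        st = popgen.diversity(gm, "C", L)
        tw.append(st.theta_w)
        pp.append(st.pi)
    out = {"theta_true": theta, "n_reps": n_reps}
    for name, est in (("theta_w", tw), ("pi", pp)):
        se = float(np.std(est, ddof=1) / math.sqrt(n_reps))
        out[f"{name}_mean"] = float(np.mean(est))
        out[f"{name}_se"] = se
        out[f"{name}_z"] = (float(np.mean(est)) - theta) / se
    return out


def fst_calibration(
    seed: int, targets=(0.0, 0.02, 0.1, 0.3), n_seeds: int = 20, n_sites: int = 10_000
) -> dict:
    rng = substream(seed, "fst_calib")
    errs = {}
    for F in targets:
        vals = []
        for _ in range(n_seeds):
            s = int(rng.integers(0, 2**31 - 1))
            gm = sim.simulate_populations(
                sim.PopulationSimSpec(
                    n_individuals_per_pop=9,
                    n_sites=n_sites,
                    between_pop_divergence=F,
                    seed=s,
                )
            )
            vals.append(popgen.weighted_fst(gm).genome_wide)
        errs[F] = abs(float(np.mean(vals)) - F)
    return {
        "abs_error_by_target": errs,
        "max_abs_error": max(errs.values()),
        "n": n_seeds * len(targets),
    }


# ---------------------------------------------------------------------------
# 5. permutation-test calibration


def randomization_calibration(
    seed: int, n_datasets: int = 200, n_reps: int = 200, n_sites: int = 1000
) -> dict:
    rng = substream(seed, "type1")
    rejections = 0
    for _ in range(n_datasets):
        s = int(rng.integers(0, 2**31 - 2))
        gm = sim.simulate_populations(
            sim.PopulationSimSpec(
                n_individuals_per_pop=9, n_sites=n_sites, between_pop_divergence=0.0, seed=s
            )
        )
        p, _, _ = popgen.fst_randomization(gm, n_reps=n_reps, seed=s + 1)
        rejections += int(p <= 0.05)
    # strongly structured data attains the minimum p
    gm = sim.simulate_populations(
        sim.PopulationSimSpec(
            n_individuals_per_pop=9, n_sites=n_sites, between_pop_divergence=0.2,
            seed=int(rng.integers(0, 2**31 - 2)),
        )
    )
    p_min, _, _ = popgen.fst_randomization(gm, n_reps=n_reps, seed=7)
    return {
        "type1_rate": rejections / n_datasets,
        "n_datasets": n_datasets,
        "min_p": p_min,
        "theoretical_min_p": 1.0 / (n_reps + 1),
    }


# ---------------------------------------------------------------------------
# 6. tree behaviour


def nj_additive_check() -> dict:
    """NJ on an exactly additive 4-taxon matrix recovers topology and path lengths."""
    ids = ["a", "b", "c", "d"]
    # tree ((a:1,b:2):1.5,(c:0.5,d:2.5)) -> additive distances
    d = np.array(
        [
            [0.0, 3.0, 3.0, 5.0],
            [3.0, 0.0, 4.0, 6.0],
            [3.0, 4.0, 0.0, 3.0],
            [5.0, 6.0, 3.0, 0.0],
        ]
    )
    tree = popgen.nj_tree(ids, d)
    splits = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
    split_ok = frozenset({"a", "b"}) in splits or frozenset({"c", "d"}) in splits
    td = tree.tip_tip_distances(ids)
    path_ok = bool(np.allclose(np.asarray(td.data), d, atol=1e-9))
    return {"topology_recovered": float(split_ok), "path_lengths_exact": float(path_ok)}


def strain_monophyly(
    seed: int,
    n_seeds: int = 20,
    fst_target: float = 0.1,
    n_sites: int = 1500,
    n_boot: int = 200,
    min_support: float = 0.9,
) -> dict:
    rng = substream(seed, "monophyly")
    ok = 0
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 2))
        gm = sim.simulate_populations(
            sim.PopulationSimSpec(
                n_individuals_per_pop=9,
                n_sites=n_sites,
                between_pop_divergence=fst_target,
                seed=s,
            )
        )
        dt = popgen.bootstrap_consensus(gm, n_boot=n_boot, seed=s + 1)
        C_ids = [x for x, p in zip(gm.samples, gm.pops) if p == "C"]
        if dt.has_clade(C_ids) and dt.clade_support(C_ids) >= min_support:
            ok += 1
    return {"monophyly_rate": ok / n_seeds, "n_seeds": n_seeds, "n_boot": n_boot}


# ---------------------------------------------------------------------------
# 7. exact-arithmetic fixtures


def _hypergeom_tail(a, b, c, d):
    row1, col1, n = a + b, a + c, a + b + c + d
    tot = comb(n, col1)
    return sum(
        comb(row1, x) * comb(n - row1, col1 - x) / tot for x in range(a, min(row1, col1) + 1)
    )


def _ng86_codon_reference(c1, c2):
    table = popgen.CODON_TABLE
    syn = []
    for codon in (c1, c2):
        s = sum(
            1 / 3
            for pos in range(3)
            for bch in "TCAG"
            if bch != codon[pos]
            and table[codon[:pos] + bch + codon[pos + 1 :]] == table[codon]
        )
        syn.append(s)
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if table[nxt] == "*" and step < len(order) - 1:
                ok = False
            if table[nxt] == table[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((ok, sd, nd))
    valid = [(s, n) for ok, s, n in paths if ok] or [(s, n) for _, s, n in paths]
    return (
        (syn[0] + syn[1]) / 2,
        sum(s for s, _ in valid) / len(valid),
        sum(n for _, n in valid) / len(valid),
    )


def exact_fixture_checks(seed: int, n_codon_pairs: int = 100) -> dict:
    n50 = scaffold.assembly_stats([100, 90, 50, 40, 20]).n50_bp

    part_in = {f"i{k}" for k in range(10)}
    part_out = {f"o{k}" for k in range(90)}
    cats = {g: ("cat" if i < 8 else "other") for i, g in enumerate(sorted(part_in))}
    cats.update({g: ("cat" if i < 10 else "other") for i, g in enumerate(sorted(part_out))})
    df = enrich.category_enrichment((part_in, part_out), cats)
    p_fisher = float(df[df.category == "cat"].iloc[0].p)
    fisher_err = abs(p_fisher - _hypergeom_tail(8, 2, 10, 80))

    bh = enrich.bh_adjust([0.01, 0.02, 0.03, 0.04])
    bh_err = float(np.max(np.abs(bh - 0.04)))

    rng = substream(seed, "ng86")
    codons = [c for c, a in popgen.CODON_TABLE.items() if a != "*"]
    agree = 0
    for _ in range(n_codon_pairs):
        n = 30
        ca = [codons[int(i)] for i in rng.integers(0, len(codons), size=n)]
        cb = [
            codons[int(rng.integers(0, len(codons)))] if rng.random() < 0.3 else x for x in ca
        ]
        a, b = "".join(ca), "".join(cb)
        r = popgen.pairwise_dnds(a, b)
        S = Sd = Nd = 0.0
        for i in range(n):
            s, sd, nd = _ng86_codon_reference(a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3])
            S, Sd, Nd = S + s, Sd + sd, Nd + nd
        if (
            abs(r.S - S) < 1e-9 and abs(r.Sd - Sd) < 1e-9 and abs(r.Nd - Nd) < 1e-9
        ):
            agree += 1
    return {
        "n50_fixture": n50,
        "fisher_abs_err": fisher_err,
        "bh_fixture_abs_err": bh_err,
        "ng86_agreement": agree / n_codon_pairs,
        "n_codon_pairs": n_codon_pairs,
    }


# ---------------------------------------------------------------------------
# 8. enrichment FDR control and power


_ENRICH_CATS = {
    "detox": 0.12,
    "digestion": 0.12,
    "chemosensory": 0.12,
    "transport": 0.12,
    "other": 0.52,
}


def _one_enrichment_sim(seed, factor):
    rng = np.random.default_rng(seed)
    L = 600_000
    regions = []
    pos = 2000
    while len(regions) < 60 and pos < L - 5000:
        regions.append((pos, pos + 3000))
        pos += 3000 + int(rng.integers(3000, 12_000))
    region_map = {"chr1": regions}
    genes = sim.plant_genes(
        {"chr1": L},
        300,
        _ENRICH_CATS,
        sv_enrichment_factor=factor,
        truth=region_map,
        enriched_category="detox" if factor != 1.0 else None,
        gene_size=(300, 900),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    part = enrich.genes_in_regions(genes, region_map)
    cats = {g.gene_id: g.category for g in genes}
    return enrich.category_enrichment(part, cats), len(part[0])


def enrichment_fdr_null(seed: int, n_seeds: int = 100) -> dict:
    rng = substream(seed, "fdr_null")
    sig = tot = 0
    for _ in range(n_seeds):
        df, _ = _one_enrichment_sim(int(rng.integers(0, 2**31 - 1)), factor=1.0)
        sig += int((df.q < 0.05).sum())
        tot += len(df)
    return {"significant_fraction": sig / tot, "n_seeds": n_seeds, "n_tests": tot}


def enrichment_power(seed: int, n_seeds: int = 50, factor: float = 4.0) -> dict:
    rng = substream(seed, "power")
    hit = 0
    min_in = 10**9
    for _ in range(n_seeds):
        df, n_in = _one_enrichment_sim(int(rng.integers(0, 2**31 - 1)), factor=factor)
        min_in = min(min_in, n_in)
        row = df[df.category == "detox"].iloc[0]
        hit += int(row.q < 0.05)
    return {"power": hit / n_seeds, "n_seeds": n_seeds, "min_genes_in_sv": min_in}
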