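"""Whole-genome anchor alignment: exact-match anchors, colinear chains, nets.

A desk-scale pairwise aligner in the chain/net tradition: unique exact k-mer
matches are merged into anchors, anchors are chained by dynamic programming
under an affine-ish gap model, chains are organised into a hierarchical net
per target genome (level 1 = best non-overlapping cover, deeper levels fill
parent gaps), and the chains that are top-level with either genome as target
form the reciprocal-best one-to-one alignment map.

Coordinates are 0-based half-open. Anchors on the ``-`` strand pair an
ascending query interval with a descending target interval.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from ._util import kmer_codes, rc_kmer_codes, seq_to_codes


@dataclass(frozen=True)
class Anchor:
    """An exact gapless match between the two genomes."""

    q_chrom: str
    q_start: int
    q_end: int
    t_chrom: str
    t_start: int
    t_end: int
    strand: str

    @property
    def length(self) -> int:
        return self.q_end - self.q_start

    def swapped(self) -> "Anchor":
        return Anchor(
            self.t_chrom, self.t_start, self.t_end,
            self.q_chrom, self.q_start, self.q_end, self.strand,
        )


@dataclass
class Chain:
    """A colinear, monotone set of anchors scored as match bp minus gap costs."""

    id: int
    q_chrom: str
    t_chrom: str
    strand: str
    anchors: list[Anchor]
    score: float

    @property
    def q_start(self) -> int:
        return self.anchors[0].q_start

    @property
    def q_end(self) -> int:
        return self.anchors[-1].q_end

    @property
    def t_start(self) -> int:
        return min(a.t_start for a in (self.anchors[0], self.anchors[-1]))

    @property
    def t_end(self) -> int:
        return max(a.t_end for a in (self.anchors[0], self.anchors[-1]))

    @property
    def q_span(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def t_span(self) -> tuple[int, int]:
        return (self.t_start, self.t_end)

    @property
    def aligned_bp(self) -> int:
        return sum(a.length for a in self.anchors)

    def swapped(self) -> "Chain":
        anchors = [a.swapped() for a in self.anchors]
        anchors.sort(key=lambda a: a.q_start)
        return Chain(self.id, self.t_chrom, self.q_chrom, self.strand, anchors, self.score)

    def t_gaps(self) -> list[tuple[int, int]]:
        """Target-space gaps between consecutive anchors (sorted by target)."""
        iv = sorted((a.t_start, a.t_end) for a in self.anchors)
        return [(e0, s1) for (_, e0), (s1, _) in zip(iv, iv[1:]) if s1 > e0]


# ---------------------------------------------------------------------------
# anchors


def _genome_seqs(genome) -> dict[str, str]:
    return genome.sequences if hasattr(genome, "sequences") else dict(genome)


def _kmer_catalog(seqs: dict[str, str], k: int):
    """Canonical k-mer codes with positions for every chromosome."""
    codes_l, chrom_l, pos_l, fwd_l = [], [], [], []
    for ci, (chrom, seq) in enumerate(sorted(seqs.items())):
        codes = seq_to_codes(seq)
        fwd = kmer_codes(codes, k)
        if fwd.size == 0:
            continue
        rc = rc_kmer_codes(fwd, k)
        canon = np.minimum(fwd, rc)
        codes_l.append(canon)
        fwd_l.append(fwd <= rc)
        pos_l.append(np.arange(fwd.size, dtype=np.int64))
        chrom_l.append(np.full(fwd.size, ci, dtype=np.int32))
    sentinel = np.uint64(1) << np.uint64(63)
    canon = np.concatenate(codes_l)
    ok = canon != sentinel
    return {
        "chrom_names": [c for c, _ in sorted(seqs.items())],
        "canon": canon[ok],
        "is_fwd": np.concatenate(fwd_l)[ok],
        "pos": np.concatenate(pos_l)[ok],
        "chrom": np.concatenate(chrom_l)[ok],
    }


def find_anchors(genome_A, genome_B, k: int = 21, max_occ: int = 1) -> list[Anchor]:
    """Exact k-mer matches occurring at most ``max_occ`` times in each genome.

    With the default ``max_occ=1`` every anchor is a merged run of k-mers
    unique in both genomes (both strands scanned), which doubles as an
    implicit repeat filter. ``max_occ >= 2`` additionally emits the secondary
    matches needed to see copy-number differences.
    """
    if k < 11 or k % 2 == 0:
        raise ValueError("k must be odd and >= 11")
    seqs_A, seqs_B = _genome_seqs(genome_A), _genome_seqs(genome_B)
    shortest = min(len(s) for s in list(seqs_A.values()) + list(seqs_B.values()))
    if k > shortest:
        raise ValueError(f"k={k} exceeds the shortest sequence ({shortest} bp)")

    cat_A = _kmer_catalog(seqs_A, k)
    cat_B = _kmer_catalog(seqs_B, k)

    order_A = np.argsort(cat_A["canon"], kind="stable")
    order_B = np.argsort(cat_B["canon"], kind="stable")
    sa, sb = cat_A["canon"][order_A], cat_B["canon"][order_B]
    codes_A, starts_A, counts_A = np.unique(sa, return_index=True, return_counts=True)
    codes_B, starts_B, counts_B = np.unique(sb, return_index=True, return_counts=True)

    keep_A = counts_A <= max_occ
    keep_B = counts_B <= max_occ
    shared, ia, ib = np.intersect1d(
        codes_A[keep_A], codes_B[keep_B], assume_unique=True, return_indices=True
    )
    st_A, ct_A = starts_A[keep_A][ia], counts_A[keep_A][ia]
    st_B, ct_B = starts_B[keep_B][ib], counts_B[keep_B][ib]

    # dominant unique-unique case, fully vectorised
    uu = (ct_A == 1) & (ct_B == 1)
    idx_A = order_A[st_A[uu]]
    idx_B = order_B[st_B[uu]]
    pairs = [
        (
            cat_A["chrom"][idx_A],
            cat_A["pos"][idx_A],
            cat_B["chrom"][idx_B],
            cat_B["pos"][idx_B],
            cat_A["is_fwd"][idx_A] == cat_B["is_fwd"][idx_B],
        )
    ]
    # multi-copy codes: small python loop
    multi = np.flatnonzero(~uu)
    if multi.size:
        qa_c, qa_p, tb_c, tb_p, ss = [], [], [], [], []
        for m in multi.tolist():
            ja = order_A[st_A[m] : st_A[m] + ct_A[m]]
            jb = order_B[st_B[m] : st_B[m] + ct_B[m]]
            for x in ja.tolist():
                for y in jb.tolist():
                    qa_c.append(cat_A["chrom"][x])
                    qa_p.append(cat_A["pos"][x])
                    tb_c.append(cat_B["chrom"][y])
                    tb_p.append(cat_B["pos"][y])
                    ss.append(cat_A["is_fwd"][x] == cat_B["is_fwd"][y])
        pairs.append(
            (
                np.asarray(qa_c, dtype=np.int32),
                np.asarray(qa_p, dtype=np.int64),
                np.asarray(tb_c, dtype=np.int32),
                np.asarray(tb_p, dtype=np.int64),
                np.asarray(ss, dtype=bool),
            )
        )

    qc = np.concatenate([p[0] for p in pairs])
    qp = np.concatenate([p[1] for p in pairs])
    tc = np.concatenate([p[2] for p in pairs])
    tp = np.concatenate([p[3] for p in pairs])
    same = np.concatenate([p[4] for p in pairs])

    anchors: list[Anchor] = []
    names_A, names_B = cat_A["chrom_names"], cat_B["chrom_names"]
    for plus in (True, False):
        sel = same if plus else ~same
        if not np.any(sel):
            continue
        q_c, q_p, t_c, t_p = qc[sel], qp[sel], tc[sel], tp[sel]
        diag = (t_p - q_p) if plus else (t_p + q_p)
        order = np.lexsort((q_p, diag, t_c, q_c))
        q_c, q_p, t_c, t_p, diag = (x[order] for x in (q_c, q_p, t_c, t_p, diag))
        new_run = np.ones(q_p.size, dtype=bool)
        if q_p.size > 1:
            same_grp = (
                (q_c[1:] == q_c[:-1]) & (t_c[1:] == t_c[:-1]) & (diag[1:] == diag[:-1])
            )
            near = (q_p[1:] - q_p[:-1]) <= k
            new_run[1:] = ~(same_grp & near)
        starts = np.flatnonzero(new_run)
        ends = np.append(starts[1:], q_p.size) - 1
        for s_i, e_i in zip(starts.tolist(), ends.tolist()):
            q0, q1 = int(q_p[s_i]), int(q_p[e_i]) + k
            if plus:
                t0, t1 = int(t_p[s_i]), int(t_p[e_i]) + k
            else:
                t0, t1 = int(t_p[e_i]), int(t_p[s_i]) + k
            anchors.append(
                Anchor(
                    names_A[int(q_c[s_i])], q0, q1,
                    names_B[int(t_c[s_i])], t0, t1,
                    "+" if plus else "-",
                )
            )
    anchors.sort(key=lambda a: (a.q_chrom, a.q_start, a.t_chrom, a.t_start, a.strand))
    return anchors


# ---------------------------------------------------------------------------
# chaining


def _gap_cost(qg: int, tg: int, gap_open: float, gap_per_bp: float) -> float:
    if qg == 0 and tg == 0:
        return 0.0
    return gap_open + gap_per_bp * (qg + tg)


def chain_anchors(
    anchors: list[Anchor],
    gap_open: float = 50.0,
    gap_per_bp: float = 0.5,
    max_gap: int = 10000,
) -> list[Chain]:
    """Greedy extraction of maximal-scoring colinear chains.

    Within each (query chromosome, target chromosome, strand) group a sparse
    DP over anchors sorted by query start finds the best chain (transitions
    allowed when both coordinate gaps are within ``max_gap``); its anchors are
    removed and the DP repeats until no positive-score chain remains. Each
    anchor therefore joins at most one chain.
    """
    groups: dict[tuple, list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.q_chrom, a.t_chrom, a.strand), []).append(a)

    chains: list[Chain] = []
    for (q_chrom, t_chrom, strand), grp in sorted(groups.items()):
        grp.sort(key=lambda a: (a.q_start, a.t_start))
        n = len(grp)
        q_starts = [a.q_start for a in grp]
        q_ends = [a.q_end for a in grp]
        t_starts = [a.t_start for a in grp]
        t_ends = [a.t_end for a in grp]
        lens = [a.length for a in grp]
        max_len = max(lens)
        active = [True] * n
        n_active = n
        plus = strand == "+"
        while n_active > 0:
            dp = [0.0] * n
            parent = [-1] * n
            best_i, best_s = -1, 0.0
            for i in range(n):
                if not active[i]:
                    continue
                qi, ti_s, ti_e = q_starts[i], t_starts[i], t_ends[i]
                best_prev, best_j = 0.0, -1
                lo = bisect_left(q_starts, qi - max_gap - max_len)
                for j in range(lo, i):
                    if not active[j]:
                        continue
                    qg = qi - q_ends[j]
                    if qg < 0 or qg > max_gap:
                        continue
                    tg = (ti_s - t_ends[j]) if plus else (t_starts[j] - ti_e)
                    if tg < 0 or tg > max_gap:
                        continue
                    cand = dp[j] - _gap_cost(qg, tg, gap_open, gap_per_bp)
                    if cand > best_prev:
                        best_prev, best_j = cand, j
                dp[i] = lens[i] + best_prev
                parent[i] = best_j
                if dp[i] > best_s:
                    best_s, best_i = dp[i], i
            if best_i < 0 or best_s <= 0.0:
                break
            members = []
            i = best_i
            while i >= 0:
                members.append(i)
                active[i] = False
                n_active -= 1
                i = parent[i]
            members.reverse()
            chains.append(
                Chain(0, q_chrom, t_chrom, strand, [grp[i] for i in members], best_s)
            )
    chains.sort(key=lambda c: (-c.score, c.q_chrom, c.q_start, c.t_chrom, c.t_start))
    for i, c in enumerate(chains):
        c.id = i + 1
    return chains


# ---------------------------------------------------------------------------
# netting


@dataclass
class NetEntry:
    chain_id: int
    level: int
    parent_chain_id: int | None
    t_chrom: str
    t_interval: tuple[int, int]


@dataclass
class Net:
    """Hierarchical placement of chains in one genome's (target) space."""

    entries: list[NetEntry]
    chains: dict[int, Chain] = field(repr=False)
    target_lengths: dict[str, int] = field(default_factory=dict)
    target: str = ""

    def level1_ids(self) -> set[int]:
        return {e.chain_id for e in self.entries if e.level == 1}

    def entry(self, chain_id: int) -> NetEntry | None:
        for e in self.entries:
            if e.chain_id == chain_id:
                return e
        return None


def build_net(
    chains: list[Chain], target_lengths: dict[str, int], overlap_tol: int = 50
) -> Net:
    """Place chains greedily by descending score into a hierarchical net.

    A chain becomes level 1 if its target interval overlaps every
    already-placed level-1 interval on that chromosome by at most
    ``overlap_tol`` bp; otherwise it nests (level = parent + 1) inside the
    first placed chain whose inter-anchor target gap fully contains it, and is
    discarded if neither applies. Tie-break: score desc, then query
    chromosome/start, then id.
    """
    for c in chains:
        L = target_lengths.get(c.t_chrom)
        if L is None or c.t_start < 0 or c.t_end > L:
            raise ValueError(f"chain {c.id} target span outside declared lengths ({c.t_chrom})")
    order = sorted(chains, key=lambda c: (-c.score, c.q_chrom, c.q_start, c.id))
    entries: list[NetEntry] = []
    level1: dict[str, list[tuple[int, int]]] = {}
    placed: list[tuple[Chain, int]] = []
    for c in order:
        ts, te = c.t_span
        ok1 = all(
            min(te, e) - max(ts, s) <= overlap_tol for s, e in level1.get(c.t_chrom, [])
        )
        if ok1:
            entries.append(NetEntry(c.id, 1, None, c.t_chrom, (ts, te)))
            level1.setdefault(c.t_chrom, []).append((ts, te))
            placed.append((c, 1))
            continue
        nested = False
        for parent, lvl in placed:
            if parent.t_chrom != c.t_chrom:
                continue
            for gs, ge in parent.t_gaps():
                if gs <= ts and te <= ge:
                    entries.append(NetEntry(c.id, lvl + 1, parent.id, c.t_chrom, (ts, te)))
                    placed.append((c, lvl + 1))
                    nested = True
                    break
            if nested:
                break
        # chains neither top-level nor nested are discarded
    return Net(entries=entries, chains={c.id: c for c in chains}, target_lengths=dict(target_lengths))


def reciprocal_best(net_AB: Net, net_BA: Net) -> set[int]:
    """Chain ids that are level 1 with either genome as target (one-to-one map)."""
    if set(net_AB.chains) != set(net_BA.chains):
        raise ValueError("nets were not built from the same chain set")
    return net_AB.level1_ids() & net_BA.level1_ids()


# ---------------------------------------------------------------------------
# genome-level convenience


@dataclass
class GenomeAlignment:
    """Chains (query = A, target = B) plus the two nets and the 1:1 chain set."""

    name_A: str
    name_B: str
    chains: list[Chain]
    net_A: Net  # A as target (coordinate-swapped chains)
    net_B: Net  # B as target
    rbest: set[int]

    def chain(self, chain_id: int) -> Chain:
        return self.net_B.chains[chain_id]

    def rbest_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.id in self.rbest]


def align_genomes(
    genome_A,
    genome_B,
    k: int = 21,
    gap_open: float = 50.0,
    gap_per_bp: float = 0.5,
    max_gap: int = 10000,
    overlap_tol: int = 50,
    max_occ: int = 1,
    name_A: str = "A",
    name_B: str = "B",
) -> GenomeAlignment:
    """Anchor, chain and net two genomes in both orientations."""
    seqs_A, seqs_B = _genome_seqs(genome_A), _genome_seqs(genome_B)
    anchors = find_anchors(seqs_A, seqs_B, k=k, max_occ=max_occ)
    chains = chain_anchors(anchors, gap_open=gap_open, gap_per_bp=gap_per_bp, max_gap=max_gap)
    lengths_A = {c: len(s) for c, s in seqs_A.items()}
    lengths_B = {c: len(s) for c, s in seqs_B.items()}
    net_B = build_net(chains, lengths_B, overlap_tol=overlap_tol)
    swapped = [c.swapped() for c in chains]
    net_A = build_net(swapped, lengths_A, overlap_tol=overlap_tol)
    rbest = reciprocal_best(net_B, net_A)
    if name_A == "A":  # default: take the genome's own name when it has one
        name_A = getattr(genome_A, "name", name_A)
    if name_B == "B":
        name_B = getattr(genome_B, "name", name_B)
    return GenomeAlignment(
        name_A=name_A, name_B=name_B, chains=chains, net_A=net_A, net_B=net_B, rbest=rbest
    )
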