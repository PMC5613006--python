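"""Strain population genetics: diversity, Fst, distance trees, dN/dS.

Diversity is summarised by Watterson's theta (S / (a_n L)) and nucleotide
diversity pi (mean per-site pairwise difference); both are reported because
they estimate the same population-scaled mutation rate under neutrality and
their comparison is itself informative. Differentiation uses the Weir &
Cockerham (1984) two-population variance components with ratio-of-sums
("weighted") aggregation over sites and 1 kb windows, a label-permutation
null for significance, genotype-sharing distance matrices with
neighbour-joining trees and site-bootstrap supports, and a Nei-Gojobori
(1986) pairwise dN/dS with Jukes-Cantor correction for coding sequence pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from ._util import substream
from .sim import GenotypeMatrix

# ---------------------------------------------------------------------------
# diversity


@dataclass
class DiversityStats:
    group: str
    S: int
    L: int
    n_chromosomes: int
    a_n: float
    theta_w: float
    pi: float


def _group_dosage(gm: GenotypeMatrix, group: str) -> np.ndarray:
    if group == "total":
        return gm.dosage
    mask = gm.pop_mask(group)
    if not mask.any():
        raise ValueError(f"no samples in group {group!r}")
    return gm.dosage[:, mask]


def diversity(gm: GenotypeMatrix, group: str, L: int) -> DiversityStats:
    """Watterson's theta and pi per site over a callable length ``L``.

    S counts sites segregating within the group; a_n = sum_{i<n} 1/i with
    n = 2 x (diploid individuals in the group); pi is the mean per-site
    unbiased expected heterozygosity between sampled chromosomes.
    """
    d = _group_dosage(gm, group)
    n_dip = d.shape[1]
    n = 2 * n_dip
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    called = d >= 0
    alt = np.where(called, d, 0).sum(axis=1)
    tot = 2 * called.sum(axis=1)
    seg = (alt > 0) & (alt < tot)
    S = int(seg.sum())
    if L < S:
        raise ValueError(f"callable length {L} < segregating sites {S}")
    a_n = float(sum(1.0 / i for i in range(1, n)))
    with np.errstate(divide="ignore", invalid="ignore"):
        het = 2.0 * alt * (tot - alt) / (tot * (tot - 1.0))
    het = np.where(tot >= 2, het, 0.0)
    return DiversityStats(
        group=group,
        S=S,
        L=L,
        n_chromosomes=n,
        a_n=a_n,
        theta_w=S / (a_n * L),
        pi=float(het.sum() / L),
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst


def wc_components(gm: GenotypeMatrix, pops: np.ndarray | None = None):
    """Per-site Weir & Cockerham (1984) variance components for two populations.

    Returns (a, b, c, keep) arrays over all sites; ``keep`` marks sites with
    >= 2 genotyped diploids in each population that are polymorphic overall.
    Sample sizes are adjusted per site for missing genotypes.
    """
    if pops is None:
        pops = gm.pops
    labels = sorted(set(pops))
    if len(labels) != 2:
        raise ValueError("Weir-Cockerham components need exactly two populations")
    d = gm.dosage
    r = 2
    n_i, p_i, h_i = [], [], []
    for lab in labels:
        sub = d[:, pops == lab]
        called = sub >= 0
        n = called.sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(called, sub, 0).sum(axis=1) / (2 * n)
            h = (sub == 1).sum(axis=1) / n
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n1, n2 = n_i
    p1, p2 = p_i
    h1, h2 = h_i
    keep = (n1 >= 2) & (n2 >= 2)
    nsum = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = nsum / r
        nc = nsum - (n1**2 + n2**2) / nsum  # (r n_bar - sum n_i^2/(r n_bar)) / (r-1)
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    poly = (pbar > 0) & (pbar < 1)
    keep &= poly & np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a, b, c, keep


@dataclass
class FstResult:
    windows: pd.DataFrame  # chrom, start, end, n_sites, weighted_fst
    genome_wide: float
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    keep: np.ndarray


def weighted_fst(gm: GenotypeMatrix, window: int = 1000) -> FstResult:
    """Windowed and genome-wide weighted Fst (ratio of summed components).

    Weighted Fst = sum(a) / sum(a + b + c) over included sites; windows are
    half-open ``window``-bp bins of the site positions. Negative estimates
    are reported as computed.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    a, b, c, keep = wc_components(gm)
    denom_all = (a + b + c)[keep].sum()
    gw = float(a[keep].sum() / denom_all) if denom_all > 0 else float("nan")
    rows = []
    wkey = gm.pos // window
    df = pd.DataFrame(
        {
            "chrom": gm.chrom[keep],
            "win": wkey[keep],
            "a": a[keep],
            "abc": (a + b + c)[keep],
        }
    )
    for (chrom, w), sub in df.groupby(["chrom", "win"], sort=True):
        denom = sub["abc"].sum()
        rows.append(
            (
                chrom,
                int(w) * window,
                (int(w) + 1) * window,
                len(sub),
                float(sub["a"].sum() / denom) if denom > 0 else float("nan"),
            )
        )
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "weighted_fst"])
    return FstResult(windows=windows, genome_wide=gw, a=a, b=b, c=c, keep=keep)


def fst_randomization(
    gm: GenotypeMatrix, n_reps: int = 200, seed: int = 0
) -> tuple[float, float, np.ndarray]:
    """Permutation test of the genome-wide weighted Fst.

    Individual population labels are shuffled (group sizes preserved),
    the weighted Fst recomputed each time, and
    p = (#{permuted >= observed} + 1) / (n_reps + 1).
    Returns (p_value, observed, permuted values).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    a, b, c, keep = wc_components(gm)
    denom = (a + b + c)[keep].sum()
    obs = float(a[keep].sum() / denom) if denom > 0 else float("nan")
    rng = substream(seed, "fst_perm")
    perms = np.empty(n_reps)
    pops = np.asarray(gm.pops)
    for i in range(n_reps):
        pa, pb, pc, pk = wc_components(gm, pops=rng.permutation(pops))
        pd_ = (pa + pb + pc)[pk].sum()
        perms[i] = pa[pk].sum() / pd_ if pd_ > 0 else np.nan
    p = (np.sum(perms >= obs) + 1) / (n_reps + 1)
    return float(p), obs, perms


# ---------------------------------------------------------------------------
# genotype distances and trees


def genotype_distance(gm: GenotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Allele-sharing dissimilarity |dosage_i - dosage_j| / 2 averaged over
    sites called in both samples (pairwise deletion)."""
    n = gm.n_samples
    if n < 2:
        raise ValueError("need >= 2 samples")
    d = gm.dosage.astype(float)
    d[gm.dosage < 0] = np.nan
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        diff = np.abs(d[:, i] - d[:, j])
        ok = ~np.isnan(diff)
        if not ok.any():
            raise ValueError(f"no shared called sites for pair ({gm.samples[i]}, {gm.samples[j]})")
        mat[i, j] = mat[j, i] = float(np.nanmean(diff[ok]) / 2.0)
    return list(gm.samples), mat


def nj_tree(ids: list[str], matrix: np.ndarray):
    """Saitou-Nei neighbour joining on a symmetric distance matrix."""
    if len(ids) < 3:
        raise ValueError("neighbour joining needs >= 3 samples")
    return nj(DistanceMatrix(matrix, ids))


def _bipartitions(tree, taxa: frozenset) -> set[frozenset]:
    """Non-trivial splits of a tree, each as the frozenset of tips on one side
    (canonicalised to the side not containing the alphabetically first taxon)."""
    ref = min(taxa)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        out.add(side if ref not in side else taxa - side)
    return out


@dataclass
class DistanceTree:
    ids: list[str]
    matrix: np.ndarray
    newick: str
    #: bipartition -> bootstrap support in [0, 1]
    supports: dict[frozenset, float]
    n_boot: int

    def clade_support(self, members) -> float:
        """Support of the split separating ``members`` from everything else."""
        taxa = frozenset(self.ids)
        side = frozenset(members)
        key = side if min(taxa) not in side else taxa - side
        return self.supports.get(key, 0.0)

    def has_clade(self, members) -> bool:
        taxa = frozenset(self.ids)
        side = frozenset(members)
        key = side if min(taxa) not in side else taxa - side
        return key in self.supports


def bootstrap_consensus(gm: GenotypeMatrix, n_boot: int = 1000, seed: int = 0) -> DistanceTree:
    """NJ tree from genotype distances with site-bootstrap edge supports.

    Bootstrap replicates resample site columns with replacement, rebuild the
    distance matrix and NJ tree, and each internal edge of the full-data tree
    gets the fraction of replicates containing the same bipartition
    (majority-rule consensus supports).
    """
    ids, mat = genotype_distance(gm)
    tree = nj_tree(ids, mat)
    taxa = frozenset(ids)
    splits = _bipartitions(tree, taxa)
    counts = {s: 0 for s in splits}
    rng = substream(seed, "boot")
    n = gm.n_samples
    d = gm.dosage.astype(float)
    d[gm.dosage < 0] = np.nan
    # per-pair per-site |dosage diff|/2 with NaN at missing, resampled per replicate
    pair_idx = list(itertools.combinations(range(n), 2))
    diffs = np.stack([np.abs(d[:, i] - d[:, j]) / 2.0 for i, j in pair_idx], axis=1)
    for _ in range(n_boot):
        take = rng.integers(0, gm.n_sites, size=gm.n_sites)
        sub = diffs[take]
        with np.errstate(invalid="ignore"):
            means = np.nanmean(sub, axis=0)
        bmat = np.zeros((n, n))
        for (i, j), v in zip(pair_idx, means):
            bmat[i, j] = bmat[j, i] = 0.0 if np.isnan(v) else float(v)
        btree = nj(DistanceMatrix(bmat, ids))
        for s in _bipartitions(btree, taxa):
            if s in counts:
                counts[s] += 1
    supports = {s: c / n_boot for s, c in counts.items()}
    return DistanceTree(
        ids=ids, matrix=mat, newick=str(tree).strip(), supports=supports, n_boot=n_boot
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) pairwise dN/dS


_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = dict(zip(_CODONS, _AA))
STOP_CODONS = {c for c, a in CODON_TABLE.items() if a == "*"}


def _syn_site_fraction(codon: str) -> float:
    """Synonymous site count of one codon (changes to stops count nonsynonymous)."""
    aa = CODON_TABLE[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE[alt] == aa:
                syn += 1
    return syn / 3.0


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over substitution
    pathways; pathways through intermediate stop codons are excluded unless all
    pathways hit one."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TABLE[nxt] == "*" and step < len(order) - 1:
                ok = False
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((ok, sd, nd))
    valid = [(s, n) for ok, s, n in paths if ok]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in valid) / len(valid)
    nd = sum(n for _, n in valid) / len(valid)
    return sd, nd


@dataclass
class DnDsResult:
    dN: float
    dS: float
    ratio: float  # NaN when dS == 0 (undefined)
    pN: float
    pS: float
    N: float
    S: float
    Nd: float
    Sd: float
    saturated: bool  # True when a proportion reached the Jukes-Cantor limit
    method: str = "NG86"


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def pairwise_dnds(cds_A: str, cds_B: str) -> DnDsResult:
    """Nei-Gojobori pairwise dN/dS with equal-pathway averaging and
    Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3).

    Sequences must be equal length, a multiple of 3 and free of internal stop
    codons. The ratio is NaN when dS = 0; ``saturated`` flags proportions at
    or beyond the correction's domain (p >= 3/4).
    """
    a, b = cds_A.upper(), cds_B.upper()
    if len(a) != len(b):
        raise ValueError("CDS lengths differ")
    if len(a) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    n_codons = len(a) // 3
    S = N = Sd = Nd = 0.0
    for i in range(n_codons):
        ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
        if (ca in STOP_CODONS or cb in STOP_CODONS) and i < n_codons - 1:
            raise ValueError(f"internal stop codon at codon {i}")
        sa, sb = _syn_site_fraction(ca), _syn_site_fraction(cb)
        S += (sa + sb) / 2.0
        N += 3.0 - (sa + sb) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, sat_s = _jc_correct(pS)
    dN, sat_n = _jc_correct(pN)
    if not math.isnan(dS) and dS > 0 and not math.isnan(dN):
        ratio = dN / dS
    else:
        ratio = float("nan")
    return DnDsResult(
        dN=dN, dS=dS, ratio=ratio, pN=pN, pS=pS, N=N, S=S, Nd=Nd, Sd=Sd,
        saturated=sat_s or sat_n,
    )
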