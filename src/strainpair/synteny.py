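"""Synteny blocks from 1:1 ortholog markers and scaffold-to-chromosome anchoring.

Ortholog pairs come from reciprocal best hits on global CDS identity; synteny
blocks are maximal runs of at least two consecutive markers in the same order
and relative orientation in both genomes; scaffolds are anchored to the
reference chromosome holding the plurality of their block markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from ._util import merge_intervals
from .sim import GeneModel


@dataclass(frozen=True)
class OrthologMarker:
    gene_id_A: str
    gene_id_B: str
    scaffold_A: str
    pos_A: int
    strand_A: str
    chrom_B: str
    pos_B: int
    strand_B: str

    @property
    def relative_orientation(self) -> str:
        return "same" if self.strand_A == self.strand_B else "inverted"


@dataclass
class SyntenyBlock:
    markers: list[OrthologMarker]
    scaffold_A: str
    chrom_B: str
    orientation: str  # 'same' | 'inverted'

    @property
    def n_markers(self) -> int:
        return len(self.markers)


def _identity(a: str, b: str) -> float:
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance", mode="NW")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def pair_orthologs(
    genes_A: list[GeneModel],
    genes_B: list[GeneModel],
    cds_A: dict[str, str],
    cds_B: dict[str, str],
    min_identity: float = 0.5,
) -> list[OrthologMarker]:
    """One-to-one ortholog pairs by reciprocal best hit on global CDS identity.

    Identity is 1 - edit_distance/max(len) under global alignment. Ties are
    broken toward the lexicographically smallest partner id, which keeps the
    pairing deterministic and drops all but one of identical paralogs. Pairs
    below ``min_identity`` are discarded.
    """
    if not genes_A or not genes_B:
        return []
    for g in genes_A:
        if g.gene_id not in cds_A:
            raise ValueError(f"missing CDS for {g.gene_id}")
    for g in genes_B:
        if g.gene_id not in cds_B:
            raise ValueError(f"missing CDS for {g.gene_id}")

    ids_A = sorted(g.gene_id for g in genes_A)
    ids_B = sorted(g.gene_id for g in genes_B)
    best_A: dict[str, tuple[float, str]] = {}
    best_B: dict[str, tuple[float, str]] = {}
    for a in ids_A:
        for b in ids_B:
            ident = _identity(cds_A[a], cds_B[b])
            if ident < min_identity:
                continue
            if a not in best_A or ident > best_A[a][0]:
                best_A[a] = (ident, b)
            if b not in best_B or ident > best_B[b][0]:
                best_B[b] = (ident, a)
    by_id_A = {g.gene_id: g for g in genes_A}
    by_id_B = {g.gene_id: g for g in genes_B}
    markers = []
    for a, (ident, b) in sorted(best_A.items()):
        if best_B.get(b, (0.0, None))[1] != a:
            continue
        ga, gb = by_id_A[a], by_id_B[b]
        markers.append(
            OrthologMarker(
                gene_id_A=a, gene_id_B=b,
                scaffold_A=ga.chrom, pos_A=(ga.start + ga.end) // 2, strand_A=ga.strand,
                chrom_B=gb.chrom, pos_B=(gb.start + gb.end) // 2, strand_B=gb.strand,
            )
        )
    markers.sort(key=lambda m: (m.scaffold_A, m.pos_A))
    return markers


def build_blocks(markers: list[OrthologMarker], min_markers: int = 2) -> list[SyntenyBlock]:
    """Maximal co-oriented colinear marker runs of at least ``min_markers``.

    Within a query scaffold (markers sorted by query position) a run extends
    while the reference chromosome and relative orientation stay constant and
    the reference position moves strictly monotonically in the direction the
    orientation implies (up for 'same', down for 'inverted').
    """
    blocks: list[SyntenyBlock] = []
    by_scaf: dict[str, list[OrthologMarker]] = {}
    for m in sorted(markers, key=lambda m: (m.scaffold_A, m.pos_A)):
        by_scaf.setdefault(m.scaffold_A, []).append(m)

    def flush(run):
        if len(run) >= min_markers:
            blocks.append(
                SyntenyBlock(
                    markers=list(run),
                    scaffold_A=run[0].scaffold_A,
                    chrom_B=run[0].chrom_B,
                    orientation=run[0].relative_orientation,
                )
            )

    for _, ms in sorted(by_scaf.items()):
        run = [ms[0]]
        for m in ms[1:]:
            prev = run[-1]
            ok = (
                m.chrom_B == prev.chrom_B
                and m.relative_orientation == prev.relative_orientation
                and (
                    m.pos_B > prev.pos_B
                    if m.relative_orientation == "same"
                    else m.pos_B < prev.pos_B
                )
            )
            if ok:
                run.append(m)
            else:
                flush(run)
                run = [m]
        flush(run)
    return blocks


@dataclass
class AnchoringResult:
    #: rows (scaffold_id, chrom_B, n_block_markers, conflicted)
    table: list[tuple[str, str, int, bool]]
    scaffold_fraction: float
    scaffold_fraction_unconflicted: float
    chrom_fraction: float


def anchor_scaffolds(
    blocks: list[SyntenyBlock],
    scaffold_lengths: dict[str, int],
    chrom_lengths: dict[str, int],
) -> AnchoringResult:
    """Assign each scaffold to the chromosome holding most of its block markers.

    Plurality wins (ties toward the lexicographically first chromosome);
    scaffolds with blocks on more than one chromosome are flagged conflicted.
    Fractions report anchored scaffold bp over total scaffold bp (with and
    without conflicted scaffolds) and the union of anchored block spans over
    total chromosome length.
    """
    per_scaf: dict[str, dict[str, int]] = {}
    spans: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        per_scaf.setdefault(b.scaffold_A, {})
        per_scaf[b.scaffold_A][b.chrom_B] = per_scaf[b.scaffold_A].get(b.chrom_B, 0) + b.n_markers
        lo = min(m.pos_B for m in b.markers)
        hi = max(m.pos_B for m in b.markers)
        spans.setdefault(b.chrom_B, []).append((lo, hi))
    table = []
    anchored_bp = 0
    anchored_bp_clean = 0
    for sid in sorted(per_scaf):
        votes = per_scaf[sid]
        chrom = max(sorted(votes), key=lambda c: votes[c])
        conflicted = len(votes) > 1
        table.append((sid, chrom, votes[chrom], conflicted))
        anchored_bp += scaffold_lengths.get(sid, 0)
        if not conflicted:
            anchored_bp_clean += scaffold_lengths.get(sid, 0)
    total_scaf = sum(scaffold_lengths.values())
    total_chrom = sum(chrom_lengths.values())
    span_bp = sum(e - s for iv in spans.values() for s, e in merge_intervals(iv))
    return AnchoringResult(
        table=table,
        scaffold_fraction=anchored_bp / total_scaf if total_scaf else 0.0,
        scaffold_fraction_unconflicted=anchored_bp_clean / total_scaf if total_scaf else 0.0,
        chrom_fraction=span_bp / total_chrom if total_chrom else 0.0,
    )
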