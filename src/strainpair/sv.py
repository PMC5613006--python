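"""Structural-variant classification between two strain assemblies.

Candidate events come from the chain/net alignment of the two assemblies:

* strain-specific sequence (insertions in one frame = deletions in the
  other) as maximal reference intervals not covered by any reciprocal-best
  alignment;
* copy-number differences as regions where secondary (multi-occurrence)
  chains align one region of a strain to two or more disjoint regions of the
  other;
* balanced events (inversions, transpositions) as blocks embedded in the
  gaps of a longer enclosing chain whose strand or target order contradicts
  the enclosing context.

Read-depth rules then validate candidates: strain-specific sequence must show
(near) zero depth of the other strain's reads; duplication groups must show
per-copy depth similar to the genome-wide median in both strains, which
rejects duplication calls caused by collapsed assembly copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import complement_intervals, merge_intervals, overlap_len, reciprocal_overlap
from .align import Chain, GenomeAlignment, align_genomes
from .sim import DepthTrack, StrainGenome, TruthSet

EVENT_CLASSES = ("insertion", "deletion", "cnv_gain", "cnv_loss", "inversion", "transposition")


@dataclass
class StructuralVariant:
    """A classified interval event in the coordinates of ``ref_strain``.

    ``validated`` is True/False after a depth test ran, None if untested.
    For CNV groups, copy numbers give the assembly alignment multiplicities
    (reference strain first) and the group is counted once regardless of
    copies.
    """

    event_class: str
    ref_strain: str
    chrom: str
    start: int
    end: int
    partner_strain: str | None = None
    partner_start: int | None = None
    partner_end: int | None = None
    copy_number_ref: int | None = None
    copy_number_other: int | None = None
    validated: bool | None = None
    evidence: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# strain-specific sequence


def _rbest_anchor_cover(aln: GenomeAlignment, reference: str) -> dict[str, list[tuple[int, int]]]:
    cover: dict[str, list[tuple[int, int]]] = {}
    on_query = reference == aln.name_A
    for c in aln.rbest_chains():
        for a in c.anchors:
            if on_query:
                cover.setdefault(a.q_chrom, []).append((a.q_start, a.q_end))
            else:
                cover.setdefault(a.t_chrom, []).append((a.t_start, a.t_end))
    return {c: merge_intervals(v) for c, v in cover.items()}


def call_strain_specific(
    aln: GenomeAlignment, reference: str, min_len: int = 100
) -> list[StructuralVariant]:
    """Maximal reference intervals >= ``min_len`` with no reciprocal-best alignment.

    With strain C as reference these are candidate C-specific sequences
    (insertions in the C frame); the same intervals seen from the R frame are
    deletion candidates.
    """
    if reference == aln.name_A:
        lengths = aln.net_A.target_lengths
    elif reference == aln.name_B:
        lengths = aln.net_B.target_lengths
    else:
        raise ValueError(f"unknown reference {reference!r}")
    cover = _rbest_anchor_cover(aln, reference)
    out = []
    for chrom, L in sorted(lengths.items()):
        for s, e in complement_intervals(cover.get(chrom, []), L):
            if e - s >= min_len:
                out.append(
                    StructuralVariant(
                        event_class="insertion",
                        ref_strain=reference,
                        chrom=chrom,
                        start=s,
                        end=e,
                        evidence={"source": "rbest_gap"},
                    )
                )
    return out


def validate_deletion(
    candidate: StructuralVariant, other_strain_depth_on_ref: DepthTrack | None, max_depth: float = 10.0
) -> StructuralVariant:
    """Depth test for strain-specific sequence: median windowed depth < ``max_depth``.

    The track must hold the *other* strain's reads mapped on the candidate's
    reference assembly. Validated iff the median per-window depth over the
    candidate is strictly below the cutoff; no overlapping windows leaves the
    candidate untested.
    """
    t = other_strain_depth_on_ref
    if t is None or candidate.chrom not in t.values:
        candidate.validated = None
        return candidate
    w = t.window_depths(candidate.chrom, candidate.start, candidate.end)
    if w.size == 0:
        candidate.validated = None
        return candidate
    med = float(np.median(w))
    candidate.validated = bool(med < max_depth)
    candidate.evidence["median_other_depth"] = med
    return candidate


# ---------------------------------------------------------------------------
# copy-number groups


def _chain_cover_by_frame(chains: list[Chain], frame_is_query: bool):
    """Per chromosome: list of (chain, merged anchor intervals in that frame)."""
    out: dict[str, list[tuple[Chain, list[tuple[int, int]]]]] = {}
    for c in chains:
        iv: dict[str, list[tuple[int, int]]] = {}
        for a in c.anchors:
            if frame_is_query:
                iv.setdefault(a.q_chrom, []).append((a.q_start, a.q_end))
            else:
                iv.setdefault(a.t_chrom, []).append((a.t_start, a.t_end))
        for chrom, v in iv.items():
            out.setdefault(chrom, []).append((c, merge_intervals(v)))
    return out


def _multiplicity_intervals(cover_entries, length: int, bridge: int = 100, min_len: int = 200):
    """Maximal intervals covered by >= 2 distinct chains, small holes bridged."""
    diff = np.zeros(length + 1, dtype=np.int32)
    for _, iv in cover_entries:
        for s, e in iv:
            diff[s] += 1
            diff[e] -= 1
    mult = np.cumsum(diff[:-1])
    hot = mult >= 2
    idx = np.flatnonzero(np.diff(np.concatenate([[0], hot.view(np.int8), [0]])))
    raw = [(int(idx[i]), int(idx[i + 1])) for i in range(0, idx.size, 2)]
    merged: list[tuple[int, int]] = []
    for s, e in raw:
        if merged and s - merged[-1][1] <= bridge:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e - s >= min_len]


def call_cnv(
    multi_chains: list[Chain],
    name_A: str,
    name_B: str,
    lengths_A: dict[str, int],
    lengths_B: dict[str, int],
    reference: str = "C",
    min_len: int = 200,
    min_cover_frac: float = 0.5,
) -> list[StructuralVariant]:
    """Duplication groups from multi-occurrence chains.

    A group is a region of one strain aligned by >= 2 distinct chains (with
    disjoint partner regions) to the other strain; the alignment multiplicity
    gives the copy numbers. The reported interval is the span of the copies in
    the multi-copy strain; ``cnv_gain`` means more copies in the reference
    strain. Groups are counted once regardless of copy count.
    """
    out: list[StructuralVariant] = []
    for single_name, frame_is_query, lengths in (
        (name_A, True, lengths_A),
        (name_B, False, lengths_B),
    ):
        multi_name = name_B if single_name == name_A else name_A
        cover = _chain_cover_by_frame(multi_chains, frame_is_query)
        for chrom, entries in sorted(cover.items()):
            # per-position chain-coverage multiplicity over the whole chromosome
            diff = np.zeros(lengths[chrom] + 1, dtype=np.int32)
            for _, iv in entries:
                for cs, ce in iv:
                    diff[cs] += 1
                    diff[ce] -= 1
            mult = np.cumsum(diff[:-1])
            for s, e in _multiplicity_intervals(entries, lengths[chrom], min_len=min_len):
                # the multiplicity IS the copy number in the other strain; the
                # secondary alignment may be split across several chain
                # fragments, so support = every chain contributing coverage
                support = []
                for c, iv in entries:
                    ov = sum(overlap_len((s, e), x) for x in iv)
                    if ov >= min(100, min_cover_frac * (e - s)):
                        support.append(c)
                if len(support) < 2:
                    continue
                # homologous copy intervals in the multi-copy strain
                copies = []
                for c in support:
                    lo, hi = None, None
                    for a in c.anchors:
                        a_single = (a.q_start, a.q_end) if frame_is_query else (a.t_start, a.t_end)
                        if overlap_len(a_single, (s, e)) > 0:
                            m = (a.t_start, a.t_end) if frame_is_query else (a.q_start, a.q_end)
                            lo = m[0] if lo is None else min(lo, m[0])
                            hi = m[1] if hi is None else max(hi, m[1])
                    if lo is not None:
                        copies.append((lo, hi))
                if len(copies) < 2:
                    continue
                mspan = (min(x[0] for x in copies), max(x[1] for x in copies))
                mchrom = support[0].t_chrom if frame_is_query else support[0].q_chrom
                k_multi, k_single = int(mult[s:e].max()), 1
                cn = {multi_name: k_multi, single_name: k_single}
                other_name = name_B if reference == name_A else name_A
                cls = "cnv_gain" if cn.get(reference, 1) > cn.get(other_name, 1) else "cnv_loss"
                out.append(
                    StructuralVariant(
                        event_class=cls,
                        ref_strain=multi_name,
                        chrom=mchrom,
                        start=mspan[0],
                        end=mspan[1],
                        partner_strain=single_name,
                        partner_start=s,
                        partner_end=e,
                        copy_number_ref=cn.get(reference, 1),
                        copy_number_other=cn.get(other_name, 1),
                        evidence={"support_chains": sorted(c.id for c in support)},
                    )
                )
    return out


def validate_cnv(
    group: StructuralVariant,
    own_depth: dict[str, DepthTrack],
    rel_tol: float = 0.5,
) -> StructuralVariant:
    """Depth similarity test for a duplication group.

    In each strain, the mean depth of that strain's own reads over its copies
    must lie within the closed band (1 +/- rel_tol) x genome-wide median of
    the same track; a collapsed assembly copy shows ~2x depth and fails.
    """
    spans = {
        group.ref_strain: (group.chrom, group.start, group.end),
        group.partner_strain: (group.chrom, group.partner_start, group.partner_end),
    }
    means = {}
    for strain, (chrom, s, e) in spans.items():
        t = own_depth.get(strain)
        if t is None or chrom not in t.values:
            group.validated = None
            return group
        w = t.window_depths(chrom, s, e)
        if w.size == 0:
            group.validated = None
            return group
        med = t.genome_median()
        means[strain] = (float(np.mean(w)), med)
    group.validated = all(
        (1 - rel_tol) * med <= mean <= (1 + rel_tol) * med for mean, med in means.values()
    )
    group.evidence["depth"] = {k: v for k, v in means.items()}
    return group


# ---------------------------------------------------------------------------
# balanced events


def call_balanced(
    chains: list[Chain], min_block_bp: int = 100, tol: int = 100
) -> list[StructuralVariant]:
    """Inversions and transpositions embedded in longer enclosing chains.

    A block chain whose query span sits inside an inter-anchor query gap of an
    enclosing chain is an inversion if its strand is opposite to the enclosing
    chain and its target interval falls in the corresponding target gap; it is
    a transposition if the strand matches but the target interval lies outside
    that corresponding gap (order violation). The enclosing context must exist
    on both sides, which the inter-anchor-gap requirement enforces.
    """
    out: list[StructuralVariant] = []
    by_pair: dict[tuple[str, str], list[Chain]] = {}
    for c in chains:
        by_pair.setdefault((c.q_chrom, c.t_chrom), []).append(c)
    for (q_chrom, t_chrom), grp in sorted(by_pair.items()):
        contexts = [c for c in grp if len(c.anchors) >= 2]
        for c in grp:
            best = None
            for P in contexts:
                if P is c or P.aligned_bp <= c.aligned_bp:
                    continue
                anchors = P.anchors
                for a0, a1 in zip(anchors, anchors[1:]):
                    # anchor ends jitter by up to ~k bp at event breakpoints
                    if not (a0.q_end <= c.q_start + tol and c.q_end <= a1.q_start + tol):
                        continue
                    if a1.q_start - a0.q_end < c.q_end - c.q_start - 2 * tol:
                        continue
                    if P.strand == "+":
                        g = (a0.t_end, a1.t_start)
                    else:
                        g = (a1.t_end, a0.t_start)
                    in_gap = g[0] - tol <= c.t_start and c.t_end <= g[1] + tol
                    if c.strand != P.strand and in_gap:
                        best = ("inversion", P)
                    elif c.strand == P.strand and not in_gap:
                        # target interval must still fall within the context span
                        if P.t_start - tol <= c.t_start and c.t_end <= P.t_end + tol:
                            best = ("transposition", P)
                    break
                if best:
                    break
            if best and c.aligned_bp >= min_block_bp:
                cls, P = best
                out.append(
                    StructuralVariant(
                        event_class=cls,
                        ref_strain="",  # filled by caller: query frame of the chain set
                        chrom=q_chrom,
                        start=c.q_start,
                        end=c.q_end,
                        partner_start=c.t_start,
                        partner_end=c.t_end,
                        evidence={"block_chain": c.id, "context_chain": P.id},
                    )
                )
    return out


# ---------------------------------------------------------------------------
# summary and pipeline


@dataclass
class SvSummary:
    """Per-class counts and union bp coverage of non-rejected events."""

    counts: dict[str, int]
    coverage_bp: dict[str, int]

    def as_rows(self):
        return [(cls, self.counts.get(cls, 0), self.coverage_bp.get(cls, 0)) for cls in EVENT_CLASSES]


def summarize(variants: list[StructuralVariant]) -> SvSummary:
    """Count events and union coverage per class, skipping depth-rejected calls.

    Duplication groups contribute one count each (copies are not multiplied)
    and their coverage is the span of the copies in the multi-copy strain.
    """
    counts: dict[str, int] = {}
    cov_iv: dict[str, dict[tuple[str, str], list[tuple[int, int]]]] = {}
    for v in variants:
        if v.validated is False:
            continue
        counts[v.event_class] = counts.get(v.event_class, 0) + 1
        cov_iv.setdefault(v.event_class, {}).setdefault((v.ref_strain, v.chrom), []).append(
            (v.start, v.end)
        )
    coverage = {
        cls: sum(e - s for iv in per.values() for s, e in merge_intervals(iv))
        for cls, per in cov_iv.items()
    }
    return SvSummary(counts=counts, coverage_bp=coverage)


@dataclass
class SvScanResult:
    variants: list[StructuralVariant]
    summary: SvSummary
    alignment: GenomeAlignment


def _drop_overlapping(cands, excluded, frac=0.5):
    out = []
    for v in cands:
        key = (v.ref_strain, v.chrom)
        ov = sum(overlap_len(v.interval, x) for x in excluded.get(key, []))
        if ov < frac * v.length:
            out.append(v)
    return out


def scan_structural_variants(
    genome_C: StrainGenome,
    genome_R: StrainGenome,
    depth_tracks: dict[tuple[str, str], DepthTrack] | None = None,
    k: int = 21,
    min_len: int = 100,
    max_depth: float = 10.0,
    rel_tol: float = 0.5,
    max_occ: int = 3,
    reference: str = "C",
) -> SvScanResult:
    """Full two-strain SV scan with C-referenced class labels.

    Runs the unique-anchor alignment for the one-to-one map, a secondary
    multi-occurrence alignment for copy-number groups, classifies balanced
    events against enclosing chains, calls strain-specific sequence from
    reciprocal-best coverage gaps (insertions when specific to the reference
    strain, deletions when specific to the other), and applies the depth
    validation rules when tracks are given.
    """
    aln = align_genomes(genome_C, genome_R, k=k, name_A="C", name_B="R")
    aln_multi = align_genomes(genome_C, genome_R, k=k, max_occ=max_occ, name_A="C", name_B="R")

    balanced = call_balanced(aln.chains)
    for v in balanced:
        v.ref_strain = "C"
        v.partner_strain = "R"

    cnv = call_cnv(
        aln_multi.chains,
        "C",
        "R",
        genome_C.chrom_lengths,
        genome_R.chrom_lengths,
        reference=reference,
    )

    excluded: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for v in balanced + cnv:
        excluded.setdefault((v.ref_strain, v.chrom), []).append(v.interval)
        if v.partner_strain is not None and v.partner_start is not None:
            excluded.setdefault((v.partner_strain, v.chrom), []).append(
                (v.partner_start, v.partner_end)
            )
    for key in excluded:
        excluded[key] = merge_intervals(excluded[key])

    other = "R" if reference == "C" else "C"
    spec_ref = _drop_overlapping(call_strain_specific(aln, reference, min_len), excluded)
    spec_other = _drop_overlapping(call_strain_specific(aln, other, min_len), excluded)
    for v in spec_other:
        v.event_class = "deletion"  # sequence specific to the non-reference strain

    if depth_tracks:
        for v in spec_ref:
            validate_deletion(v, depth_tracks.get((reference, other)), max_depth)
        for v in spec_other:
            validate_deletion(v, depth_tracks.get((other, reference)), max_depth)
        own = {s: depth_tracks.get((s, s)) for s in ("C", "R")}
        if all(own.values()):
            for v in cnv:
                validate_cnv(v, own, rel_tol)

    variants = spec_ref + spec_other + cnv + balanced
    return SvScanResult(variants=variants, summary=summarize(variants), alignment=aln)


# ---------------------------------------------------------------------------
# truth scoring


def _truth_interval_in_frame(rec, frame: str):
    if rec.strain == frame:
        return rec.chrom, (rec.start, rec.end)
    if rec.partner_strain == frame and rec.partner_start is not None:
        return rec.chrom, (rec.partner_start, rec.partner_end)
    return None


_CALL_FOR_TRUTH = {
    "insertion": ("insertion", "deletion"),
    "deletion": ("insertion", "deletion"),
    "tandem_duplication": ("cnv_gain", "cnv_loss"),
    "inversion": ("inversion",),
    "transposition": ("transposition",),
}


def score_sv_recovery(
    result: SvScanResult,
    truth: TruthSet,
    min_ro: float = 0.5,
    require_validated: bool = True,
) -> dict:
    """Per-class precision/recall of calls against planted truth.

    A call matches a truth record when their intervals reciprocally overlap by
    >= ``min_ro`` in a frame where both have coordinates. Collapsed-duplication
    decoys are excluded from truth; ``decoy_rejection`` reports the fraction of
    decoys without a surviving (validated or untested) matching CNV call.
    """
    calls = [
        v
        for v in result.variants
        if not (require_validated and v.validated is False)
    ]
    truth_recs = truth.by_class(*_CALL_FOR_TRUTH)
    matched_truth: set[int] = set()
    matched_call: set[int] = set()
    for ti, rec in enumerate(truth_recs):
        for ci, v in enumerate(calls):
            if v.event_class not in _CALL_FOR_TRUTH[rec.event_class]:
                continue
            loc = _truth_interval_in_frame(rec, v.ref_strain)
            hit = False
            if loc is not None and loc[0] == v.chrom:
                hit = reciprocal_overlap(loc[1], v.interval) >= min_ro
            if not hit and v.partner_start is not None and rec.partner_strain is not None:
                ploc = _truth_interval_in_frame(rec, v.partner_strain)
                if ploc is not None and ploc[0] == v.chrom:
                    hit = (
                        reciprocal_overlap(ploc[1], (v.partner_start, v.partner_end)) >= min_ro
                    )
            if hit:
                matched_truth.add(ti)
                matched_call.add(ci)
    per_class: dict[str, dict] = {}
    for cls in ("insertion", "deletion", "tandem_duplication", "inversion", "transposition"):
        t_idx = [i for i, r in enumerate(truth_recs) if r.event_class == cls]
        if cls in ("insertion", "deletion"):
            c_idx = [i for i, v in enumerate(calls) if v.event_class in ("insertion", "deletion")]
        elif cls == "tandem_duplication":
            c_idx = [i for i, v in enumerate(calls) if v.event_class in ("cnv_gain", "cnv_loss")]
        else:
            c_idx = [i for i, v in enumerate(calls) if v.event_class == cls]
        if not t_idx:
            continue
        recall = sum(1 for i in t_idx if i in matched_truth) / len(t_idx)
        precision = (
            sum(1 for i in c_idx if i in matched_call) / len(c_idx) if c_idx else 0.0
        )
        per_class[cls] = {
            "n_truth": len(t_idx),
            "n_calls": len(c_idx),
            "recall": recall,
            "precision": precision,
        }

    decoys = truth.by_class("collapsed_duplication")
    rejected = 0
    for rec in decoys:
        survives = False
        for v in calls:
            if v.event_class not in ("cnv_gain", "cnv_loss"):
                continue
            for frame in (v.ref_strain, v.partner_strain):
                loc = _truth_interval_in_frame(rec, frame)
                iv = v.interval if frame == v.ref_strain else (v.partner_start, v.partner_end)
                if loc is not None and loc[0] == v.chrom and reciprocal_overlap(loc[1], iv) >= min_ro:
                    survives = True
        if not survives:
            rejected += 1
    out = {"per_class": per_class}
    if decoys:
        out["decoy_rejection"] = rejected / len(decoys)
    return out
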