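"""Synthetic two-strain genome simulator with fully recorded ground truth.

Emulates a pair of moth host strains ("C" and "R") that diverged from a common
ancestor: branch-specific SNPs and small indels, planted structural variants of
five classes (insertion, deletion, tandem duplication, inversion,
transposition) plus optional collapsed-duplication assembly decoys, fragmented
scaffold output, copy-number-aware read-depth tracks, a two-population diploid
genotype matrix under a Balding-Nichols model with an optional
high-divergence mitochondrial-like locus, and planted gene models with
functional categories optionally enriched inside SV regions.

Every planted event is recorded in a :class:`TruthSet` with coordinates in the
frame of the strain that carries the event footprint, so downstream callers can
be scored against exact ground truth.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._util import BASES, codes_to_seq, seq_to_codes, substream

STRAINS = ("C", "R")
SV_CLASSES = ("insertion", "deletion", "tandem_duplication", "inversion", "transposition")

#: Padding (bp) kept clear around every planted structural event.
SV_PAD = 500
#: Minimum distance (bp) of planted events from chromosome ends, so every
#: event keeps flanking alignable context on both sides (balanced events are
#: only defined relative to an enclosing alignment).
SV_EDGE_MARGIN = 5000


# ---------------------------------------------------------------------------
# ancestral genome


@dataclass
class AncestralGenome:
    """A set of named ancestral chromosomes with controlled base composition."""

    sequences: dict[str, str]
    gc_content: float
    seed: int
    name: str = "ancestor"

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def simulate_ancestor(
    chrom_lengths: list[int] | dict[str, int],
    gc_content: float = 0.36,
    seed: int = 0,
) -> AncestralGenome:
    """Draw i.i.d. ancestral chromosomes with the requested GC fraction.

    The 36% default matches the typical AT-rich lepidopteran genome
    composition the simulator is meant to emulate.
    """
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must lie in [0, 1]")
    if isinstance(chrom_lengths, dict):
        items = list(chrom_lengths.items())
    else:
        items = [(f"chr{i + 1}", length) for i, length in enumerate(chrom_lengths)]
    for name, length in items:
        if length < 1000:
            raise ValueError(f"chromosome {name}: length {length} < 1 kb minimum")
    p = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    rng = np.random.default_rng(seed)
    seqs = {
        name: codes_to_seq(rng.choice(4, size=length, p=p).astype(np.uint8))
        for name, length in items
    }
    return AncestralGenome(sequences=seqs, gc_content=gc_content, seed=seed)


# ---------------------------------------------------------------------------
# divergence model and truth bookkeeping


@dataclass
class DivergenceModel:
    """Branch mutation rates and structural-variant plan for one divergence run.

    ``snp_rate`` is the expected total per-site substitution divergence between
    the two strains; half is applied along each branch. ``sv_counts`` maps each
    event class to the number of planted events (assigned to a random branch
    each). ``decoy_collapsed`` plants tandem duplications present in *both*
    real genomes but collapsed to a single copy in one strain's assembly; these
    emulate the heterozygosity/repeat misassemblies that depth validation must
    reject.
    """

    snp_rate: float = 0.005
    small_indel_rate: float = 0.0002
    sv_counts: dict[str, int] = field(default_factory=dict)
    sv_size_dist: dict[str, tuple[int, int]] = field(default_factory=dict)
    decoy_collapsed: int = 0
    dup_copies: int = 2
    min_transposition_move: int = 5000
    seed: int = 0

    def __post_init__(self):
        if self.snp_rate < 0 or self.small_indel_rate < 0:
            raise ValueError("mutation rates must be >= 0")
        for cls, n in self.sv_counts.items():
            if cls not in SV_CLASSES:
                raise ValueError(f"unknown SV class {cls!r}")
            if n < 0:
                raise ValueError(f"sv_counts[{cls!r}] must be >= 0")
        for cls, (lo, hi) in self.sv_size_dist.items():
            if lo <= 0 or hi < lo:
                raise ValueError(f"sv_size_dist[{cls!r}] must be a positive range")

    def size_range(self, cls: str) -> tuple[int, int]:
        return self.sv_size_dist.get(cls, (500, 2000))


@dataclass
class SvRecord:
    """One planted event, in the coordinate frame of ``strain``.

    ``strain``/``start``/``end`` locate the event footprint in the strain that
    carries it (insertions: the novel sequence; deletions: the surviving copy
    in the *other* strain; duplications: the full multi-copy span).
    ``partner_*`` give the homologous interval in the opposite strain where one
    exists. ``copy_number_C``/``copy_number_R`` are assembly copy numbers as an
    aligner would see them; ``real_copies`` is the copy count present in actual
    individuals (differs from assembly only for collapsed-duplication decoys).
    """

    event_class: str
    strain: str
    chrom: str
    start: int
    end: int
    copy_number_C: int = 1
    copy_number_R: int = 1
    branch: str = ""
    partner_strain: str | None = None
    partner_start: int | None = None
    partner_end: int | None = None
    anc_start: int = -1
    anc_end: int = -1
    real_copies: int = 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TruthSet:
    """All planted variation of one :func:`diverge` run."""

    records: list[SvRecord]
    snp_positions: dict[str, dict[str, np.ndarray]]  # branch -> chrom -> anc positions

    def by_class(self, *classes: str) -> list[SvRecord]:
        return [r for r in self.records if r.event_class in classes]

    def intervals(self, strain: str, classes=SV_CLASSES) -> dict[str, list[tuple[int, int]]]:
        """Event footprints in ``strain`` coordinates (own frame or partner frame)."""
        out: dict[str, list[tuple[int, int]]] = {}
        for r in self.records:
            if r.event_class not in classes:
                continue
            if r.strain == strain:
                out.setdefault(r.chrom, []).append((r.start, r.end))
            elif r.partner_strain == strain and r.partner_start is not None:
                out.setdefault(r.chrom, []).append((r.partner_start, r.partner_end))
        for chrom in out:
            out[chrom].sort()
        return out


@dataclass
class StrainGenome:
    """A diverged strain assembly plus its ancestor-to-strain coordinate map."""

    name: str
    sequences: dict[str, str]
    # piecewise-identity map: per chrom, parallel arrays of segment
    # (anc_start, anc_end, derived_start) for unrearranged sequence
    _segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def map_position(self, chrom: str, anc_pos: int) -> int:
        """Lift an ancestral coordinate onto this strain.

        Positions inside branch-removed or rearranged segments map to the
        derived position where the flanking sequence rejoins.
        """
        anc_s, anc_e, der_s = self._segments[chrom]
        i = int(np.searchsorted(anc_s, anc_pos, side="right")) - 1
        if i < 0:
            return 0
        if anc_pos < anc_e[i]:
            return int(der_s[i] + (anc_pos - anc_s[i]))
        if i + 1 < anc_s.size:
            return int(der_s[i + 1])
        return int(der_s[i] + (anc_e[i] - anc_s[i]))

    def in_identity_segment(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) in ancestral coords survives unrearranged."""
        anc_s, anc_e, _ = self._segments[chrom]
        i = int(np.searchsorted(anc_s, start, side="right")) - 1
        return i >= 0 and start >= anc_s[i] and end <= anc_e[i]


# ---------------------------------------------------------------------------
# divergence


def _place_intervals(rng, length, wants, pad=SV_PAD, max_tries=400):
    """Reserve non-overlapping [start, start+size) slots on one chromosome.

    ``wants`` is a list of (key, size); returns {key: start}. Raises if a slot
    cannot be found after bounded retries. Slots stay ``SV_EDGE_MARGIN`` away
    from chromosome ends (falling back to ``pad`` on short chromosomes).
    """
    reserved: list[tuple[int, int]] = []
    placed: dict = {}
    for key, size in wants:
        margin = SV_EDGE_MARGIN if length >= 4 * SV_EDGE_MARGIN else pad
        lo, hi = margin, length - size - margin
        if hi <= lo:
            raise ValueError(f"cannot place event {key} of {size} bp on a {length} bp chromosome")
        ok = False
        for _ in range(max_tries):
            s = int(rng.integers(lo, hi))
            if all(s - pad >= e or s + size + pad <= b for b, e in reserved):
                reserved.append((s, s + size))
                placed[key] = s
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place non-overlapping event {key} after {max_tries} tries"
            )
        reserved.sort()
    return placed


def _random_different_bases(rng, old_codes):
    return (old_codes + rng.integers(1, 4, size=old_codes.size).astype(np.uint8)) % 4


_RC_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)


def _apply_edits(codes: np.ndarray, edits: list[dict]) -> tuple[np.ndarray, tuple, dict]:
    """Apply structural edits (sorted by ancestral position) to one chromosome.

    Returns (derived codes, identity-segment arrays, {edit id: derived span}).
    """
    parts: list[np.ndarray] = []
    seg_anc_s: list[int] = []
    seg_anc_e: list[int] = []
    seg_der_s: list[int] = []
    spans: dict = {}
    cur = 0
    der = 0

    def copy_through(stop):
        nonlocal cur, der
        if stop > cur:
            parts.append(codes[cur:stop])
            seg_anc_s.append(cur)
            seg_anc_e.append(stop)
            seg_der_s.append(der)
            der += stop - cur
            cur = stop

    for ed in sorted(edits, key=lambda e: (e["pos"], e.get("end", e["pos"]))):
        kind = ed["kind"]
        s = ed["pos"]
        copy_through(s)
        if kind == "ins":
            payload = ed["payload"]
            spans[ed["id"]] = (der, der + payload.size)
            parts.append(payload)
            der += payload.size
        elif kind == "del":
            spans[ed["id"]] = (der, der)
            cur = ed["end"]
        elif kind == "inv":
            e = ed["end"]
            block = _RC_CODE[codes[s:e]][::-1]
            spans[ed["id"]] = (der, der + block.size)
            parts.append(block)
            der += block.size
            cur = e
        elif kind == "dup":
            e = ed["end"]
            k = ed["copies"]
            block = codes[s:e]
            # first copy is ancestral-identity sequence
            parts.append(block)
            seg_anc_s.append(s)
            seg_anc_e.append(e)
            seg_der_s.append(der)
            der += block.size
            for _ in range(k - 1):
                parts.append(block)
                der += block.size
            spans[ed["id"]] = (der - k * block.size, der)
            cur = e
        else:  # pragma: no cover - guarded upstream
            raise ValueError(f"unknown edit kind {kind}")
    copy_through(codes.size)
    out = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    segs = (
        np.asarray(seg_anc_s, dtype=np.int64),
        np.asarray(seg_anc_e, dtype=np.int64),
        np.asarray(seg_der_s, dtype=np.int64),
    )
    return out, segs, spans


def diverge(
    ancestor: AncestralGenome, model: DivergenceModel
) -> tuple[StrainGenome, StrainGenome, TruthSet]:
    """Evolve two strain genomes from the ancestor and record all variation.

    SNPs and small indels are applied independently on each branch at half the
    model rate; each structural variant is applied to exactly one branch.
    Planted events never overlap one another (padding :data:`SV_PAD`).
    """
    rng = np.random.default_rng(model.seed)
    chroms = list(ancestor.sequences)
    lengths = ancestor.chrom_lengths
    total = sum(lengths.values())
    weights = np.array([lengths[c] for c in chroms], dtype=float) / total

    # --- plan events -------------------------------------------------------
    plans: list[dict] = []
    eid = 0
    for cls in SV_CLASSES:
        for _ in range(model.sv_counts.get(cls, 0)):
            lo, hi = model.size_range(cls)
            plans.append(
                {
                    "id": eid,
                    "class": cls,
                    "chrom": chroms[int(rng.choice(len(chroms), p=weights))],
                    "size": int(rng.integers(lo, hi + 1)),
                    "branch": STRAINS[int(rng.integers(2))],
                }
            )
            eid += 1
    for _ in range(model.decoy_collapsed):
        lo, hi = model.size_range("tandem_duplication")
        collapsed = STRAINS[int(rng.integers(2))]
        plans.append(
            {
                "id": eid,
                "class": "collapsed_duplication",
                "chrom": chroms[int(rng.choice(len(chroms), p=weights))],
                "size": int(rng.integers(lo, hi + 1)),
                # the duplication edit runs on the branch whose assembly keeps
                # both copies; `collapsed` is the strain whose assembly lost one
                "branch": {"C": "R", "R": "C"}[collapsed],
                "collapsed_strain": collapsed,
            }
        )
        eid += 1

    # reserve genomic slots (transpositions need a destination slot too)
    for chrom in chroms:
        wants = []
        for p in plans:
            if p["chrom"] != chrom:
                continue
            wants.append(((p["id"], "src"), p["size"]))
            if p["class"] == "transposition":
                wants.append(((p["id"], "dst"), 0))
        if not wants:
            continue
        placed = _place_intervals(rng, lengths[chrom], wants)
        for p in plans:
            if p["chrom"] != chrom:
                continue
            p["start"] = placed[(p["id"], "src")]
            if p["class"] == "transposition":
                dst = placed[(p["id"], "dst")]
                if abs(dst - p["start"]) < model.min_transposition_move:
                    # push the destination away deterministically
                    dst = (p["start"] + model.min_transposition_move) % lengths[chrom]
                    # fall back to a rejection loop keeping non-overlap
                    for _ in range(400):
                        if all(
                            dst <= q.get("start", -1) - SV_PAD
                            or dst >= q.get("start", -1) + q["size"] + SV_PAD
                            for q in plans
                            if q["chrom"] == chrom and q is not p and "start" in q
                        ) and abs(dst - p["start"]) >= model.min_transposition_move:
                            break
                        dst = int(rng.integers(SV_PAD, lengths[chrom] - SV_PAD))
                    else:
                        raise RuntimeError("could not place transposition destination")
                p["dest"] = dst

    reserved_by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for p in plans:
        reserved_by_chrom[p["chrom"]].append((p["start"] - SV_PAD, p["start"] + p["size"] + SV_PAD))
        if "dest" in p:
            reserved_by_chrom[p["chrom"]].append((p["dest"] - SV_PAD, p["dest"] + SV_PAD))

    # --- per-branch mutation layers ---------------------------------------
    snp_positions: dict[str, dict[str, np.ndarray]] = {b: {} for b in STRAINS}
    branch_edits: dict[str, dict[str, list[dict]]] = {b: {c: [] for c in chroms} for b in STRAINS}
    branch_codes: dict[str, dict[str, np.ndarray]] = {b: {} for b in STRAINS}

    for branch in STRAINS:
        brng = substream(model.seed, "branch", branch)
        for chrom in chroms:
            codes = seq_to_codes(ancestor.sequences[chrom]).copy()
            L = codes.size
            pos = np.flatnonzero(brng.random(L) < model.snp_rate / 2)
            codes[pos] = _random_different_bases(brng, codes[pos])
            snp_positions[branch][chrom] = pos
            # small indels: keep clear of SV slots and of each other
            ipos = np.flatnonzero(brng.random(L) < model.small_indel_rate / 2)
            if ipos.size:
                keep = np.ones(ipos.size, dtype=bool)
                for b, e in reserved_by_chrom[chrom]:
                    keep &= (ipos < b - 12) | (ipos >= e + 12)
                ipos = ipos[keep]
                if ipos.size > 1:
                    ipos = ipos[np.concatenate([[True], np.diff(ipos) >= 24])]
            nid = 0
            for ppos in ipos.tolist():
                size = int(brng.integers(1, 11))
                if brng.random() < 0.5:
                    payload = brng.integers(0, 4, size=size).astype(np.uint8)
                    branch_edits[branch][chrom].append(
                        {"id": ("indel", branch, nid), "kind": "ins", "pos": ppos, "payload": payload}
                    )
                else:
                    branch_edits[branch][chrom].append(
                        {
                            "id": ("indel", branch, nid),
                            "kind": "del",
                            "pos": ppos,
                            "end": min(ppos + size, L),
                        }
                    )
                nid += 1
            branch_codes[branch][chrom] = codes

    # --- structural edits ---------------------------------------------------
    novel_rng = substream(model.seed, "novel")
    for p in plans:
        branch, chrom, s, size = p["branch"], p["chrom"], p["start"], p["size"]
        cls = p["class"]
        if cls == "insertion":
            payload = novel_rng.integers(0, 4, size=size).astype(np.uint8)
            branch_edits[branch][chrom].append(
                {"id": ("sv", p["id"]), "kind": "ins", "pos": s, "payload": payload}
            )
        elif cls == "deletion":
            branch_edits[branch][chrom].append(
                {"id": ("sv", p["id"]), "kind": "del", "pos": s, "end": s + size}
            )
        elif cls in ("tandem_duplication", "collapsed_duplication"):
            branch_edits[branch][chrom].append(
                {
                    "id": ("sv", p["id"]),
                    "kind": "dup",
                    "pos": s,
                    "end": s + size,
                    "copies": model.dup_copies,
                }
            )
        elif cls == "inversion":
            branch_edits[branch][chrom].append(
                {"id": ("sv", p["id"]), "kind": "inv", "pos": s, "end": s + size}
            )
        elif cls == "transposition":
            block = branch_codes[branch][chrom][s : s + size].copy()
            branch_edits[branch][chrom].append(
                {"id": ("sv", p["id"], "del"), "kind": "del", "pos": s, "end": s + size}
            )
            branch_edits[branch][chrom].append(
                {"id": ("sv", p["id"]), "kind": "ins", "pos": p["dest"], "payload": block}
            )

    # --- apply --------------------------------------------------------------
    genomes: dict[str, StrainGenome] = {}
    spans: dict[str, dict[str, dict]] = {b: {} for b in STRAINS}
    for branch in STRAINS:
        seqs = {}
        segmap = {}
        for chrom in chroms:
            out, segs, sp = _apply_edits(branch_codes[branch][chrom], branch_edits[branch][chrom])
            seqs[chrom] = codes_to_seq(out)
            segmap[chrom] = segs
            spans[branch][chrom] = sp
        genomes[branch] = StrainGenome(name=branch, sequences=seqs, _segments=segmap)

    # --- truth records ------------------------------------------------------
    records: list[SvRecord] = []
    for p in plans:
        branch, chrom, cls = p["branch"], p["chrom"], p["class"]
        other = {"C": "R", "R": "C"}[branch]
        s, size = p["start"], p["size"]
        gb, go = genomes[branch], genomes[other]
        if cls == "insertion":
            ds, de = spans[branch][chrom][("sv", p["id"])]
            records.append(
                SvRecord(
                    "insertion", branch, chrom, ds, de,
                    copy_number_C=1 if branch == "C" else 0,
                    copy_number_R=1 if branch == "R" else 0,
                    branch=branch, anc_start=s, anc_end=s,
                )
            )
        elif cls == "deletion":
            ps, pe = go.map_position(chrom, s), go.map_position(chrom, s + size)
            records.append(
                SvRecord(
                    "deletion", other, chrom, ps, pe,
                    copy_number_C=0 if branch == "C" else 1,
                    copy_number_R=0 if branch == "R" else 1,
                    branch=branch, anc_start=s, anc_end=s + size,
                )
            )
        elif cls == "tandem_duplication":
            ds, de = spans[branch][chrom][("sv", p["id"])]
            ps, pe = go.map_position(chrom, s), go.map_position(chrom, s + size)
            records.append(
                SvRecord(
                    "tandem_duplication", branch, chrom, ds, de,
                    copy_number_C=model.dup_copies if branch == "C" else 1,
                    copy_number_R=model.dup_copies if branch == "R" else 1,
                    branch=branch,
                    partner_strain=other, partner_start=ps, partner_end=pe,
                    anc_start=s, anc_end=s + size, real_copies=model.dup_copies,
                )
            )
        elif cls == "collapsed_duplication":
            collapsed = p["collapsed_strain"]
            ds, de = spans[branch][chrom][("sv", p["id"])]  # k-copy span, branch frame
            cs, ce = genomes[collapsed].map_position(chrom, s), genomes[collapsed].map_position(
                chrom, s + size
            )
            records.append(
                SvRecord(
                    "collapsed_duplication", collapsed, chrom, cs, ce,
                    copy_number_C=1 if collapsed == "C" else model.dup_copies,
                    copy_number_R=1 if collapsed == "R" else model.dup_copies,
                    branch=branch,
                    partner_strain=branch, partner_start=ds, partner_end=de,
                    anc_start=s, anc_end=s + size, real_copies=model.dup_copies,
                )
            )
        elif cls == "inversion":
            ds, de = spans[branch][chrom][("sv", p["id"])]
            ps, pe = go.map_position(chrom, s), go.map_position(chrom, s + size)
            records.append(
                SvRecord(
                    "inversion", branch, chrom, ds, de, branch=branch,
                    partner_strain=other, partner_start=ps, partner_end=pe,
                    anc_start=s, anc_end=s + size,
                )
            )
        elif cls == "transposition":
            ds, de = spans[branch][chrom][("sv", p["id"])]
            ps, pe = go.map_position(chrom, s), go.map_position(chrom, s + size)
            records.append(
                SvRecord(
                    "transposition", branch, chrom, ds, de, branch=branch,
                    partner_strain=other, partner_start=ps, partner_end=pe,
                    anc_start=s, anc_end=s + size,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.start, r.event_class))
    truth = TruthSet(records=records, snp_positions=snp_positions)
    return genomes["C"], genomes["R"], truth


# ---------------------------------------------------------------------------
# fragmentation


@dataclass
class ScaffoldedGenome:
    """Fragmented scaffolds plus the truth needed to score re-scaffolding."""

    sequences: dict[str, str]
    #: rows (scaffold_id, chrom, start, end, orientation, order_index)
    source: list[tuple[str, str, int, int, str, int]]
    #: truth adjacencies (left_id, left_orient, right_id, right_orient)
    adjacencies: list[tuple[str, str, str, str]]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def fragment(
    genome, n_pieces_per_chrom, min_piece: int = 1000, seed: int = 0
) -> ScaffoldedGenome:
    """Break each chromosome into shuffled, randomly oriented scaffold pieces.

    ``n_pieces_per_chrom`` is an int or a (lo, hi) range sampled per
    chromosome. Reverse-complemented pieces are flagged in the truth tables;
    concatenating pieces in recorded order/orientation reconstructs the input.
    """
    if min_piece < 1:
        raise ValueError("min_piece must be >= 1")
    seqs = genome.sequences if hasattr(genome, "sequences") else dict(genome)
    rng = np.random.default_rng(seed)
    pieces = []  # (chrom, order_index, start, end, orient)
    for chrom, seq in seqs.items():
        L = len(seq)
        if isinstance(n_pieces_per_chrom, int):
            n = n_pieces_per_chrom
        else:
            n = int(rng.integers(n_pieces_per_chrom[0], n_pieces_per_chrom[1] + 1))
        if n < 1:
            raise ValueError("piece count must be >= 1")
        if n * min_piece > L:
            raise ValueError(f"cannot cut {chrom} ({L} bp) into {n} pieces of >= {min_piece} bp")
        # cut points with min_piece spacing, via spacings construction
        slack = L - n * min_piece
        bounds = np.sort(rng.integers(0, slack + 1, size=n - 1)) if n > 1 else np.empty(0, int)
        cuts = [0]
        for i, b in enumerate(bounds):
            cuts.append(int(b) + (i + 1) * min_piece)
        cuts.append(L)
        for i in range(n):
            orient = "+" if (n == 1 or rng.random() < 0.5) else "-"
            pieces.append((chrom, i, cuts[i], cuts[i + 1], orient))

    order = rng.permutation(len(pieces))
    names = {}
    for rank, idx in enumerate(order):
        names[idx] = f"scf_{rank + 1:05d}"

    from ._util import revcomp as _rc

    sequences = {}
    source = []
    for idx, (chrom, oi, s, e, orient) in enumerate(pieces):
        sid = names[idx]
        piece = seqs[chrom][s:e]
        sequences[sid] = piece if orient == "+" else _rc(piece)
        source.append((sid, chrom, s, e, orient, oi))
    sequences = {sid: sequences[sid] for sid in sorted(sequences)}
    source.sort(key=lambda r: (r[1], r[5]))

    adjacencies = []
    by_chrom: dict[str, list] = {}
    for row in source:
        by_chrom.setdefault(row[1], []).append(row)
    for chrom, rows in by_chrom.items():
        rows.sort(key=lambda r: r[5])
        for a, b in zip(rows, rows[1:]):
            adjacencies.append((a[0], a[4], b[0], b[4]))
    return ScaffoldedGenome(sequences=sequences, source=source, adjacencies=adjacencies)


# ---------------------------------------------------------------------------
# read-depth tracks


@dataclass
class DepthTrack:
    """Windowed read depth of one strain's reads mapped onto one assembly."""

    assembly: str
    reads: str
    window: int
    values: dict[str, np.ndarray]
    mean_depth: float

    def window_depths(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depths of all windows overlapping [start, end)."""
        v = self.values[chrom]
        lo = start // self.window
        hi = -(-end // self.window)
        return v[lo:hi]

    def median_over(self, chrom: str, start: int, end: int) -> float:
        w = self.window_depths(chrom, start, end)
        return float(np.median(w)) if w.size else float("nan")

    def genome_median(self) -> float:
        return float(np.median(np.concatenate(list(self.values.values()))))


def _depth_ratio_spans(truth: TruthSet, assembly: str, reads: str):
    """Yield (chrom, start, end, expected-depth ratio) for non-neutral regions."""
    for r in truth.records:
        k = r.real_copies
        if r.event_class == "insertion":
            if r.strain == assembly and reads != assembly:
                yield (r.chrom, r.start, r.end, 0.0)
        elif r.event_class == "deletion":
            if r.strain == assembly and reads != assembly:
                yield (r.chrom, r.start, r.end, 0.0)
        elif r.event_class == "tandem_duplication":
            if r.strain == assembly:  # k-copy span in this assembly
                if reads != assembly:
                    yield (r.chrom, r.start, r.end, 1.0 / k)
            elif r.partner_strain == assembly and reads == r.strain:
                # k copies of reads pile onto the single assembly copy
                yield (r.chrom, r.partner_start, r.partner_end, float(k))
        elif r.event_class == "collapsed_duplication":
            if r.strain == assembly:
                # both strains really carry k copies; assembly kept one
                yield (r.chrom, r.start, r.end, float(k))
            elif r.partner_strain == assembly and reads == r.strain:
                # reads of the collapsed strain over the k-copy assembly: k/k = 1
                pass
        # inversions / transpositions are depth-neutral


def simulate_depth(
    assembly: StrainGenome,
    truth: TruthSet,
    reads: str,
    mean_depth: float = 30.0,
    noise_sd: float = 2.0,
    window: int = 100,
    seed: int = 0,
) -> DepthTrack:
    """Simulate a windowed depth track of ``reads``-strain reads on ``assembly``.

    Expected depth is ``mean_depth`` scaled by the copy-number ratio implied by
    the truth set (0 over assembly-specific sequence when mapping the other
    strain's reads; 1/k per copy over a k-copy duplication mapped by the
    single-copy strain; k over a collapsed duplication). Gaussian noise with
    standard deviation ``noise_sd * sqrt(ratio)`` is added per window and
    depths are clipped at zero.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if window <= 0:
        raise ValueError("window must be > 0")
    rng = substream(seed, "depth", assembly.name, reads)
    values = {}
    for chrom, L in assembly.chrom_lengths.items():
        ratio = np.ones(L)
        for c, s, e, f in _depth_ratio_spans(truth, assembly.name, reads):
            if c == chrom:
                ratio[s:e] = f
        nwin = -(-L // window)
        idx = np.arange(0, L, window)
        wratio = np.add.reduceat(ratio, idx) / np.diff(np.append(idx, L))
        depth = wratio * mean_depth + rng.normal(0.0, noise_sd, size=nwin) * np.sqrt(wratio)
        values[chrom] = np.clip(depth, 0.0, None)
    return DepthTrack(
        assembly=assembly.name, reads=reads, window=window, values=values, mean_depth=mean_depth
    )


def depth_track_set(
    genome_C: StrainGenome,
    genome_R: StrainGenome,
    truth: TruthSet,
    mean_depth: float = 30.0,
    noise_sd: float = 2.0,
    window: int = 100,
    seed: int = 0,
) -> dict[tuple[str, str], DepthTrack]:
    """All four (assembly, reads) depth tracks used by SV validation."""
    out = {}
    for asm in (genome_C, genome_R):
        for reads in STRAINS:
            out[(asm.name, reads)] = simulate_depth(
                asm, truth, reads, mean_depth, noise_sd, window, seed
            )
    return out


# ---------------------------------------------------------------------------
# two-population genotype simulator


@dataclass
class MtLocusSpec:
    """A haploid high-divergence locus emulating mitochondrial DNA."""

    n_sites: int = 40
    n_fixed: int = 30
    chrom: str = "mt"


@dataclass
class PopulationSimSpec:
    """Balding-Nichols two-population diploid SNP simulation parameters."""

    n_individuals_per_pop: int = 9
    n_sites: int = 10000
    between_pop_divergence: float = 0.02
    site_positions: np.ndarray | None = None
    chrom: str = "nuc1"
    mt_locus: MtLocusSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals_per_pop < 2:
            raise ValueError("need at least two individuals per population")
        if not 0.0 <= self.between_pop_divergence <= 1.0:
            raise ValueError("between_pop_divergence must lie in [0, 1]")
        if self.site_positions is not None:
            p = np.asarray(self.site_positions)
            if p.size != self.n_sites or np.any(np.diff(p) <= 0):
                raise ValueError("site_positions must be strictly increasing, one per site")


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes (alt-allele dosage; -1 = missing)."""

    samples: list[str]
    pops: np.ndarray  # per-sample population label, 'C' or 'R'
    chrom: np.ndarray  # per-site
    pos: np.ndarray  # per-site, sorted within chrom
    dosage: np.ndarray  # (n_sites, n_samples) int8

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def pop_mask(self, pop: str) -> np.ndarray:
        return self.pops == pop

    def subset_sites(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples, self.pops, self.chrom[mask], self.pos[mask], self.dosage[mask]
        )

    def relabel(self, pops) -> "GenotypeMatrix":
        return dataclasses.replace(self, pops=np.asarray(pops, dtype=object))


def simulate_populations(spec: PopulationSimSpec) -> GenotypeMatrix:
    """Draw a two-population diploid genotype matrix.

    Per nuclear site: ancestral frequency ~ Uniform(0.05, 0.95); population
    frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with F the differentiation
    target (F = 0 degenerates to identical frequencies); genotypes ~
    Binomial(2, p_pop). The optional mitochondrial-like locus is haploid
    (dosage 0/2, heterozygotes impossible) with ``n_fixed`` fixed differences
    and the remainder shared intermediate-frequency polymorphism.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals_per_pop
    F = spec.between_pop_divergence
    m = spec.n_sites
    p_anc = rng.uniform(0.05, 0.95, size=m)
    if F == 0.0:
        p_C = p_anc
        p_R = p_anc.copy()
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_C = rng.beta(a, b)
        p_R = rng.beta(a, b)
    dos_C = rng.binomial(2, p_C[:, None], size=(m, n)).astype(np.int8)
    dos_R = rng.binomial(2, p_R[:, None], size=(m, n)).astype(np.int8)
    dosage = np.concatenate([dos_C, dos_R], axis=1)
    pos = (
        np.asarray(spec.site_positions, dtype=np.int64)
        if spec.site_positions is not None
        else np.arange(1, m + 1, dtype=np.int64) * 100
    )
    chrom = np.full(m, spec.chrom, dtype=object)

    if spec.mt_locus is not None:
        mt = spec.mt_locus
        k = mt.n_sites
        hap_C = np.zeros((k, n), dtype=np.int8)
        hap_R = np.zeros((k, n), dtype=np.int8)
        fixed = np.arange(k) < mt.n_fixed
        hap_R[fixed] = 1
        shared = ~fixed
        freq = rng.uniform(0.2, 0.8, size=int(shared.sum()))
        hap_C[shared] = rng.binomial(1, freq[:, None], size=(freq.size, n))
        hap_R[shared] = rng.binomial(1, freq[:, None], size=(freq.size, n))
        mt_dosage = np.concatenate([hap_C, hap_R], axis=1) * 2  # haploid as homozygous
        dosage = np.concatenate([dosage, mt_dosage.astype(np.int8)], axis=0)
        chrom = np.concatenate([chrom, np.full(k, mt.chrom, dtype=object)])
        pos = np.concatenate([pos, np.arange(1, k + 1, dtype=np.int64) * 10])

    samples = [f"MS_C{i + 1}" for i in range(n)] + [f"MS_R{i + 1}" for i in range(n)]
    pops = np.array(["C"] * n + ["R"] * n, dtype=object)
    return GenotypeMatrix(samples=samples, pops=pops, chrom=chrom, pos=pos, dosage=dosage)


# ---------------------------------------------------------------------------
# gene planting


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str


def _as_lengths(genome) -> dict[str, int]:
    if hasattr(genome, "chrom_lengths"):
        return genome.chrom_lengths
    first = next(iter(genome.values()), None)
    if isinstance(first, str):
        return {c: len(s) for c, s in genome.items()}
    return dict(genome)


def plant_genes(
    genome,
    n_genes: int,
    categories: dict[str, float],
    sv_enrichment_factor: float = 1.0,
    truth=None,
    enriched_category: str | None = None,
    gene_size: tuple[int, int] = (300, 1500),
    seed: int = 0,
) -> list[GeneModel]:
    """Place non-overlapping single-exon gene models and assign categories.

    Genes land uniformly over the genome. Inside the structural-variant
    intervals of ``truth`` (a :class:`TruthSet`, scored in the genome's own
    frame, or a plain {chrom: [(start, end)]} mapping) the odds of drawing
    ``enriched_category`` are multiplied by ``sv_enrichment_factor``, so the
    expected in/out odds ratio of that category equals the factor.
    """
    lengths = _as_lengths(genome)
    rng = np.random.default_rng(seed)
    probs = np.array(list(categories.values()), dtype=float)
    if probs.sum() <= 0:
        raise ValueError("category probabilities must sum to > 0")
    probs = probs / probs.sum()
    names = list(categories)
    if enriched_category is None and sv_enrichment_factor != 1.0:
        raise ValueError("sv_enrichment_factor != 1 requires enriched_category")

    if truth is None:
        sv_iv: dict[str, list[tuple[int, int]]] = {}
    elif isinstance(truth, TruthSet):
        frame = getattr(genome, "name", "C")
        sv_iv = truth.intervals(frame)
    else:
        sv_iv = {c: sorted(v) for c, v in truth.items()}

    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    genes: list[GeneModel] = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    tries = 0
    while len(genes) < n_genes:
        tries += 1
        if tries > 50 * n_genes + 1000:
            raise RuntimeError(f"could not place {n_genes} non-overlapping genes")
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        size = int(rng.integers(gene_size[0] // 3, gene_size[1] // 3 + 1)) * 3
        if size >= lengths[chrom]:
            continue
        s = int(rng.integers(0, lengths[chrom] - size))
        e = s + size
        if any(s < pe and e > ps for ps, pe in placed[chrom]):
            continue
        placed[chrom].append((s, e))
        in_sv = any(s < ive and e > ivs for ivs, ive in sv_iv.get(chrom, []))
        w = probs.copy()
        if in_sv and enriched_category is not None:
            w[names.index(enriched_category)] *= sv_enrichment_factor
            w = w / w.sum()
        cat = names[int(rng.choice(len(names), p=w))]
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_{len(genes) + 1:05d}", chrom, s, e, strand, cat))
    genes.sort(key=lambda g: (g.chrom, g.start))
    for i, g in enumerate(genes):
        g.gene_id = f"gene_{i + 1:05d}"
    return genes


def cds_sequence(genome, gene: GeneModel) -> str:
    """Extract a gene's CDS (reverse-complemented on the minus strand)."""
    from ._util import revcomp as _rc

    seqs = genome.sequences if hasattr(genome, "sequences") else genome
    s = seqs[gene.chrom][gene.start : gene.end]
    return _rc(s) if gene.strand == "-" else s


def lift_genes(genes: list[GeneModel], strain: StrainGenome) -> list[GeneModel]:
    """Lift ancestor-frame gene models onto a diverged strain.

    Genes overlapping branch-specific rearrangements (so not wholly inside an
    identity segment) are dropped.
    """
    out = []
    for g in genes:
        if strain.in_identity_segment(g.chrom, g.start, g.end):
            s = strain.map_position(g.chrom, g.start)
            out.append(GeneModel(g.gene_id, g.chrom, s, s + (g.end - g.start), g.strand, g.category))
    return out
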