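"""Readers and writers for the standard formats the pipeline exchanges.

FASTA via Biopython; VCF v4.2 (GT-only) read via cyvcf2 and written as text;
BED/bedGraph/GFF3/AGP/TSV/PHYLIP as plain text. All internal coordinates are
0-based half-open; GFF3 and VCF writers convert to 1-based inclusive.
"""

from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .sim import DepthTrack, GeneModel, GenotypeMatrix, SvRecord, TruthSet


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# truth / intervals


def write_truth_tsv(truth: TruthSet, path) -> None:
    cols = (
        "event_class strain chrom start end copy_number_C copy_number_R branch "
        "partner_strain partner_start partner_end anc_start anc_end real_copies"
    ).split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in truth.records:
            fh.write(
                "\t".join(str(getattr(r, c) if getattr(r, c) is not None else ".") for c in cols)
                + "\n"
            )


def read_truth_tsv(path) -> TruthSet:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            records.append(
                SvRecord(
                    event_class=vals["event_class"],
                    strain=vals["strain"],
                    chrom=vals["chrom"],
                    start=int(vals["start"]),
                    end=int(vals["end"]),
                    copy_number_C=int(vals["copy_number_C"]),
                    copy_number_R=int(vals["copy_number_R"]),
                    branch=vals["branch"],
                    partner_strain=None if vals["partner_strain"] == "." else vals["partner_strain"],
                    partner_start=None if vals["partner_start"] == "." else int(vals["partner_start"]),
                    partner_end=None if vals["partner_end"] == "." else int(vals["partner_end"]),
                    anc_start=int(vals["anc_start"]),
                    anc_end=int(vals["anc_end"]),
                    real_copies=int(vals["real_copies"]),
                )
            )
    return TruthSet(records=records, snp_positions={})


def write_bed(rows, path) -> None:
    """rows: iterables (chrom, start, end, name, ...) written as BED columns."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# depth tracks


def write_bedgraph(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# assembly={track.assembly} reads={track.reads} window={track.window}\n")
        for chrom, vals in track.values.items():
            for i, v in enumerate(vals.tolist()):
                fh.write(f"{chrom}\t{i * track.window}\t{(i + 1) * track.window}\t{v:.3f}\n")


def read_bedgraph(path) -> DepthTrack:
    assembly = reads = ""
    window = 0
    values: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                meta = dict(kv.split("=") for kv in line[1:].split())
                assembly, reads = meta.get("assembly", ""), meta.get("reads", "")
                window = int(meta.get("window", 0))
                continue
            chrom, start, end, v = line.rstrip("\n").split("\t")
            if window == 0:
                window = int(end) - int(start)
            values.setdefault(chrom, []).append(float(v))
    vals = {c: np.asarray(v) for c, v in values.items()}
    mean = float(np.median(np.concatenate(list(vals.values())))) if vals else 0.0
    return DepthTrack(assembly=assembly, reads=reads, window=window, values=vals, mean_depth=mean)


# ---------------------------------------------------------------------------
# genes


def write_gff3(genes: list[GeneModel], path, source: str = "strainpair") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};category={g.category}"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if ftype != "gene":
                continue
            kv = dict(x.split("=", 1) for x in attrs.split(";") if "=" in x)
            genes.append(
                GeneModel(
                    gene_id=kv.get("ID", f"{chrom}:{start}"),
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    category=kv.get("category", "other"),
                )
            )
    return genes


def write_categories_tsv(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcategory\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.category}\n")


def read_categories_tsv(path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            parts = header.rstrip("\n").split("\t")
            out[parts[0]] = parts[1]
        for line in fh:
            gid, cat = line.rstrip("\n").split("\t")[:2]
            out[gid] = cat
    return out


# ---------------------------------------------------------------------------
# VCF


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with GT genotypes (synthetic REF=A, ALT=T)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=strainpair\n")
        for chrom in dict.fromkeys(gm.chrom.tolist()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        gt_of = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for i in range(gm.n_sites):
            row = [str(gm.chrom[i]), str(int(gm.pos[i])), ".", "A", "T", ".", "PASS", ".", "GT"]
            row += [gt_of[int(x)] for x in gm.dosage[i]]
            fh.write("\t".join(row) + "\n")


def read_vcf(path, pop_of=None) -> GenotypeMatrix:
    """Read GT dosages from a VCF (biallelic sites only).

    ``pop_of`` maps sample name -> population label; by default samples whose
    name contains ``"R"`` after the last ``_`` prefix letter are R, else C
    (matching the simulator's MS_C*/MS_R* naming).
    """
    from cyvcf2 import VCF

    v = VCF(str(path), gts012=True)
    samples = list(v.samples)
    chroms, poss, rows = [], [], []
    for var in v:
        if len(var.ALT) != 1:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gt = var.gt_types.astype(np.int8)  # 0,1,2 and 3=missing with gts012
        gt[gt == 3] = -1
        rows.append(gt.copy())
    if pop_of is None:
        pops = np.array(["R" if "R" in s.split("_")[-1] else "C" for s in samples], dtype=object)
    else:
        pops = np.array([pop_of[s] for s in samples], dtype=object)
    return GenotypeMatrix(
        samples=samples,
        pops=pops,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosage=np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# alignment artefacts


def write_chains_tsv(chains, path) -> None:
    """chain_id, q_chrom, q_start, q_end, t_chrom, t_start, t_end, strand,
    score, n_anchors, aligned_bp (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(
            "chain_id\tq_chrom\tq_start\tq_end\tt_chrom\tt_start\tt_end\t"
            "strand\tscore\tn_anchors\taligned_bp\n"
        )
        for c in chains:
            fh.write(
                f"{c.id}\t{c.q_chrom}\t{c.q_start}\t{c.q_end}\t{c.t_chrom}\t"
                f"{c.t_start}\t{c.t_end}\t{c.strand}\t{c.score:.1f}\t"
                f"{len(c.anchors)}\t{c.aligned_bp}\n"
            )


def write_net_tsv(net, path) -> None:
    """chain_id, level, parent_chain_id, t_chrom, t_start, t_end."""
    with open(path, "w") as fh:
        fh.write("chain_id\tlevel\tparent_chain_id\tt_chrom\tt_start\tt_end\n")
        for e in net.entries:
            parent = e.parent_chain_id if e.parent_chain_id is not None else "."
            fh.write(
                f"{e.chain_id}\t{e.level}\t{parent}\t{e.t_chrom}\t"
                f"{e.t_interval[0]}\t{e.t_interval[1]}\n"
            )


def write_agp(agp_rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version 2.1\n")
        for row in agp_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_variants_tsv(variants, path) -> None:
    cols = (
        "event_class ref_strain chrom start end partner_strain partner_start "
        "partner_end copy_number_ref copy_number_other validated"
    ).split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for v in variants:
            vals = []
            for c in cols:
                x = getattr(v, c)
                if c == "validated":
                    x = {True: "true", False: "false", None: "untested"}[x]
                vals.append("." if x is None else str(x))
            fh.write("\t".join(vals) + "\n")


def write_phylip(ids, matrix, path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, name in enumerate(ids):
            row = " ".join(f"{matrix[i, j]:.6f}" for j in range(len(ids)))
            fh.write(f"{name[:10]:<10} {row}\n")
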