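"""Functional-category enrichment of genes inside structural-variant regions.

Genes are partitioned by any-bp overlap with the SV region union, each
category is tested for over-representation inside SV regions with a one-sided
Fisher exact test, and p-values are Benjamini-Hochberg adjusted across
categories. Significance labels follow the convention: q < 0.001 -> "***",
q >= 0.05 -> "ns", anything between -> "other".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .sim import GeneModel


def genes_in_regions(
    genes: list[GeneModel],
    regions: dict[str, list[tuple[int, int]]],
    chroms=None,
) -> tuple[set[str], set[str]]:
    """Partition gene ids into (inside, outside) an SV region union.

    A gene is inside iff it shares >= 1 bp with any region (half-open
    coordinates, so a gene abutting a region boundary is outside). When
    ``chroms`` is given, genes on chromosomes outside it raise an error.
    """
    trees = {c: IntervalTree.from_tuples((s, e) for s, e in iv if e > s) for c, iv in regions.items()}
    inside, outside = set(), set()
    for g in genes:
        if chroms is not None and g.chrom not in chroms:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
        t = trees.get(g.chrom)
        if t is not None and t.overlap(g.start, g.end):
            inside.add(g.gene_id)
        else:
            outside.add(g.gene_id)
    return inside, outside


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def _label(q: float) -> str:
    if q < 0.001:
        return "***"
    if q >= 0.05:
        return "ns"
    return "other"


def category_enrichment(
    partition: tuple[set[str], set[str]],
    categories: dict[str, str],
) -> pd.DataFrame:
    """Per-category over-representation inside the SV partition.

    ``partition`` is (inside ids, outside ids); ``categories`` maps every gene
    id to exactly one category label. For each category a 2x2 table
    (in&cat, in&other, out&cat, out&other) is tested with Fisher's exact test
    (one-sided, greater) and BH-adjusted across categories. With an empty
    partition side all tests report p = q = 1.
    """
    inside, outside = partition
    for gid in inside | outside:
        if gid not in categories:
            raise ValueError(f"gene {gid} has no category label")
    cats = sorted(set(categories[g] for g in inside | outside))
    rows = []
    degenerate = not inside or not outside
    for cat in cats:
        a = sum(1 for g in inside if categories[g] == cat)
        b = len(inside) - a
        c = sum(1 for g in outside if categories[g] == cat)
        d = len(outside) - c
        if degenerate:
            odds, p = float("nan"), 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((cat, a, b, c, d, float(odds), float(p)))
    df = pd.DataFrame(
        rows,
        columns=["category", "n_in_cat", "n_in_other", "n_out_cat", "n_out_other", "odds_ratio", "p"],
    )
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    df["label"] = [_label(q) for q in df["q"]]
    return df
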