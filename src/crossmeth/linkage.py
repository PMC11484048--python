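"""DMR liftover between assemblies and gene-region linkage.

Lifting uses the block coordinate map: a DMR lifts when at least 90% of its
bases map onto a single target chromosome, and a lifted DMR pairs with a
target-side DMR when they overlap reciprocally by at least 90% of each
length. Gene-anchored region classes follow the distance-defined enhancer
convention: on each side of the gene body, a 5-kb flank and a 125-kb
putative enhancer window running from 130 kb to 5 kb away; "upstream" is
strand-aware. DMR-to-region assignment uses the bedtools
``-f 0.9 -F 0.9 -e`` OR semantics: an overlap covering >=90% of the DMR or
>=90% of the region assigns the DMR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coords import CoordinateMap

REGION_CLASSES = (
    "upstream_enhancer", "upstream_5kb", "gene_body", "downstream_5kb", "downstream_enhancer",
)
ENHANCER_FAR = 130_000
ENHANCER_NEAR = 5_000


# ---------------------------------------------------------------- liftover


def liftover_and_filter(dmrs: pd.DataFrame, coord_map: CoordinateMap,
                        dmrs_other: pd.DataFrame, min_frac: float = 0.9):
    """Lift DMRs through the map and pair them with target-side DMRs.

    ``dmrs`` / ``dmrs_other`` need columns chrom, start0, end0, direction.
    Returns (pairs, unmapped): pairs carries the source DMR, its lifted
    interval and the matched target DMR; unmapped lists DMRs that failed the
    90%-mapped-bases rule (e.g. inside deleted segments or off-map contigs).
    """
    lifted_rows = []
    unmapped = []
    for i, r in enumerate(dmrs.itertuples(index=False)):
        length = r.end0 - r.start0
        mapped, dchrom, lo, hi = coord_map.map_interval(r.chrom, r.start0, r.end0)
        if dchrom is None or mapped < min_frac * length:
            unmapped.append(i)
            continue
        lifted_rows.append((i, r.chrom, r.start0, r.end0, r.direction, dchrom, lo, hi))
    lifted = pd.DataFrame(
        lifted_rows,
        columns=["src_idx", "chrom", "start0", "end0", "direction",
                 "lift_chrom", "lift_start0", "lift_end0"],
    )
    pair_rows = []
    for lr in lifted.itertuples(index=False):
        llen = lr.lift_end0 - lr.lift_start0
        cand = dmrs_other[dmrs_other["chrom"] == lr.lift_chrom]
        for j, tr in zip(cand.index, cand.itertuples(index=False)):
            ov = min(lr.lift_end0, tr.end0) - max(lr.lift_start0, tr.start0)
            if ov <= 0:
                continue
            tlen = tr.end0 - tr.start0
            if ov >= min_frac * llen and ov >= min_frac * tlen:
                pair_rows.append(
                    (lr.src_idx, lr.chrom, lr.start0, lr.end0, lr.direction,
                     lr.lift_chrom, lr.lift_start0, lr.lift_end0,
                     j, tr.start0, tr.end0, tr.direction)
                )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["src_idx", "src_chrom", "src_start0", "src_end0", "src_direction",
                 "lift_chrom", "lift_start0", "lift_end0",
                 "tgt_idx", "tgt_start0", "tgt_end0", "tgt_direction"],
    )
    return pairs, dmrs.iloc[unmapped].reset_index(drop=True)


def detect_direction_changes(pairs: pd.DataFrame) -> pd.DataFrame:
    """Pairs whose hypo/hyper direction flips between references."""
    if pairs.empty:
        return pairs
    return pairs[pairs["src_direction"] != pairs["tgt_direction"]].reset_index(drop=True)


# ---------------------------------------------------------------- gene regions


def build_gene_regions(genes: pd.DataFrame, contig_lengths: dict[str, int]) -> pd.DataFrame:
    """Five strand-aware region classes per gene, clipped to the contig.

    For a plus-strand gene [s, e): upstream_enhancer [s-130k, s-5k),
    upstream_5kb [s-5k, s), gene_body [s, e), downstream_5kb [e, e+5k),
    downstream_enhancer [e+5k, e+130k); minus-strand genes are mirrored.
    Regions emptied by clipping are dropped.
    """
    if genes["strand"].isna().any() or (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("every gene needs a '+' or '-' strand")
    rows = []
    for g in genes.itertuples(index=False):
        L = contig_lengths[g.chrom]
        s, e = g.start0, g.end0
        if g.strand == "+":
            spans = {
                "upstream_enhancer": (s - ENHANCER_FAR, s - ENHANCER_NEAR),
                "upstream_5kb": (s - ENHANCER_NEAR, s),
                "gene_body": (s, e),
                "downstream_5kb": (e, e + ENHANCER_NEAR),
                "downstream_enhancer": (e + ENHANCER_NEAR, e + ENHANCER_FAR),
            }
        else:
            spans = {
                "upstream_enhancer": (e + ENHANCER_NEAR, e + ENHANCER_FAR),
                "upstream_5kb": (e, e + ENHANCER_NEAR),
                "gene_body": (s, e),
                "downstream_5kb": (s - ENHANCER_NEAR, s),
                "downstream_enhancer": (s - ENHANCER_FAR, s - ENHANCER_NEAR),
            }
        for cls, (a, b) in spans.items():
            a2, b2 = max(0, a), min(L, b)
            if b2 > a2:
                rows.append((g.gene_id, cls, g.chrom, a2, b2))
    return pd.DataFrame(rows, columns=["gene_id", "region_class", "chrom", "start0", "end0"])


# ---------------------------------------------------------------- assignment


def _overlap_assigned(dmr_start, dmr_end, reg_start, reg_end, min_frac=0.9) -> bool:
    ov = min(dmr_end, reg_end) - max(dmr_start, reg_start)
    if ov <= 0:
        return False
    return ov >= min_frac * (dmr_end - dmr_start) or ov >= min_frac * (reg_end - reg_start)


@dataclass
class LinkageSummary:
    class_counts: pd.DataFrame      # region_class, n_dmrs, total_length, dmrs_per_mb
    assignments: pd.DataFrame       # dmr_idx, gene_id, region_class
    deg_overlaps: pd.DataFrame      # gene_id, direction, dmr_idx list length
    imprinted: pd.DataFrame
    warnings: list


def assign_dmrs(dmrs: pd.DataFrame, regions: pd.DataFrame,
                deg_table: pd.DataFrame | None = None,
                imprinted: pd.DataFrame | None = None,
                min_frac: float = 0.9) -> LinkageSummary:
    """Assign DMRs to gene region classes with the 0.9/0.9 OR rule.

    A DMR may count in several classes and several genes; within one
    (gene, class) it counts once. Class totals are length-normalized to
    DMRs per Mb of (merged) region length.
    """
    assign_rows = []
    for cls in REGION_CLASSES:
        sub = regions[regions["region_class"] == cls]
        for chrom in sub["chrom"].unique():
            sc = sub[sub["chrom"] == chrom]
            dc = dmrs[dmrs["chrom"] == chrom]
            if dc.empty:
                continue
            for reg in sc.itertuples(index=False):
                for di, dr in zip(dc.index, dc.itertuples(index=False)):
                    if _overlap_assigned(dr.start0, dr.end0, reg.start0, reg.end0, min_frac):
                        assign_rows.append((di, reg.gene_id, cls))
    assignments = pd.DataFrame(assign_rows, columns=["dmr_idx", "gene_id", "region_class"]).drop_duplicates()

    class_rows = []
    for cls in REGION_CLASSES:
        sub = regions[regions["region_class"] == cls]
        merged_len = 0
        for chrom in sub["chrom"].unique():
            iv = sorted(zip(sub[sub["chrom"] == chrom]["start0"], sub[sub["chrom"] == chrom]["end0"]))
            last_end = -1
            for s, e in iv:
                s2 = max(s, last_end)
                if e > s2:
                    merged_len += e - s2
                    last_end = e
                last_end = max(last_end, e)
        n = assignments[assignments["region_class"] == cls]["dmr_idx"].nunique()
        mb = merged_len / 1e6
        class_rows.append((cls, int(n), int(merged_len), n / mb if mb > 0 else np.nan))
    class_counts = pd.DataFrame(class_rows, columns=["region_class", "n_dmrs", "total_length", "dmrs_per_mb"])

    warnings = []
    deg_rows = []
    if deg_table is not None:
        known = set(regions["gene_id"])
        for dg in deg_table.itertuples(index=False):
            if dg.gene_id not in known:
                warnings.append(f"DEG {dg.gene_id} absent from the gene annotation")
                continue
            hit = assignments[assignments["gene_id"] == dg.gene_id]["dmr_idx"].unique()
            deg_rows.append((dg.gene_id, dg.direction, len(hit), list(hit)))
    deg_overlaps = pd.DataFrame(deg_rows, columns=["gene_id", "direction", "n_dmrs", "dmr_idxs"])

    imprinted_df = pd.DataFrame()
    if imprinted is not None:
        imprinted_df = summarize_imprinted(dmrs, assignments, imprinted, deg_table, warnings,
                                           known_genes=set(regions["gene_id"]))
    return LinkageSummary(class_counts, assignments, deg_overlaps, imprinted_df, warnings)


def summarize_imprinted(dmrs: pd.DataFrame, assignments: pd.DataFrame,
                        imprinted: pd.DataFrame, deg_table: pd.DataFrame | None = None,
                        warnings: list | None = None,
                        known_genes: set | None = None) -> pd.DataFrame:
    """Per imprinted gene: hypo/hyper DMR counts and DEG status.

    Genes without any overlapping DMR appear with zero counts; imprinted
    ids absent from the annotation go to the warnings list.
    """
    warnings = warnings if warnings is not None else []
    deg_dir = {}
    if deg_table is not None:
        deg_dir = dict(zip(deg_table["gene_id"], deg_table["direction"]))
    rows = []
    for g in imprinted.itertuples(index=False):
        if known_genes is not None and g.gene_id not in known_genes:
            warnings.append(f"imprinted gene {g.gene_id} absent from the gene annotation")
            continue
        hit = assignments[assignments["gene_id"] == g.gene_id]["dmr_idx"].unique()
        dirs = dmrs.loc[hit, "direction"] if len(hit) else pd.Series(dtype=str)
        rows.append(
            (g.gene_id, getattr(g, "symbol", g.gene_id),
             int((dirs == "hypo").sum()), int((dirs == "hyper").sum()),
             deg_dir.get(g.gene_id, "-"))
        )
    return pd.DataFrame(rows, columns=["gene_id", "symbol", "n_hypo", "n_hyper", "deg_direction"])
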