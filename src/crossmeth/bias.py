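"""Quantification bias attributable to reference-genome choice.

The same biological sample quantified against two assemblies yields two
methylation vectors; systematic differences between them are reference bias,
not biology. This module implements the comparison battery used to measure
it: sample-wise and pooled group-wise distribution tests (two-sample
Kolmogorov-Smirnov as the primary statistic, Wilcoxon rank-sum as the
companion), matched shared-CpG divergence (RMSE and variable-CpG counts),
paired signed-rank tests inside homologous 100-kb windows, and the shift of
breed-specific-CpG methylation against the shared-site background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import MethylationCallSet


# ---------------------------------------------------------------- vectors


def methylation_vector(calls: MethylationCallSet, min_cov: int = 10,
                       site_filter: pd.DataFrame | None = None) -> np.ndarray:
    """Percent methylation of every site with >= min_cov coverage.

    ``site_filter`` optionally restricts to given (chrom, pos0) rows, e.g.
    the shared CpGs from crossmap. Values are ordered by (chrom, pos0).
    """
    d = calls.df
    d = d[d["coverage"] >= min_cov]
    if site_filter is not None:
        key = pd.MultiIndex.from_frame(site_filter[["chrom", "pos0"]])
        d = d[pd.MultiIndex.from_frame(d[["chrom", "pos0"]]).isin(key)]
    if d.empty:
        raise ValueError("no sites left after filtering")
    d = d.sort_values(["chrom", "pos0"], kind="mergesort")
    return 100.0 * d["n_meth"].to_numpy() / d["coverage"].to_numpy()


# ---------------------------------------------------------------- distribution tests


@dataclass
class BiasResult:
    mean_abs_diff_pct: float
    mean_diff_pct: float  # signed, A minus B after subsetting
    ks_stat: float
    ks_p: float
    ranksum_p: float
    n_sites_used: int
    seed: int
    ks_p_adj: float = np.nan


def compare_reference_bias(vec_a: np.ndarray, vec_b: np.ndarray, seed: int) -> BiasResult:
    """Down-sample the larger vector to the smaller's length (one draw,
    without replacement, under ``seed``), then compare distributions."""
    if seed is None:
        raise ValueError("a seed is required: the subset draw must be reproducible")
    if len(vec_a) == 0 or len(vec_b) == 0:
        raise ValueError("empty methylation vector")
    rng = np.random.default_rng(seed)
    a, b = np.asarray(vec_a, dtype=float), np.asarray(vec_b, dtype=float)
    n = min(a.size, b.size)
    if a.size > n:
        a = rng.choice(a, size=n, replace=False)
    elif b.size > n:
        b = rng.choice(b, size=n, replace=False)
    if np.array_equal(a, b):
        ks_stat, ks_p = 0.0, 1.0
        rs_p = 1.0
    else:
        ks_stat, ks_p = sps.ks_2samp(a, b)
        rs_p = sps.mannwhitneyu(a, b, alternative="two-sided")[1]
    return BiasResult(
        mean_abs_diff_pct=float(abs(a.mean() - b.mean())),
        mean_diff_pct=float(a.mean() - b.mean()),
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
        ranksum_p=float(rs_p),
        n_sites_used=int(n),
        seed=seed,
    )


def adjust_bias_batch(results: list[BiasResult]) -> list[BiasResult]:
    """BH adjustment of KS p-values across a batch of samples/groups."""
    ps = [r.ks_p for r in results]
    padj = multipletests(ps, method="fdr_bh")[1]
    for r, q in zip(results, padj):
        r.ks_p_adj = float(q)
    return results


# ---------------------------------------------------------------- matched divergence


@dataclass
class MatchedDivergence:
    rmse: float  # proportion scale (0-1)
    n_abs_diff_gt_10pct: int
    n_abs_diff_gt_50pct: int
    n_matched: int
    table: pd.DataFrame  # variable CpGs: chrom, pos0, pct_a, pct_b, diff


def matched_cpg_divergence(calls_a: MethylationCallSet, calls_b: MethylationCallSet,
                           shared_map: pd.DataFrame, min_cov: int = 10) -> MatchedDivergence:
    """Per-site divergence over matched shared CpGs covered >=min_cov in both.

    ``shared_map`` columns: chrom, pos0 (reference A) and counterpart_chrom,
    counterpart_pos0 (reference B), as produced by crossmap.shared_pairs.
    RMSE is on the proportion scale; the >10 / >50 thresholds are percentage
    points, and sites beyond 10 points are returned as the variable-CpG table.
    """
    da = calls_a.df[calls_a.df["coverage"] >= min_cov].set_index(["chrom", "pos0"])
    db = calls_b.df[calls_b.df["coverage"] >= min_cov].set_index(["chrom", "pos0"])
    rows = []
    for r in shared_map.itertuples(index=False):
        ka = (r.chrom, r.pos0)
        kb = (r.counterpart_chrom, r.counterpart_pos0)
        if ka in da.index and kb in db.index:
            ra = da.loc[ka]
            rb = db.loc[kb]
            pa = 100.0 * float(ra["n_meth"]) / float(ra["coverage"])
            pb = 100.0 * float(rb["n_meth"]) / float(rb["coverage"])
            rows.append((r.chrom, r.pos0, pa, pb, pa - pb))
    if not rows:
        raise ValueError("no matched shared CpGs with sufficient coverage in both call sets")
    tab = pd.DataFrame(rows, columns=["chrom", "pos0", "pct_a", "pct_b", "diff"])
    diff_prop = (tab["diff"] / 100.0).to_numpy()
    return MatchedDivergence(
        rmse=float(np.sqrt(np.mean(diff_prop**2))),
        n_abs_diff_gt_10pct=int((tab["diff"].abs() > 10).sum()),
        n_abs_diff_gt_50pct=int((tab["diff"].abs() > 50).sum()),
        n_matched=int(tab.shape[0]),
        table=tab[tab["diff"].abs() > 10].reset_index(drop=True),
    )


# ---------------------------------------------------------------- homologous windows


def find_homologous_windows(genome_a: dict[str, str], genome_b: dict[str, str],
                            win: int = 100_000, k: int = 21, stride: int = 8,
                            query_stride: int = 15, min_anchors: int = 20) -> pd.DataFrame:
    """Coarse window homology via the shared anchor index (modal diagonal).

    Returns one row per A-window that places confidently on B:
    chrom_a, start_a, end_a, chrom_b, start_b, end_b, short_last (flag).
    """
    from .align import GenomeIndex, best_diagonal_cluster, encode, kmer_codes

    index = GenomeIndex.build(genome_b, k, stride)
    rows = []
    for chrom, seq in genome_a.items():
        codes = kmer_codes(encode(seq), k)
        s_idx = np.arange(0, codes.size, query_stride)
        tpos, tci, _ = index.match(codes[s_idx])
        for start in range(0, len(seq), win):
            end = min(len(seq), start + win)
            i0 = -(-start // query_stride)
            i1 = max(i0, (end - k) // query_stride)
            sl = slice(i0, i1 + 1)
            hit = tpos[sl] >= 0
            if int(hit.sum()) < min_anchors:
                continue
            qp = s_idx[sl][hit] - start
            best = None
            for ci in np.unique(tci[sl][hit]):
                s2 = tci[sl][hit] == ci
                cl = best_diagonal_cluster(qp[s2], tpos[sl][hit][s2])
                if cl and (best is None or cl[1] > best[1]):
                    best = (int(ci), cl[1], cl[0])
            if best is None or best[1] < min_anchors:
                continue
            ci, _, diag = best
            # cluster diagonals are t - (q - start), i.e. the absolute
            # target coordinate of the window start
            rows.append(
                (chrom, start, end, index.chroms[ci], max(0, diag),
                 diag + (end - start), end - start < win)
            )
    return pd.DataFrame(
        rows, columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "short_last"]
    )


@dataclass
class WindowBiasResult:
    windows: pd.DataFrame  # chrom, start, end, n_paired_cpgs, mean_diff, p, p_adj
    n_tested: int
    n_skipped: int


def homologous_window_bias(shared_map: pd.DataFrame,
                           calls_a: list[MethylationCallSet],
                           calls_b: list[MethylationCallSet],
                           chrom_lengths: dict[str, int],
                           win: int = 100_000, min_cov: int = 10,
                           min_pairs: int = 10,
                           windows: pd.DataFrame | None = None) -> WindowBiasResult:
    """Wilcoxon signed-rank on paired per-CpG group means within windows.

    Windows tile reference A (or are supplied, e.g. from
    :func:`find_homologous_windows`); within each, shared CpGs pair the two
    references, the per-CpG value is the mean across the group's samples on
    each side, and a two-sided signed-rank test is applied to the paired
    differences. Windows with fewer than ``min_pairs`` paired CpGs are
    skipped (and counted). BH correction across tested windows.
    """

    def group_mean(calls, key_cols):
        frames = []
        for cs in calls:
            d = cs.df[cs.df["coverage"] >= min_cov]
            pct = 100.0 * d["n_meth"] / d["coverage"]
            frames.append(pd.DataFrame({"chrom": d["chrom"], "pos0": d["pos0"], "pct": pct}))
        allf = pd.concat(frames, ignore_index=True)
        return allf.groupby(["chrom", "pos0"])["pct"].mean()

    ma = group_mean(calls_a, ("chrom", "pos0"))
    mb = group_mean(calls_b, ("chrom", "pos0"))

    sm = shared_map.copy()
    ka = pd.MultiIndex.from_frame(sm[["chrom", "pos0"]])
    kb = pd.MultiIndex.from_frame(
        sm[["counterpart_chrom", "counterpart_pos0"]].rename(
            columns={"counterpart_chrom": "chrom", "counterpart_pos0": "pos0"}
        )
    )
    sm["pct_a"] = ma.reindex(ka).to_numpy()
    sm["pct_b"] = mb.reindex(kb).to_numpy()
    sm = sm.dropna(subset=["pct_a", "pct_b"])

    if windows is None:
        rows = []
        for chrom, L in chrom_lengths.items():
            for start in range(0, L, win):
                rows.append((chrom, start, min(L, start + win)))
        windows = pd.DataFrame(rows, columns=["chrom_a", "start_a", "end_a"])

    out_rows = []
    n_skipped = 0
    for w in windows.itertuples(index=False):
        inw = sm[(sm["chrom"] == w.chrom_a) & (sm["pos0"] >= w.start_a) & (sm["pos0"] < w.end_a)]
        if inw.shape[0] < min_pairs:
            n_skipped += 1
            continue
        diffs = (inw["pct_a"] - inw["pct_b"]).to_numpy()
        if np.allclose(diffs, 0.0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided")[1])
        out_rows.append((w.chrom_a, w.start_a, w.end_a, int(inw.shape[0]), float(diffs.mean()), p))
    if not out_rows and n_skipped == 0:
        raise ValueError("no homologous window contains paired CpGs")
    df = pd.DataFrame(out_rows, columns=["chrom", "start", "end", "n_paired_cpgs", "mean_diff", "p"])
    if not df.empty:
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = pd.Series(dtype=float)
    return WindowBiasResult(df, int(df.shape[0]), n_skipped)


# ---------------------------------------------------------------- breed-specific shift


@dataclass
class ShiftReport:
    median_breed_specific: float
    median_background: float
    direction: str  # 'lower' | 'higher' | 'none'
    p: float
    n_breed_specific: int
    n_background: int


def breed_specific_meth_shift(calls: MethylationCallSet, classification: pd.DataFrame,
                              min_cov: int = 10) -> ShiftReport:
    """Breed-specific-CpG methylation vs the shared-site background.

    A two-sample rank test (Mann-Whitney U) compares the distributions; the
    sets are unpaired and of different sizes, so a paired signed-rank test
    is not defined here.
    """
    d = calls.df[calls.df["coverage"] >= min_cov]
    keys = pd.MultiIndex.from_frame(d[["chrom", "pos0"]])
    bs_sites = classification[classification["cls"].isin(["breed_specific", "snp_affected"])]
    sh_sites = classification[classification["cls"] == "shared"]
    if bs_sites.empty:
        raise ValueError("breed-specific site set is empty")
    bs_key = pd.MultiIndex.from_frame(bs_sites[["chrom", "pos0"]])
    sh_key = pd.MultiIndex.from_frame(sh_sites[["chrom", "pos0"]])
    pct = 100.0 * d["n_meth"].to_numpy() / d["coverage"].to_numpy()
    bs = pct[keys.isin(bs_key)]
    bg = pct[keys.isin(sh_key)]
    if bg.size == 0:
        raise ValueError("background (shared-site) set is empty")
    if bs.size == 0:
        raise ValueError("no breed-specific site has sufficient coverage")
    u, p = sps.mannwhitneyu(bs, bg, alternative="two-sided")
    med_bs, med_bg = float(np.median(bs)), float(np.median(bg))
    direction = "none"
    if p < 0.05:
        direction = "lower" if med_bs < med_bg else "higher"
    return ShiftReport(med_bs, med_bg, direction, float(p), int(bs.size), int(bg.size))
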