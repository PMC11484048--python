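"""SNP/SV calling between assemblies and CpG enrichment statistics.

Variants can come from three places: the built-in chunked aligner
(:func:`align_genomes`, anchors + banded DP, good for simulated assemblies),
minimap2 PAF records carrying cs tags, or a VCF. Substitutions become SNP
records; indels of at least 50 bp become SV records; 1-49 bp indels are
recorded but excluded from both the SNP and SV statistics (standard SV size
convention).

Statistics reproduce the dual-assembly comparison design: a per-chromosome
2x2 chi-square for SNPs hitting CpG bases (BH-corrected across chromosomes),
the substitution spectrum at CpG sites (deamination fraction = C>T + G>A),
and a Mann-Whitney U test on per-chromosome CpG densities inside vs outside
SV material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .align import GenomeIndex, encode, kmer_codes, parse_cigar
from .cpg_catalog import cpg_positions

SV_MIN_LEN = 50


@dataclass
class VariantCalls:
    snps: list[tuple[str, int, str, str]] = field(default_factory=list)
    svs: list[tuple[str, int, int, str, int, str]] = field(default_factory=list)
    small_indels: list[tuple[str, int, int, str, int, str]] = field(default_factory=list)


# ---------------------------------------------------------------- built-in genome aligner


def _chain_blocks(qpos: np.ndarray, tpos: np.ndarray, k: int,
                  diag_tol: int = 30, min_anchors: int = 5):
    """Greedy chaining of exact-match anchors into colinear blocks.

    A block is a maximal run of q-sorted anchors whose diagonal (t - q)
    stays within diag_tol; runs with fewer than min_anchors anchors are
    dropped as noise. Returns (q0, q1, t0, t1) per block with the k-mer
    length folded into the right ends, filtered to be monotone in t.
    """
    order = np.argsort(qpos, kind="stable")
    qp, tp = qpos[order], tpos[order]
    blocks = []
    i = 0
    n = qp.size
    while i < n:
        j = i + 1
        d = tp[i] - qp[i]
        while j < n and abs((tp[j] - qp[j]) - d) <= diag_tol and tp[j] > tp[j - 1]:
            j += 1
        if j - i >= min_anchors:
            blocks.append((int(qp[i]), int(qp[j - 1]) + k, int(tp[i]), int(tp[j - 1]) + k))
        i = j
    # enforce monotone, non-overlapping progression on both axes
    out = []
    for b in blocks:
        if out and (b[0] < out[-1][1] or b[2] < out[-1][3]):
            if (b[1] - b[0]) > (out[-1][1] - out[-1][0]):
                out[-1] = b
            continue
        out.append(b)
    return out


_JUNCTION_ALIGNER = None


def _junction_aligner():
    """Affine-gap global aligner used to place SV breakpoints.

    Unit-cost DP (edlib) fragments long gaps across chance matches; an
    affine gap penalty consolidates them the way asm-to-asm aligners do.
    """
    global _JUNCTION_ALIGNER
    if _JUNCTION_ALIGNER is None:
        from Bio import Align

        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 2
        a.mismatch_score = -4
        a.open_gap_score = -24
        a.extend_gap_score = -1
        _JUNCTION_ALIGNER = a
    return _JUNCTION_ALIGNER


def _affine_ops(qseq: str, tseq: str):
    """Extended-cigar ops of an affine global alignment (query vs target)."""
    aln = _junction_aligner().align(tseq, qseq)[0]
    t_blocks, q_blocks = aln.aligned
    ops = []
    q = t = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if qs > q:
            ops.append((qs - q, "I"))
        if ts > t:
            ops.append((ts - t, "D"))
        for a, b in zip(qseq[qs:qe], tseq[ts:te]):
            ops.append((1, "=" if a == b else "X"))
        q, t = qe, te
    if len(qseq) > q:
        ops.append((len(qseq) - q, "I"))
    if len(tseq) > t:
        ops.append((len(tseq) - t, "D"))
    merged = []
    for n, op in ops:
        if merged and merged[-1][1] == op:
            merged[-1][0] += n
        else:
            merged.append([n, op])
    return [(n, op) for n, op in merged]


def align_genomes(reference: dict[str, str], query: dict[str, str],
                  k: int = 21, stride: int = 8, query_stride: int = 3,
                  min_anchors: int = 5, diag_tol: int = 30,
                  block_chunk: int = 50_000, junction_margin: int = 60,
                  max_junction: int = 20_000):
    """Anchor-chained whole-genome alignment of query onto reference.

    Exact k-mer anchors are chained into colinear blocks per chromosome;
    within a block the sequences are aligned with banded bit-parallel DP
    (edlib, in <=block_chunk slices), and block junctions — where indels and
    SVs live — are re-aligned with an affine-gap aligner so gaps come out
    consolidated. Yields (query_chrom, q_start, ref_chrom, ref_start, ops)
    with extended-cigar ops and absolute coordinates. Junctions larger than
    max_junction on both sides are emitted as coarse D+I ops.
    """
    index = GenomeIndex.build(reference, k, stride)
    out = []
    for qchrom, qseq in query.items():
        codes = kmer_codes(encode(qseq), k)
        s_idx = np.arange(0, codes.size, query_stride)
        tpos, tci, _amb = index.match(codes[s_idx])
        hit = tpos >= 0
        if int(hit.sum()) < min_anchors:
            continue
        # dominant target chromosome (assemblies are chromosome-paired here)
        cis, counts = np.unique(tci[hit], return_counts=True)
        ci = int(cis[np.argmax(counts)])
        rchrom = index.chroms[ci]
        rseq = reference[rchrom]
        sel = hit & (tci == ci)
        blocks = _chain_blocks(s_idx[sel], tpos[sel], k, diag_tol, min_anchors)
        prev = None
        for q0, q1, t0, t1 in blocks:
            if prev is not None:
                pq, pt = prev
                gq, gt = q0 - pq, t0 - pt
                m = junction_margin
                jq0, jt0 = pq - m, pt - m
                if gq <= max_junction and gt <= max_junction:
                    ops = _affine_ops(qseq[jq0 : q0 + m], rseq[jt0 : t0 + m])
                    out.append((qchrom, jq0, rchrom, jt0, ops))
                else:
                    coarse = []
                    if gt:
                        coarse.append((gt, "D"))
                    if gq:
                        coarse.append((gq, "I"))
                    out.append((qchrom, pq, rchrom, pt, coarse))
            # colinear interior, in bounded slices
            pos_q, pos_t = q0, t0
            span_q, span_t = q1 - q0, t1 - t0
            n_slices = max(1, -(-max(span_q, span_t) // block_chunk))
            for s in range(n_slices):
                qa = q0 + span_q * s // n_slices
                qb = q0 + span_q * (s + 1) // n_slices
                ta = t0 + span_t * s // n_slices
                tb = t0 + span_t * (s + 1) // n_slices
                if qb <= qa or tb <= ta:
                    continue
                res = edlib.align(qseq[qa:qb], rseq[ta:tb], mode="NW", task="path")
                if res["editDistance"] < 0:
                    continue
                out.append((qchrom, qa, rchrom, ta, parse_cigar(res["cigar"])))
            prev = (q1, t1)
    return out


def _normalize_ops(ops, qseq, rseq, q_start, r_start, max_shift=10):
    """Rewrite balanced indel pairs as substitution runs.

    Unit-cost DP can represent two nearby substitutions as an equal-cost
    deletion/insertion pair separated by coincidentally matching bases
    (e.g. ``1D 3= 1I``). Whenever an I and a D of equal length are separated
    by at most ``max_shift`` matching columns, the stretch is re-expressed
    by direct base comparison, which recovers the substitutions an
    affine-scoring aligner would report.
    """
    out = []
    q, r = q_start, r_start
    i = 0
    while i < len(ops):
        n, op = ops[i]
        pat = None
        if op in ("I", "D") and n <= max_shift:
            j = i + 1
            gap = 0
            if j < len(ops) and ops[j][1] == "=" and ops[j][0] <= max_shift:
                gap = ops[j][0]
                j += 1
            if j < len(ops) and ops[j][1] == ("D" if op == "I" else "I") and ops[j][0] == n:
                pat = (n, gap, j)
        if pat is not None:
            n, gap, j = pat
            span = n + gap
            for t in range(span):
                out.append((1, "=" if qseq[q + t] == rseq[r + t] else "X"))
            q += span
            r += span
            i = j + 1
            continue
        if op in ("=", "X", "M"):
            q += n
            r += n
        elif op == "I":
            q += n
        elif op == "D":
            r += n
        out.append((n, op))
        i += 1
    # merge runs of identical ops
    merged = []
    for n, op in out:
        if merged and merged[-1][1] == op:
            merged[-1][0] += n
        else:
            merged.append([n, op])
    return [(n, op) for n, op in merged]


def variants_from_ops(alignments, reference: dict[str, str], query: dict[str, str]) -> VariantCalls:
    """Walk alignment ops and emit SNP / SV / small-indel records.

    Coordinates are on the reference. Duplicate SNPs from overlapping chunk
    windows are deduplicated by position.
    """
    calls = VariantCalls()
    seen = set()
    for qchrom, q_start, rchrom, r_start, ops in alignments:
        ops = _normalize_ops(ops, query[qchrom], reference[rchrom], q_start, r_start)
        q = q_start
        r = r_start
        qseq = query[qchrom]
        rseq = reference[rchrom]
        for n, op in ops:
            if op in ("=", "M"):
                q += n
                r += n
            elif op == "X":
                for j in range(n):
                    key = (rchrom, r + j)
                    if key not in seen:
                        seen.add(key)
                        calls.snps.append((rchrom, r + j, rseq[r + j], qseq[q + j]))
                q += n
                r += n
            elif op == "I":  # present in query, absent from reference: insertion
                rec = (rchrom, r, r, "ins", n, qseq[q : q + n])
                (calls.svs if n >= SV_MIN_LEN else calls.small_indels).append(rec)
                q += n
            elif op == "D":  # absent from query: deletion of reference material
                rec = (rchrom, r, r + n, "del", n, rseq[r : r + n])
                (calls.svs if n >= SV_MIN_LEN else calls.small_indels).append(rec)
                r += n
    calls.snps.sort(key=lambda s: (s[0], s[1]))
    calls.svs.sort(key=lambda s: (s[0], s[1]))
    return calls


def call_variants(reference: dict[str, str], query: dict[str, str] | None = None,
                  paf_records=None, vcf_path=None, alignments=None) -> VariantCalls:
    """Call SNPs and SVs between two assemblies.

    Exactly one source is used, in order of precedence: pre-computed
    ``alignments`` (from :func:`align_genomes`), ``paf_records`` with cs
    tags, a ``vcf_path``, or — when only genomes are given — the built-in
    aligner run on the spot.
    """
    if alignments is not None:
        return variants_from_ops(alignments, reference, query)
    if paf_records is not None:
        return _variants_from_paf(reference, paf_records)
    if vcf_path is not None:
        from .io import read_snp_vcf

        calls = VariantCalls()
        calls.snps = read_snp_vcf(vcf_path)
        return calls
    if query is None:
        raise ValueError("need a query genome, alignments, PAF records or a VCF")
    return variants_from_ops(align_genomes(reference, query), reference, query)


def _variants_from_paf(reference, paf_records):
    from .crossmap import _cs_to_ops

    calls = VariantCalls()
    seen = set()
    for rec in paf_records:
        if rec.cs is None:
            raise ValueError(f"PAF record {rec.query_name} lacks a cs tag")
        r = rec.target_start
        rseq = reference[rec.target_name]
        import re as _re

        for m in _re.finditer(r":(\d+)|\*([a-z])([a-z])|\+([a-z]+)|-([a-z]+)", rec.cs):
            if m.group(1):
                r += int(m.group(1))
            elif m.group(2):
                ref_b, alt_b = m.group(2).upper(), m.group(3).upper()
                if rseq[r].upper() != ref_b:
                    raise ValueError(
                        f"cs string inconsistent with reference at {rec.target_name}:{r} "
                        f"(cs says {ref_b}, reference has {rseq[r].upper()})"
                    )
                if (rec.target_name, r) not in seen:
                    seen.add((rec.target_name, r))
                    calls.snps.append((rec.target_name, r, ref_b, alt_b))
                r += 1
            elif m.group(4):
                seq = m.group(4).upper()
                n = len(seq)
                recd = (rec.target_name, r, r, "ins", n, seq)
                (calls.svs if n >= SV_MIN_LEN else calls.small_indels).append(recd)
            elif m.group(5):
                seq = m.group(5).upper()
                n = len(seq)
                recd = (rec.target_name, r, r + n, "del", n, seq)
                (calls.svs if n >= SV_MIN_LEN else calls.small_indels).append(recd)
                r += n
    calls.snps.sort(key=lambda s: (s[0], s[1]))
    calls.svs.sort(key=lambda s: (s[0], s[1]))
    return calls


# ---------------------------------------------------------------- enrichment statistics


@dataclass
class EnrichmentResult:
    per_chrom: pd.DataFrame  # chrom, cpg_snp, noncpg_snp, cpg_unaffected, noncpg_unaffected, chi2, p, p_adj, fold
    pooled_chi2: float
    pooled_p: float
    pooled_fold: float
    site_level_fold: float


def _cpg_base_masks(genome: dict[str, str]):
    masks = {}
    for chrom, seq in genome.items():
        pos = cpg_positions(seq)
        mask = np.zeros(len(seq), dtype=bool)
        mask[pos] = True
        mask[pos + 1] = True
        masks[chrom] = mask
    return masks


def cpg_snp_enrichment(snps, genome: dict[str, str], yates: bool = False) -> EnrichmentResult:
    """Chi-square test of SNP x CpG-base independence, per chromosome.

    A SNP affects a CpG when its position falls on either base of a
    catalogued CG dinucleotide. Fold = (CpG-base SNP rate) / (non-CpG-base
    SNP rate); BH correction is applied across chromosomes.
    """
    masks = _cpg_base_masks(genome)
    rows = []
    for chrom, seq in genome.items():
        mask = masks[chrom]
        n_cpg = int(mask.sum())
        n_non = len(seq) - n_cpg
        pos = np.array([p for c, p, _, _ in snps if c == chrom], dtype=np.int64)
        on_cpg = int(mask[pos].sum()) if pos.size else 0
        off_cpg = int(pos.size) - on_cpg
        rows.append((chrom, on_cpg, off_cpg, n_cpg - on_cpg, n_non - off_cpg))
    df = pd.DataFrame(rows, columns=["chrom", "cpg_snp", "noncpg_snp", "cpg_unaffected", "noncpg_unaffected"])

    chi2s, ps, folds = [], [], []
    for r in df.itertuples(index=False):
        n_snp = r.cpg_snp + r.noncpg_snp
        cpg_bases = r.cpg_snp + r.cpg_unaffected
        non_bases = r.noncpg_snp + r.noncpg_unaffected
        fold = _fold(r.cpg_snp, cpg_bases, r.noncpg_snp, non_bases)
        folds.append(fold)
        if n_snp == 0:
            chi2s.append(np.nan)
            ps.append(np.nan)
            continue
        table = [[r.cpg_snp, r.noncpg_snp], [r.cpg_unaffected, r.noncpg_unaffected]]
        chi2, p, _, _ = sps.chi2_contingency(table, correction=yates)
        chi2s.append(chi2)
        ps.append(p)
    df["chi2"] = chi2s
    df["p"] = ps
    padj = np.full(len(ps), np.nan)
    ok = ~np.isnan(ps)
    if ok.any():
        padj[ok] = multipletests(np.asarray(ps)[ok], method="fdr_bh")[1]
    df["p_adj"] = padj
    df["fold"] = folds

    pooled = df[["cpg_snp", "noncpg_snp", "cpg_unaffected", "noncpg_unaffected"]].sum()
    pooled_fold = _fold(
        pooled["cpg_snp"], pooled["cpg_snp"] + pooled["cpg_unaffected"],
        pooled["noncpg_snp"], pooled["noncpg_snp"] + pooled["noncpg_unaffected"],
    )
    if pooled["cpg_snp"] + pooled["noncpg_snp"] > 0:
        chi2, p, _, _ = sps.chi2_contingency(
            [[pooled["cpg_snp"], pooled["noncpg_snp"]], [pooled["cpg_unaffected"], pooled["noncpg_unaffected"]]],
            correction=yates,
        )
    else:
        chi2, p = np.nan, np.nan

    # site-level companion: fraction of CpG dinucleotides hit vs same-rate per-site expectation
    n_sites = sum(cpg_positions(s).size for s in genome.values())
    hit_sites = _snp_hit_site_count(snps, genome)
    total_len = sum(len(s) for s in genome.values())
    n_cpg_bases = int(sum(m.sum() for m in masks.values()))
    n_snps = len(snps)
    site_rate = hit_sites / n_sites if n_sites else np.nan
    bg_rate = (n_snps - _snps_on_cpg(snps, masks)) / (total_len - n_cpg_bases) if total_len > n_cpg_bases else np.nan
    site_fold = site_rate / (2 * bg_rate) if bg_rate else np.inf  # per-site = two assayable bases
    return EnrichmentResult(df, float(chi2), float(p), float(pooled_fold), float(site_fold))


def _fold(cpg_snp, cpg_bases, non_snp, non_bases):
    if cpg_bases == 0 or non_bases == 0 or non_snp == 0:
        return 0.0 if cpg_snp == 0 else np.inf
    return (cpg_snp / cpg_bases) / (non_snp / non_bases)


def _snps_on_cpg(snps, masks):
    n = 0
    for c, p, _, _ in snps:
        if masks[c][p]:
            n += 1
    return n


def _snp_hit_site_count(snps, genome):
    hit = set()
    for chrom, seq in genome.items():
        pos = set(cpg_positions(seq).tolist())
        for c, p, _, _ in snps:
            if c != chrom:
                continue
            if p in pos:
                hit.add((c, p))
            elif (p - 1) in pos:
                hit.add((c, p - 1))
    return len(hit)


@dataclass
class SpectrumResult:
    counts: pd.Series  # substitution type ('C>T', ...) -> count at CpG bases
    deamination_fraction: float


def substitution_spectrum(snps, genome: dict[str, str]) -> SpectrumResult:
    """Substitution-type spectrum restricted to CpG-affecting SNPs."""
    masks = _cpg_base_masks(genome)
    types = []
    for c, p, ref, alt in snps:
        if masks[c][p]:
            types.append(f"{ref}>{alt}")
    if not types:
        raise ValueError("no CpG-affecting SNPs; spectrum undefined")
    counts = pd.Series(types).value_counts()
    deam = (counts.get("C>T", 0) + counts.get("G>A", 0)) / counts.sum()
    return SpectrumResult(counts, float(deam))


@dataclass
class SVEnrichmentResult:
    per_chrom: pd.DataFrame  # chrom, sv_cpg_prop, nonsv_cpg_prop
    u_stat: float
    p: float
    pooled_fold: float


def _count_cg(seq: str) -> int:
    return cpg_positions(seq).size


def sv_cpg_enrichment(svs, genome: dict[str, str]) -> SVEnrichmentResult:
    """CpG density inside SV material vs the non-SV remainder of the genome.

    SV material is the inserted sequence for insertions and the deleted
    reference sequence for deletions; the complement is the reference with
    deletion footprints removed. Per-chromosome density vectors feed a
    two-sided Mann-Whitney U test; the pooled fold is the ratio of pooled
    densities.
    """
    rows = []
    sv_cpg_total = sv_len_total = non_cpg_total = non_len_total = 0
    for chrom, seq in genome.items():
        ch_svs = [s for s in svs if s[0] == chrom]
        sv_cpg = sum(_count_cg(s[5]) for s in ch_svs)
        sv_len = sum(s[4] for s in ch_svs)
        # complement: reference minus deletion footprints
        dels = sorted((s[1], s[2]) for s in ch_svs if s[3] == "del")
        non_cpg = _count_cg(seq)
        non_len = len(seq)
        for s, e in dels:
            non_cpg -= _count_cg(seq[s:e])
            non_len -= e - s
        if sv_len > 0:
            rows.append((chrom, sv_cpg / sv_len, non_cpg / non_len))
            sv_cpg_total += sv_cpg
            sv_len_total += sv_len
        else:
            rows.append((chrom, np.nan, non_cpg / non_len))
        non_cpg_total += non_cpg
        non_len_total += non_len
    df = pd.DataFrame(rows, columns=["chrom", "sv_cpg_prop", "nonsv_cpg_prop"])
    sv_vec = df["sv_cpg_prop"].dropna().to_numpy()
    non_vec = df["nonsv_cpg_prop"].to_numpy()
    if sv_vec.size == 0:
        raise ValueError("no SV material on any chromosome")
    if np.array_equal(np.sort(sv_vec), np.sort(non_vec)) and np.all(sv_vec == non_vec):
        u, p = float(sv_vec.size * non_vec.size / 2), 1.0
    else:
        u, p = sps.mannwhitneyu(sv_vec, non_vec, alternative="two-sided")
    pooled_fold = (sv_cpg_total / sv_len_total) / (non_cpg_total / non_len_total)
    return SVEnrichmentResult(df, float(u), float(p), float(pooled_fold))
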