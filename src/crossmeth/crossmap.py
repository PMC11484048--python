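"""Cross-assembly CpG classification.

Each catalogued CpG of one assembly (the query) is carried by its 1,002-bp
flank onto the other assembly (the target): the flank is mapped (built-in
seed-and-extend mapper, or ingested minimap2 PAF records), alignments with
fewer than 900 aligned bases are discarded, the 102-bp windows around the
midpoints are locally aligned, and the site is classified:

* ``shared``        - the target dinucleotide under the site is CG and the
                      midpoint alignment is confident;
* ``snp_affected``  - exactly one of the two site bases differs, no gap
                      touches the site, alignment confident (single-base
                      change, typically C>T/G>A deamination);
* ``breed_specific``- the flank does not map at all (the region is absent
                      from the other assembly);
* ``unresolved``    - everything else: failed 900-bp filter, low-confidence
                      or gapped midpoint alignment, both bases changed,
                      multi-mapping flank.

In the summary accounting the breed-specific set is the union of unmapped
and SNP-affected sites, matching how single-base losses of a CpG are counted
as breed-specific in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import (
    GenomeIndex,
    MidpointAligner,
    best_diagonal_cluster,
    cigar_stats,
    encode,
    infix_align,
    kmer_codes,
    project_offset,
    revcomp,
)
from .cpg_catalog import FLANK, FLANK_LEN, cpg_positions

MID_HALF = 51  # midpoint window is 102 bp: query flank[450:552]
MID_OFF = 450


@dataclass
class CrossmapConfig:
    k: int = 21
    target_stride: int = 8
    query_stride: int = 3
    min_anchors: int = 4
    min_aligned: int = 900
    pad: int = 150
    midpoint_min_cols: int = 90
    midpoint_min_identity: float = 0.95
    chromosome_paired: bool = True
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5


@dataclass
class FlankAlignment:
    chrom: str
    pos0: int
    target_chrom: str
    target_start0: int
    target_end0: int
    aligned_bases: int
    identity: float
    orientation: str
    ops: list = field(default_factory=list)
    ops_t_start: int = 0  # absolute target coordinate where ops begin


@dataclass
class ClassificationSummary:
    counts: dict
    fractions: dict
    n_excluded_flanks: int
    per_chrom: pd.DataFrame

    @property
    def breed_specific_combined(self) -> int:
        """Unmapped plus SNP-affected: the full breed-specific accounting."""
        return self.counts.get("breed_specific", 0) + self.counts.get("snp_affected", 0)


# ---------------------------------------------------------------- public single-flank ops


def map_flank(flank, target_genome: dict[str, str], index: GenomeIndex | None = None,
              config: CrossmapConfig | None = None) -> FlankAlignment | None:
    """Map one flank onto the target; None when unmapped.

    Tries forward orientation first, then reverse-complement. Ambiguous
    (multi-mapping) flanks return an alignment flagged with orientation '?'.
    """
    config = config or CrossmapConfig()
    if index is None:
        index = GenomeIndex.build(target_genome, config.k, config.target_stride)
    best = None
    for orient, seq in (("+", flank.sequence), ("-", revcomp(flank.sequence))):
        codes = kmer_codes(encode(seq), config.k)[:: config.query_stride]
        qpos = np.arange(0, codes.size) * config.query_stride
        tpos, tci, amb = index.match(codes)
        hit = tpos >= 0
        if int(hit.sum()) < config.min_anchors:
            if int(amb.sum()) >= config.min_anchors and best is None:
                best = "ambiguous"
            continue
        cand = _best_chrom_cluster(qpos[hit], tpos[hit], tci[hit])
        if cand is None:
            continue
        ci, diag, support, runner, q_lo, q_hi = cand
        if support < config.min_anchors:
            continue
        if runner >= support:
            best = "ambiguous"
            continue
        if not (q_lo <= FLANK + 252 and q_hi + config.k >= FLANK - 250):
            continue  # anchor chain never reaches the midpoint region
        tchrom = index.chroms[ci]
        tseq = target_genome[tchrom]
        wstart = max(0, diag - config.pad)
        wend = min(len(tseq), diag + FLANK_LEN + config.pad)
        res = infix_align(seq, tseq[wstart:wend])
        if res is None:
            continue
        ops, t0, t1 = res
        aligned, m, x, qi, td = cigar_stats(ops)
        identity = m / (m + x) if (m + x) else 0.0
        cand_aln = FlankAlignment(
            flank.chrom, flank.pos0, tchrom, wstart + t0, wstart + t1,
            aligned, identity, orient, ops, wstart + t0,
        )
        if best is None or best == "ambiguous" or (
            (cand_aln.aligned_bases, cand_aln.identity, -cand_aln.target_start0)
            > (best.aligned_bases, best.identity, -best.target_start0)
        ):
            best = cand_aln
    if best == "ambiguous":
        aln = FlankAlignment(flank.chrom, flank.pos0, "", -1, -1, 0, 0.0, "?")
        return aln
    return best


def _best_chrom_cluster(qpos, tpos, tci):
    """Best anchor cluster across target chromosomes.

    Returns (chrom_idx, diag_flank_start, support, runner_up, q_lo, q_hi)
    where diag_flank_start is the estimated target coordinate of flank
    offset 0. runner_up includes the best cluster on any other chromosome.
    """
    best = None
    supports = []
    for ci in np.unique(tci):
        sel = tci == ci
        cl = best_diagonal_cluster(qpos[sel], tpos[sel])
        if cl is None:
            continue
        diag, support, runner, q_lo, q_hi = cl
        supports.append((support, int(ci), diag, runner, q_lo, q_hi))
    if not supports:
        return None
    supports.sort(reverse=True)
    support, ci, diag, runner, q_lo, q_hi = supports[0]
    if len(supports) > 1:
        runner = max(runner, supports[1][0])
    return ci, diag, support, runner, q_lo, q_hi


def filter_alignment(aln: FlankAlignment, config: CrossmapConfig | None = None) -> bool:
    """The >=900 aligned-bases filter, plus the same-chromosome restriction
    when the run is configured chromosome-paired."""
    config = config or CrossmapConfig()
    if aln.aligned_bases < config.min_aligned:
        return False
    if config.chromosome_paired and aln.target_chrom != aln.chrom:
        return False
    return True


def midpoint_align(flank, target_genome: dict[str, str], aln: FlankAlignment,
                   aligner: MidpointAligner | None = None,
                   config: CrossmapConfig | None = None):
    """Local alignment of the 102-bp midpoint windows.

    Returns the aligner's statistics dict augmented with the absolute target
    positions/bases under the site, or None when the projected center sits
    within 51 bp of a contig end (window not extractable).
    """
    config = config or CrossmapConfig()
    aligner = aligner or MidpointAligner(config.match, config.mismatch, config.gap_open, config.gap_extend)
    seq = flank.sequence if aln.orientation == "+" else revcomp(flank.sequence)
    center, _ = project_offset(aln.ops, FLANK, aln.ops_t_start)
    tseq = target_genome[aln.target_chrom]
    if center - 51 < 0 or center + 51 > len(tseq):
        return None
    twin = tseq[center - 51 : center + 51]
    qwin = seq[MID_OFF : MID_OFF + 2 * MID_HALF]
    stats = aligner.align(qwin, twin)
    t0, t1 = stats["site_t"]
    stats["site_t_abs"] = tuple(None if t is None else center - 51 + t for t in (t0, t1))
    stats["site_bases"] = "".join(
        "-" if t is None else twin[t] for t in (t0, t1)
    )
    return stats


def classify_site(mid_stats, config: CrossmapConfig | None = None):
    """Four-way call from midpoint statistics (None = unmapped flank).

    Returns (cls, counterpart_pos0 or None, snp_detail or None).
    """
    config = config or CrossmapConfig()
    if mid_stats is None:
        return "breed_specific", None, None
    if mid_stats == "filtered" or mid_stats == "ambiguous":
        return "unresolved", None, None
    confident = (
        mid_stats["aligned_cols"] >= config.midpoint_min_cols
        and mid_stats["identity"] >= config.midpoint_min_identity
        and mid_stats["site_clean"]
    )
    if not confident:
        return "unresolved", None, None
    bases = mid_stats["site_bases"].upper()
    if bases == "CG":
        return "shared", mid_stats["site_t_abs"][0], None
    n_diff = (bases[0] != "C") + (bases[1] != "G")
    if n_diff == 1 and "-" not in bases:
        return "snp_affected", None, f"CG>{bases}"
    return "unresolved", None, None


# ---------------------------------------------------------------- driver


def classify_direction(query_genome: dict[str, str], target_genome: dict[str, str],
                       config: CrossmapConfig | None = None,
                       paf_records=None) -> tuple[pd.DataFrame, ClassificationSummary]:
    """Classify every flank-retained CpG of the query against the target.

    The hot path avoids per-flank seeding: query k-mers are matched against
    the target index genome-wide, and flanks whose anchors sit on a single
    exact diagonal (no indel) are resolved by direct base comparison, which
    is exactly what the banded DP would produce for a gapless alignment.
    Flanks spanning indels, with ambiguous anchors, or on the minus strand
    take the full map_flank / midpoint_align route.
    """
    config = config or CrossmapConfig()
    if paf_records is not None:
        return _classify_direction_paf(query_genome, target_genome, paf_records, config)
    index = GenomeIndex.build(target_genome, config.k, config.target_stride)
    aligner = MidpointAligner(config.match, config.mismatch, config.gap_open, config.gap_extend)
    t_enc = {c: encode(s) for c, s in target_genome.items()}
    chrom_to_ci = {c: i for i, c in enumerate(index.chroms)}

    rows = []
    n_excluded = 0
    for chrom, seq in query_genome.items():
        L = len(seq)
        q_enc = encode(seq)
        codes = kmer_codes(q_enc, config.k)
        s_idx = np.arange(0, codes.size, config.query_stride)
        tpos, tci, amb = index.match(codes[s_idx])
        sites = cpg_positions(seq)
        for pos in sites:
            pos = int(pos)
            if pos < FLANK or pos + FLANK + 2 > L:
                n_excluded += 1
                continue
            fs = pos - FLANK
            i0 = -(-fs // config.query_stride)  # ceil
            i1 = (fs + FLANK_LEN - config.k) // config.query_stride
            sl = slice(i0, i1 + 1)
            t_sl, ci_sl, amb_sl = tpos[sl], tci[sl], amb[sl]
            q_sl = s_idx[sl]
            hit = t_sl >= 0
            n_hit = int(hit.sum())
            cls = cp = detail = None
            cp_chrom = None
            if n_hit < config.min_anchors:
                if int(amb_sl.sum()) >= config.min_anchors:
                    cls = "unresolved"  # repetitive flank: multi-mapping
                else:
                    slow = _slow_classify(seq, pos, chrom, target_genome, index, aligner, config)
                    cls, cp_chrom, cp, detail = slow
                rows.append((chrom, pos, cls, cp_chrom, cp, detail))
                continue
            cand = _best_chrom_cluster(q_sl[hit] - fs, t_sl[hit], ci_sl[hit])
            ci, diag, support, runner, q_lo, q_hi = cand
            tchrom = index.chroms[ci]
            if runner >= support:
                rows.append((chrom, pos, "unresolved", None, None, None))
                continue
            if not (q_lo <= FLANK + 252 and q_hi + config.k >= FLANK - 250):
                slow = _slow_classify(seq, pos, chrom, target_genome, index, aligner, config)
                rows.append((chrom, pos, *slow[:1], slow[1], slow[2], slow[3]))
                continue
            if config.chromosome_paired and tchrom != chrom:
                rows.append((chrom, pos, "unresolved", None, None, None))
                continue
            # gapless fast path: one exact diagonal covering the flank
            on_best = hit & (ci_sl == ci)
            diags = t_sl[on_best] - (q_sl[on_best] - fs)
            if diags.min() == diags.max():
                tstart = int(diags[0])
                te = t_enc[tchrom]
                if tstart < 0 or tstart + FLANK_LEN > te.size:
                    rows.append((chrom, pos, "unresolved", None, None, None))
                    continue
                qf = q_enc[fs : fs + FLANK_LEN]
                tf = te[tstart : tstart + FLANK_LEN]
                mm_win = int(np.count_nonzero(qf[MID_OFF : MID_OFF + 102] != tf[MID_OFF : MID_OFF + 102]))
                identity_win = (102 - mm_win) / 102
                if identity_win < config.midpoint_min_identity:
                    rows.append((chrom, pos, "unresolved", None, None, None))
                    continue
                b0 = target_genome[tchrom][tstart + FLANK]
                b1 = target_genome[tchrom][tstart + FLANK + 1]
                bases = (b0 + b1).upper()
                if bases == "CG":
                    rows.append((chrom, pos, "shared", tchrom, tstart + FLANK, None))
                elif (bases[0] != "C") + (bases[1] != "G") == 1:
                    rows.append((chrom, pos, "snp_affected", None, None, f"CG>{bases}"))
                else:
                    rows.append((chrom, pos, "unresolved", None, None, None))
                continue
            slow = _slow_classify(seq, pos, chrom, target_genome, index, aligner, config)
            rows.append((chrom, pos, *slow[:1], slow[1], slow[2], slow[3]))

    df = pd.DataFrame(rows, columns=["chrom", "pos0", "cls", "counterpart_chrom", "counterpart_pos0", "snp_detail"])
    summary = summarize(df, n_excluded)
    return df, summary


def _slow_classify(seq, pos, chrom, target_genome, index, aligner, config):
    """Full map -> filter -> midpoint -> classify route for one site."""
    from .cpg_catalog import FlankRecord

    flank = FlankRecord(chrom, pos, seq[pos - FLANK : pos + FLANK + 2].upper())
    aln = map_flank(flank, target_genome, index, config)
    if aln is None:
        return "breed_specific", None, None, None
    if aln.orientation == "?":
        return "unresolved", None, None, None
    if not filter_alignment(aln, config):
        return "unresolved", None, None, None
    mid = midpoint_align(flank, target_genome, aln, aligner, config)
    if mid is None:
        return "unresolved", None, None, None
    cls, cp, detail = classify_site(mid, config)
    return cls, (aln.target_chrom if cp is not None else None), cp, detail


def summarize(df: pd.DataFrame, n_excluded: int = 0) -> ClassificationSummary:
    counts = df["cls"].value_counts().to_dict()
    total = int(df.shape[0])
    fractions = {k: v / total for k, v in counts.items()} if total else {}
    per_chrom = df.groupby(["chrom", "cls"]).size().unstack(fill_value=0) if total else pd.DataFrame()
    return ClassificationSummary(counts, fractions, n_excluded, per_chrom)


def classify_genome_pair(genome_a: dict[str, str], genome_b: dict[str, str],
                         config: CrossmapConfig | None = None,
                         paf_ab=None, paf_ba=None):
    """Run the full classification in both directions (A->B and B->A)."""
    a_to_b = classify_direction(genome_a, genome_b, config, paf_records=paf_ab)
    b_to_a = classify_direction(genome_b, genome_a, config, paf_records=paf_ba)
    return {"a_to_b": a_to_b, "b_to_a": b_to_a}


def shared_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Position pairs of shared sites: (chrom, pos0) -> (counterpart_chrom, counterpart_pos0)."""
    sh = df[df["cls"] == "shared"].copy()
    sh["counterpart_pos0"] = sh["counterpart_pos0"].astype(np.int64)
    return sh[["chrom", "pos0", "counterpart_chrom", "counterpart_pos0"]].reset_index(drop=True)


# ---------------------------------------------------------------- PAF ingestion


def _cs_to_ops(cs: str):
    """Convert a minimap2 cs tag (short form) to extended-cigar ops."""
    import re as _re

    ops = []
    for m in _re.finditer(r":(\d+)|\*([a-z])([a-z])|\+([a-z]+)|-([a-z]+)", cs):
        if m.group(1):
            ops.append((int(m.group(1)), "="))
        elif m.group(2):
            ops.append((1, "X"))
        elif m.group(4):
            ops.append((len(m.group(4)), "I"))
        elif m.group(5):
            ops.append((len(m.group(5)), "D"))
    return ops


def _classify_direction_paf(query_genome, target_genome, paf_records, config):
    """Classification driven by externally produced PAF records.

    Records are keyed by flank id 'chrom:pos0'. The best record per flank
    (by matches, then identity, then target position for a deterministic
    tie-break) supplies the alignment; midpoint windows are aligned locally
    as in the built-in route.
    """
    by_id: dict[str, list] = {}
    for rec in paf_records:
        by_id.setdefault(rec.query_name, []).append(rec)
    for qid in by_id:
        chrom = qid.rsplit(":", 1)[0]
        if chrom not in query_genome:
            raise ValueError(f"PAF record references unknown flank id {qid}")
    aligner = MidpointAligner(config.match, config.mismatch, config.gap_open, config.gap_extend)
    rows = []
    n_excluded = 0
    for chrom, seq in query_genome.items():
        L = len(seq)
        for pos in cpg_positions(seq):
            pos = int(pos)
            if pos < FLANK or pos + FLANK + 2 > L:
                n_excluded += 1
                continue
            recs = by_id.get(f"{chrom}:{pos}")
            if not recs:
                rows.append((chrom, pos, "breed_specific", None, None, None))
                continue
            recs = sorted(
                recs,
                key=lambda r: (-r.matches, -(r.matches / max(1, r.aln_len)), r.target_name, r.target_start),
            )
            rec = recs[0]
            if len(recs) > 1 and recs[1].matches == rec.matches:
                rows.append((chrom, pos, "unresolved", None, None, None))
                continue
            if rec.cs is not None:
                ops = _cs_to_ops(rec.cs)
            else:
                flank_seq = seq[pos - FLANK : pos + FLANK + 2].upper()
                q = flank_seq if rec.strand == "+" else revcomp(flank_seq)
                res = infix_align(
                    q[rec.query_start : rec.query_end],
                    target_genome[rec.target_name][rec.target_start : rec.target_end],
                )
                if res is None:
                    rows.append((chrom, pos, "unresolved", None, None, None))
                    continue
                ops = res[0]
            aligned, m, x, qi, td = cigar_stats(ops)
            # unaligned flank ends (soft-clips) do not count as aligned bases
            aln = FlankAlignment(
                chrom, pos, rec.target_name, rec.target_start, rec.target_end,
                min(aligned, rec.query_end - rec.query_start),
                m / (m + x) if m + x else 0.0,
                rec.strand, ops, rec.target_start,
            )
            if not filter_alignment(aln, config):
                rows.append((chrom, pos, "unresolved", None, None, None))
                continue
            flank_seq = seq[pos - FLANK : pos + FLANK + 2].upper()
            from .cpg_catalog import FlankRecord

            fr = FlankRecord(chrom, pos, flank_seq)
            mid = _midpoint_from_paf(fr, target_genome, aln, rec, aligner)
            if mid is None:
                rows.append((chrom, pos, "unresolved", None, None, None))
                continue
            cls, cp, detail = classify_site(mid, config)
            rows.append((chrom, pos, cls, rec.target_name if cp is not None else None, cp, detail))
    df = pd.DataFrame(rows, columns=["chrom", "pos0", "cls", "counterpart_chrom", "counterpart_pos0", "snp_detail"])
    return df, summarize(df, n_excluded)


def _midpoint_from_paf(flank, target_genome, aln: FlankAlignment, rec, aligner):
    seq = flank.sequence if rec.strand == "+" else revcomp(flank.sequence)
    # PAF query coordinates are on the original strand; cs/cigar ops run along
    # the target, i.e. along the reverse-complemented query for '-' records.
    # The CG midpoint of a flank sits at offset 500 in both orientations.
    if rec.strand == "+":
        q_in_aln = FLANK - rec.query_start
    else:
        q_in_aln = FLANK - (FLANK_LEN - rec.query_end)
    if q_in_aln < 0:
        return None
    center, _ = project_offset(aln.ops, q_in_aln, rec.target_start)
    tseq = target_genome[rec.target_name]
    if center - 51 < 0 or center + 51 > len(tseq):
        return None
    twin = tseq[center - 51 : center + 51]
    qwin = seq[MID_OFF : MID_OFF + 102]
    stats = aligner.align(qwin, twin)
    t0, t1 = stats["site_t"]
    stats["site_t_abs"] = tuple(None if t is None else center - 51 + t for t in (t0, t1))
    stats["site_bases"] = "".join("-" if t is None else twin[t] for t in (t0, t1))
    return stats
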