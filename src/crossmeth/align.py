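"""Built-in seed-and-extend alignment engine.

Exact k-mer anchors (2-bit rolling codes, sampled on the target) locate a
candidate homologous window; edlib's bit-parallel banded DP extends the
candidate and yields an extended cigar; a Smith-Waterman local aligner
(Bio.Align.PairwiseAligner) scores the short midpoint windows. This keeps
the pipeline free of external binaries while staying fast enough for
multi-megabase simulated assemblies; full-scale runs can instead ingest
minimap2 PAF records (see crossmap).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align

_ENC = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[ord(chr(b).lower())] = i

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3 (case-insensitive); anything else -> 4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(enc: np.ndarray, k: int = 21) -> np.ndarray:
    """2-bit rolling codes; windows containing a non-ACGT base get -1."""
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for j in range(k):
        codes += enc[j : j + n].astype(np.int64) << (2 * (k - 1 - j))
    bad = (enc >= 4).astype(np.int64)
    cb = np.concatenate([[0], np.cumsum(bad)])
    invalid = (cb[k:] - cb[:-k]) > 0
    codes[invalid] = -1
    return codes


@dataclass
class GenomeIndex:
    """Sampled unique-k-mer index over a genome (the alignment target).

    Queries are themselves usually sampled; the query stride must be coprime
    with ``stride``, otherwise anchors exist only on diagonals congruent to
    0 modulo their gcd and any indel shifts homology out of reach.
    """

    chroms: list[str]
    codes: np.ndarray       # sorted unique sampled codes
    pos: np.ndarray         # target position per code
    chrom_idx: np.ndarray   # chromosome index per code
    dup_codes: np.ndarray   # sorted codes seen more than once (repetitive)
    k: int
    stride: int

    @classmethod
    def build(cls, genome: dict[str, str], k: int = 21, stride: int = 8) -> "GenomeIndex":
        chroms = list(genome)
        all_codes, all_pos, all_ci = [], [], []
        for ci, chrom in enumerate(chroms):
            codes = kmer_codes(encode(genome[chrom]), k)
            sel = np.arange(0, codes.size, stride)
            c = codes[sel]
            ok = c >= 0
            all_codes.append(c[ok])
            all_pos.append(sel[ok])
            all_ci.append(np.full(int(ok.sum()), ci, dtype=np.int32))
        codes = np.concatenate(all_codes) if all_codes else np.empty(0, dtype=np.int64)
        pos = np.concatenate(all_pos) if all_pos else np.empty(0, dtype=np.int64)
        ci = np.concatenate(all_ci) if all_ci else np.empty(0, dtype=np.int32)
        order = np.argsort(codes, kind="stable")
        codes, pos, ci = codes[order], pos[order], ci[order]
        # drop repetitive codes but remember them for multi-map detection
        uniq_mask = np.ones(codes.size, dtype=bool)
        dup = np.zeros(codes.size, dtype=bool)
        same_as_prev = np.zeros(codes.size, dtype=bool)
        if codes.size > 1:
            same_as_prev[1:] = codes[1:] == codes[:-1]
        dup = same_as_prev.copy()
        dup[:-1] |= same_as_prev[1:]
        uniq_mask = ~dup
        dup_codes = np.unique(codes[dup])
        return cls(chroms, codes[uniq_mask], pos[uniq_mask], ci[uniq_mask], dup_codes, k, stride)

    def match(self, query_codes: np.ndarray):
        """Per query k-mer: matched target (chrom_idx, pos) or -1; plus a
        mask of query k-mers whose code is repetitive in the target."""
        tpos = np.full(query_codes.size, -1, dtype=np.int64)
        tci = np.full(query_codes.size, -1, dtype=np.int32)
        valid = query_codes >= 0
        i = np.searchsorted(self.codes, query_codes)
        inb = valid & (i < self.codes.size)
        hit = np.zeros(query_codes.size, dtype=bool)
        hit[inb] = self.codes[i[inb]] == query_codes[inb]
        tpos[hit] = self.pos[i[hit]]
        tci[hit] = self.chrom_idx[i[hit]]
        j = np.searchsorted(self.dup_codes, query_codes)
        amb = np.zeros(query_codes.size, dtype=bool)
        jn = valid & (j < self.dup_codes.size)
        amb[jn] = self.dup_codes[j[jn]] == query_codes[jn]
        return tpos, tci, amb


def best_diagonal_cluster(qpos: np.ndarray, tpos: np.ndarray, band: int = 48):
    """Largest co-diagonal anchor cluster.

    Returns (diag, support, runner_up_support, q_lo, q_hi) where diag is the
    median target-minus-query offset of the winning cluster and q_lo/q_hi the
    query span its anchors cover. runner_up_support counts the best cluster
    at least 1 kb away on the diagonal axis (multi-mapping evidence).
    """
    if qpos.size == 0:
        return None
    diag = np.sort(tpos - qpos)
    hi = np.searchsorted(diag, diag + band, side="right")
    counts = hi - np.arange(diag.size)
    best = int(np.argmax(counts))
    d_lo = diag[best]
    d_hi = diag[hi[best] - 1]
    d_est = int(np.median(diag[best : hi[best]]))
    far = (diag < d_lo - 1000) | (diag > d_hi + 1000)
    runner = 0
    if far.any():
        dfar = diag[far]
        hi2 = np.searchsorted(dfar, dfar + band, side="right")
        runner = int(np.max(hi2 - np.arange(dfar.size)))
    in_cluster = (tpos - qpos >= d_lo) & (tpos - qpos <= d_hi)
    q_in = qpos[in_cluster]
    return d_est, int(counts[best]), runner, int(q_in.min()), int(q_in.max())


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = _CIGAR_RE.findall(cigar)
    return [(int(n), op) for n, op in ops]


def cigar_stats(ops: list[tuple[int, str]]):
    """(aligned_bases, matches, mismatches, q_ins, t_del) of an extended cigar."""
    m = x = i = d = 0
    for n, op in ops:
        if op == "=":
            m += n
        elif op == "X":
            x += n
        elif op == "I":
            i += n
        elif op == "D":
            d += n
        elif op == "M":
            m += n  # unresolved match/mismatch; edlib task="path" emits =/X
    return m + x, m, x, i, d


def project_offset(ops: list[tuple[int, str]], q_off: int, t_start: int):
    """Target position aligned to query offset q_off (extended cigar walk).

    Returns (t_pos, exact): exact is False when q_off falls inside a
    query-only insertion, in which case t_pos is the next aligned target base.
    """
    q = 0
    t = t_start
    for n, op in ops:
        if op in ("=", "X", "M"):
            if q <= q_off < q + n:
                return t + (q_off - q), True
            q += n
            t += n
        elif op == "I":
            if q <= q_off < q + n:
                return t, False
            q += n
        elif op == "D":
            t += n
    return t, False


def infix_align(query: str, target_window: str):
    """edlib infix (HW) alignment of the full query inside a target window.

    Returns (ops, t_start, t_end) in window coordinates, or None when edlib
    fails to align (empty inputs).
    """
    if not query or not target_window:
        return None
    res = edlib.align(query, target_window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    ops = parse_cigar(res["cigar"])
    return ops, int(loc[0]), int(loc[1]) + 1


class MidpointAligner:
    """Smith-Waterman local alignment of the 102-bp midpoint windows.

    Scoring: match +1, mismatch -1, gap open -2, gap extend -0.5 (standard
    DNA local alignment; configurable).
    """

    def __init__(self, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-0.5):
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = match
        a.mismatch_score = mismatch
        a.open_gap_score = gap_open
        a.extend_gap_score = gap_extend
        self._aligner = a

    def align(self, query: str, target: str):
        """Best local alignment; returns a dict of column-level statistics.

        site_q_offsets 50/51 (the CG under the midpoint) are projected to
        target offsets; ``site_t`` holds None where the query base is
        unaligned (gap at the site).
        """
        alns = self._aligner.align(target, query)
        aln = alns[0]
        t_blocks, q_blocks = aln.aligned
        matches = 0
        aligned_cols = 0
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            aligned_cols += te - ts
            tq = np.frombuffer(target[ts:te].encode(), dtype=np.uint8)
            qq = np.frombuffer(query[qs:qe].encode(), dtype=np.uint8)
            matches += int((tq == qq).sum())
        gaps = 0
        for i in range(1, len(q_blocks)):
            gaps += (q_blocks[i][0] - q_blocks[i - 1][1]) + (t_blocks[i][0] - t_blocks[i - 1][1])

        def q_to_t(q_off: int):
            for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
                if qs <= q_off < qe:
                    return ts + (q_off - qs)
            return None

        site_t = (q_to_t(50), q_to_t(51))
        # gap within +/-2 bp of the site: offsets 48..53 must be aligned and colinear
        clean = True
        prev = None
        for q in range(48, 54):
            t = q_to_t(q)
            if t is None or (prev is not None and t != prev + 1):
                clean = False
                break
            prev = t
        return {
            "matches": matches,
            "mismatches": aligned_cols - matches,
            "gaps": gaps,
            "aligned_cols": aligned_cols,
            "identity": matches / aligned_cols if aligned_cols else 0.0,
            "score": aln.score,
            "site_t": site_t,
            "site_clean": clean,
        }


def smith_waterman_full(query: str, target: str, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-0.5) -> float:
    """Plain O(nm) affine-gap local alignment score (independent oracle)."""
    n, m = len(query), len(target)
    neg = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # first gap column scores gap_open, each further column gap_extend
            # (Bio.Align.PairwiseAligner convention)
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open)
            s = match if query[i - 1] == target[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best
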