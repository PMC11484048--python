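"""CpG enumeration and flank extraction.

A CpG site is recorded once per forward-strand CG dinucleotide (methylation
is symmetric, so the reverse-strand C is the same biological site). Flanks
are the fixed 1,002-bp windows used for cross-assembly mapping: 500 bp on
each side of the 2-bp dinucleotide, so sites within 500 bp of a chromosome
end carry no full flank and are excluded (and counted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FLANK = 500
FLANK_LEN = 2 * FLANK + 2  # 1,002 bp


def cpg_positions(seq: str) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide (case-insensitive)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)


def enumerate_cpgs(genome: dict[str, str], chromosomes=None) -> pd.DataFrame:
    """Catalog every CG dinucleotide; N-containing dinucleotides never match.

    ``chromosomes`` optionally restricts the catalog (e.g. autosomes only).
    Returns a frame with columns chrom, pos0 sorted by (chrom, pos0).
    """
    frames = []
    for chrom, seq in genome.items():
        if chromosomes is not None and chrom not in chromosomes:
            continue
        pos = cpg_positions(seq)
        frames.append(pd.DataFrame({"chrom": chrom, "pos0": pos}))
    if not frames:
        return pd.DataFrame({"chrom": pd.Series(dtype=str), "pos0": pd.Series(dtype=np.int64)})
    return pd.concat(frames, ignore_index=True)


@dataclass
class FlankRecord:
    chrom: str
    pos0: int
    sequence: str
    midpoint_offset: int = FLANK

    def __post_init__(self) -> None:
        if len(self.sequence) != FLANK_LEN:
            raise ValueError(f"flank length {len(self.sequence)} != {FLANK_LEN}")
        if self.sequence[FLANK : FLANK + 2].upper() != "CG":
            raise ValueError(f"no CG at flank midpoint for {self.chrom}:{self.pos0}")


def retained_mask(sites: pd.DataFrame, chrom_lengths: dict[str, int]) -> np.ndarray:
    """A site keeps its flank iff pos0 >= 500 and pos0 + 502 <= chrom length."""
    lens = sites["chrom"].map(chrom_lengths).to_numpy()
    pos = sites["pos0"].to_numpy()
    return (pos >= FLANK) & (pos + FLANK + 2 <= lens)


def extract_flanks(
    genome: dict[str, str], sites: pd.DataFrame
) -> tuple[list[FlankRecord], int]:
    """Extract 1,002-bp flanks; returns (records, n_excluded_near_edges)."""
    lengths = {c: len(s) for c, s in genome.items()}
    keep = retained_mask(sites, lengths)
    records = []
    for r in sites[keep].itertuples(index=False):
        seq = genome[r.chrom][r.pos0 - FLANK : r.pos0 + FLANK + 2].upper()
        if seq[FLANK : FLANK + 2] != "CG":
            raise ValueError(f"site {r.chrom}:{r.pos0} is not a CG dinucleotide")
        records.append(FlankRecord(r.chrom, int(r.pos0), seq))
    return records, int((~keep).sum())


def write_catalog_bed(sites: pd.DataFrame, path) -> None:
    out = sites.assign(end=sites["pos0"] + 2)[["chrom", "pos0", "end"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_flanks_fasta(records: list[FlankRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.chrom}:{rec.pos0}\n{rec.sequence}\n")
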