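"""Piecewise block map between two assemblies.

A :class:`CoordinateMap` is a list of gap-free blocks ``(src_chrom, src_start,
src_end, dst_chrom, dst_start, dst_end)`` with equal src/dst lengths, sorted
and non-overlapping on both sides. It plays the role a liftover chain plays
for real assembly pairs: in simulations it is the ground-truth map implied by
the planted variants; for real data it can be read from a chain-like TSV.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import pandas as pd

Block = tuple[str, int, int, str, int, int]


@dataclass
class CoordinateMap:
    blocks: list[Block] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in self.blocks:
            if b[2] - b[1] != b[5] - b[4]:
                raise ValueError(f"block src/dst lengths differ: {b}")
        self.blocks = sorted(self.blocks, key=lambda b: (b[0], b[1]))
        self._starts: dict[str, list[int]] = {}
        self._per_chrom: dict[str, list[Block]] = {}
        for b in self.blocks:
            self._per_chrom.setdefault(b[0], []).append(b)
        for chrom, bl in self._per_chrom.items():
            self._starts[chrom] = [b[1] for b in bl]

    def map_pos(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """Project a single source position; None if it falls in a gap."""
        bl = self._per_chrom.get(chrom)
        if not bl:
            return None
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i < 0:
            return None
        b = bl[i]
        if pos < b[2]:
            return b[3], b[4] + (pos - b[1])
        return None

    def map_interval(self, chrom: str, start: int, end: int):
        """Project an interval.

        Returns ``(mapped_bases, dst_chrom, dst_start, dst_end)`` where the
        dst interval is the span of all mapped bases, or
        ``(mapped, None, None, None)`` when nothing maps or the image spans
        more than one destination chromosome.
        """
        bl = self._per_chrom.get(chrom, [])
        mapped = 0
        dst_chrom = None
        lo = hi = None
        for b in bl:
            s = max(start, b[1])
            e = min(end, b[2])
            if s >= e:
                continue
            mapped += e - s
            ds = b[4] + (s - b[1])
            de = b[4] + (e - b[1])
            if dst_chrom is None:
                dst_chrom, lo, hi = b[3], ds, de
            elif b[3] != dst_chrom:
                return mapped, None, None, None
            else:
                lo, hi = min(lo, ds), max(hi, de)
        if dst_chrom is None:
            return 0, None, None, None
        return mapped, dst_chrom, lo, hi

    def invert(self) -> "CoordinateMap":
        return CoordinateMap([(b[3], b[4], b[5], b[0], b[1], b[2]) for b in self.blocks])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.blocks,
            columns=["src_chrom", "src_start", "src_end", "dst_chrom", "dst_start", "dst_end"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CoordinateMap":
        df = pd.read_csv(path, sep="\t")
        return cls([tuple(r) for r in df.itertuples(index=False)])

    @classmethod
    def identity(cls, chrom_lengths: dict[str, int]) -> "CoordinateMap":
        return cls([(c, 0, n, c, 0, n) for c, n in chrom_lengths.items()])
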