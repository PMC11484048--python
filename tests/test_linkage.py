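"""Liftover, direction-change detection, gene regions, DMR assignment."""

import numpy as np
import pandas as pd
import pytest

from crossmeth import linkage as lk
from crossmeth.coords import CoordinateMap


def _dmrs(rows):
    return pd.DataFrame(rows, columns=["chrom", "start0", "end0", "direction"])


IDENTITY = CoordinateMap.identity({"chr1": 1_000_000})


class TestLiftover:
    def test_identity_map_is_bit_exact(self):
        dmrs = _dmrs([("chr1", 1_000, 2_000, "hyper"), ("chr1", 5_000, 6_000, "hypo")])
        pairs, unmapped = lk.liftover_and_filter(dmrs, IDENTITY, dmrs)
        assert unmapped.empty
        assert pairs.shape[0] == 2
        assert (pairs["lift_start0"] == pairs["src_start0"]).all()
        assert (pairs["lift_end0"] == pairs["src_end0"]).all()

    def test_dmr_inside_deleted_segment_unmapped(self):
        cmap = CoordinateMap(
            [("chr1", 0, 10_000, "chr1", 0, 10_000),
             ("chr1", 15_000, 30_000, "chr1", 10_000, 25_000)]
        )
        dmrs = _dmrs([("chr1", 11_000, 12_000, "hyper")])
        pairs, unmapped = lk.liftover_and_filter(dmrs, cmap, _dmrs([]))
        assert pairs.empty
        assert unmapped.shape[0] == 1

    def test_partial_overlap_below_90pct_rejected(self):
        src = _dmrs([("chr1", 1_000, 2_000, "hyper")])
        tgt = _dmrs([("chr1", 1_150, 2_150, "hyper")])  # 85% reciprocal overlap
        pairs, _ = lk.liftover_and_filter(src, IDENTITY, tgt)
        assert pairs.empty

    def test_reciprocality(self):
        rng = np.random.default_rng(0)
        rows_a, rows_b = [], []
        for i in range(40):
            s = int(rng.integers(0, 900_000))
            L = int(rng.integers(500, 2_000))
            rows_a.append(("chr1", s, s + L, "hyper"))
            jitter = int(rng.integers(-200, 200))
            rows_b.append(("chr1", max(0, s + jitter), max(0, s + jitter) + L, "hypo"))
        a, b = _dmrs(rows_a), _dmrs(rows_b)
        ab, _ = lk.liftover_and_filter(a, IDENTITY, b)
        ba, _ = lk.liftover_and_filter(b, IDENTITY, a)
        fwd = {(r.src_idx, r.tgt_idx) for r in ab.itertuples(index=False)}
        rev = {(r.tgt_idx, r.src_idx) for r in ba.itertuples(index=False)}
        assert fwd == rev

    def test_map_missing_contig_not_fatal(self):
        dmrs = _dmrs([("chr9", 0, 1_000, "hyper")])
        pairs, unmapped = lk.liftover_and_filter(dmrs, IDENTITY, dmrs)
        assert pairs.empty
        assert unmapped.shape[0] == 1


class TestDirectionChanges:
    def _pairs(self, combos):
        rows = []
        for i, (d1, d2) in enumerate(combos):
            rows.append((i, "chr1", i * 1_000, i * 1_000 + 500, d1,
                         "chr1", i * 1_000, i * 1_000 + 500, i, i * 1_000, i * 1_000 + 500, d2))
        return pd.DataFrame(
            rows,
            columns=["src_idx", "src_chrom", "src_start0", "src_end0", "src_direction",
                     "lift_chrom", "lift_start0", "lift_end0",
                     "tgt_idx", "tgt_start0", "tgt_end0", "tgt_direction"],
        )

    def test_same_direction_not_flagged(self):
        assert lk.detect_direction_changes(self._pairs([("hyper", "hyper")])).empty

    def test_flip_flagged(self):
        out = lk.detect_direction_changes(self._pairs([("hypo", "hyper"), ("hypo", "hypo")]))
        assert out.shape[0] == 1

    def test_identity_end_to_end_zero_changes(self):
        dmrs = _dmrs([("chr1", 1_000, 2_000, "hyper"), ("chr1", 9_000, 9_800, "hypo")])
        pairs, _ = lk.liftover_and_filter(dmrs, IDENTITY, dmrs)
        assert lk.detect_direction_changes(pairs).empty


class TestGeneRegions:
    LENS = {"chr1": 5_000_000}

    def _one(self, start, end, strand):
        genes = pd.DataFrame(
            [("chr1", start, end, strand, "G1")],
            columns=["chrom", "start0", "end0", "strand", "gene_id"],
        )
        df = lk.build_gene_regions(genes, self.LENS)
        return {r.region_class: (r.start0, r.end0) for r in df.itertuples(index=False)}

    def test_plus_strand_arithmetic(self):
        r = self._one(1_000_000, 1_010_000, "+")
        assert r["upstream_enhancer"] == (870_000, 995_000)
        assert r["upstream_enhancer"][1] - r["upstream_enhancer"][0] == 125_000
        assert r["upstream_5kb"] == (995_000, 1_000_000)
        assert r["gene_body"] == (1_000_000, 1_010_000)
        assert r["downstream_5kb"] == (1_010_000, 1_015_000)
        assert r["downstream_enhancer"] == (1_015_000, 1_140_000)

    def test_minus_strand_mirrored(self):
        r = self._one(1_000_000, 1_010_000, "-")
        assert r["upstream_enhancer"] == (1_015_000, 1_140_000)
        assert r["upstream_5kb"] == (1_010_000, 1_015_000)
        assert r["downstream_5kb"] == (995_000, 1_000_000)
        assert r["downstream_enhancer"] == (870_000, 995_000)

    def test_contig_start_clipping(self):
        r = self._one(3_000, 10_000, "+")
        assert "upstream_enhancer" not in r  # [-127k, -2k) clips to nothing
        assert r["upstream_5kb"] == (0, 3_000)

    def test_contig_end_clipping(self):
        r = self._one(4_990_000, 4_998_000, "+")
        assert r["downstream_5kb"] == (4_998_000, 5_000_000)
        assert "downstream_enhancer" not in r

    def test_missing_strand_rejected(self):
        genes = pd.DataFrame(
            [("chr1", 0, 100, ".", "G1")],
            columns=["chrom", "start0", "end0", "strand", "gene_id"],
        )
        with pytest.raises(ValueError, match="strand"):
            lk.build_gene_regions(genes, self.LENS)


class TestAssignment:
    def _regions(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "region_class", "chrom", "start0", "end0"])

    def test_dmr_inside_region_assigned(self):
        regions = self._regions([("G1", "upstream_enhancer", "chr1", 10_000, 135_000)])
        dmrs = _dmrs([("chr1", 50_000, 51_000, "hyper")])
        s = lk.assign_dmrs(dmrs, regions)
        assert s.assignments.shape[0] == 1

    def test_half_overlap_not_assigned(self):
        regions = self._regions([("G1", "gene_body", "chr1", 0, 1_000_000)])
        dmrs = _dmrs([("chr1", 999_500, 1_000_500, "hyper")])  # 50% of the DMR
        s = lk.assign_dmrs(dmrs, regions)
        assert s.assignments.empty

    def test_small_region_covered_by_large_dmr_assigned(self):
        # -e OR semantics: 95% of the region counts even at 1% of the DMR
        regions = self._regions([("G1", "upstream_5kb", "chr1", 5_000, 5_100)])
        dmrs = _dmrs([("chr1", 0, 10_000, "hyper")])
        s = lk.assign_dmrs(dmrs, regions)
        assert s.assignments.shape[0] == 1

    def test_matches_bruteforce_interval_oracle(self):
        rng = np.random.default_rng(1)
        regions_rows, dmr_rows = [], []
        for i in range(60):
            s = int(rng.integers(0, 500_000))
            regions_rows.append((f"G{i}", "gene_body", "chr1", s, s + int(rng.integers(100, 20_000))))
        for _ in range(60):
            s = int(rng.integers(0, 500_000))
            dmr_rows.append(("chr1", s, s + int(rng.integers(100, 20_000)), "hyper"))
        regions = self._regions(regions_rows)
        dmrs = _dmrs(dmr_rows)
        s = lk.assign_dmrs(dmrs, regions)
        got = {(r.dmr_idx, r.gene_id) for r in s.assignments.itertuples(index=False)}
        want = set()
        for di, d in dmrs.iterrows():
            for _, r in regions.iterrows():
                ov = min(d.end0, r.end0) - max(d.start0, r.start0)
                if ov > 0 and (ov >= 0.9 * (d.end0 - d.start0) or ov >= 0.9 * (r.end0 - r.start0)):
                    want.add((di, r.gene_id))
        assert got == want

    def test_doubling_lengths_halves_densities(self):
        regions = self._regions([("G1", "gene_body", "chr1", 0, 10_000)])
        doubled = self._regions([("G1", "gene_body", "chr1", 0, 20_000)])
        dmrs = _dmrs([("chr1", 100, 600, "hyper")])
        d1 = lk.assign_dmrs(dmrs, regions).class_counts.set_index("region_class")
        d2 = lk.assign_dmrs(dmrs, doubled).class_counts.set_index("region_class")
        assert d2.loc["gene_body", "dmrs_per_mb"] == pytest.approx(
            d1.loc["gene_body", "dmrs_per_mb"] / 2
        )

    def test_deg_absent_from_annotation_warns(self):
        regions = self._regions([("G1", "gene_body", "chr1", 0, 10_000)])
        dmrs = _dmrs([("chr1", 100, 600, "hyper")])
        degs = pd.DataFrame({"gene_id": ["GX"], "direction": ["up"], "padj": [0.01]})
        s = lk.assign_dmrs(dmrs, regions, deg_table=degs)
        assert any("GX" in w for w in s.warnings)


class TestImprinted:
    def test_counts_and_deg_status(self):
        regions = pd.DataFrame(
            [("G1", "gene_body", "chr1", 0, 100_000)],
            columns=["gene_id", "region_class", "chrom", "start0", "end0"],
        )
        dmrs = _dmrs(
            [("chr1", 1_000, 2_000, "hypo"), ("chr1", 3_000, 4_000, "hypo"),
             ("chr1", 5_000, 6_000, "hypo"), ("chr1", 7_000, 8_000, "hyper"),
             ("chr1", 9_000, 10_000, "hyper")]
        )
        imp = pd.DataFrame({"gene_id": ["G1"], "symbol": ["DGAT1"]})
        degs = pd.DataFrame({"gene_id": ["G1"], "direction": ["up"], "padj": [0.01]})
        s = lk.assign_dmrs(dmrs, regions, deg_table=degs, imprinted=imp)
        row = s.imprinted.iloc[0]
        assert (row["n_hypo"], row["n_hyper"], row["deg_direction"]) == (3, 2, "up")

    def test_gene_without_dmrs_kept_with_zeros(self):
        regions = pd.DataFrame(
            [("MKRN3", "gene_body", "chr1", 500_000, 600_000)],
            columns=["gene_id", "region_class", "chrom", "start0", "end0"],
        )
        imp = pd.DataFrame({"gene_id": ["MKRN3"], "symbol": ["MKRN3"]})
        s = lk.assign_dmrs(_dmrs([("chr1", 0, 1_000, "hyper")]), regions, imprinted=imp)
        row = s.imprinted.iloc[0]
        assert (row["n_hypo"], row["n_hyper"], row["deg_direction"]) == (0, 0, "-")

    def test_gene_absent_from_annotation_warns(self):
        regions = pd.DataFrame(
            [("G1", "gene_body", "chr1", 0, 100)],
            columns=["gene_id", "region_class", "chrom", "start0", "end0"],
        )
        imp = pd.DataFrame({"gene_id": ["GZ"], "symbol": ["GZ"]})
        s = lk.assign_dmrs(_dmrs([]), regions, imprinted=imp)
        assert any("GZ" in w for w in s.warnings)
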