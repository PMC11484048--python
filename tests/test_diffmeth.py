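"""Differential methylation caller: uniting, tiling, logistic test, thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crossmeth import diffmeth as dm
from crossmeth.io import MethylationCallSet


def _sheet(n_per_group=6, groups=("BIBI", "BTBT")):
    rows = []
    for g in groups:
        for i in range(n_per_group):
            rows.append((f"{g}_{i + 1}", g, "M" if i % 2 == 0 else "F"))
    return pd.DataFrame(rows, columns=["sample_id", "group", "sex"])


def _callset(sample, rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "coverage", "n_meth"])
    return MethylationCallSet(sample, "A", df)


def _design(sheet):
    return dm.make_design(sheet, ("BIBI",), ("BTBT",))


class TestContrasts:
    def test_breed_contrast_brahman_reference(self):
        assert dm.contrast_groups("breed", "brahman") == (("BIBI",), ("BTBT",))

    def test_breed_contrast_angus_reference(self):
        assert dm.contrast_groups("breed", "angus") == (("BTBT",), ("BIBI",))

    def test_dam_of_origin_sides(self):
        ctrl, treat = dm.contrast_groups("dam", "brahman")
        assert set(ctrl) == {"BIBI", "BTBI"}
        assert set(treat) == {"BTBT", "BIBT"}

    def test_sire_of_origin_sides(self):
        ctrl, treat = dm.contrast_groups("sire", "brahman")
        assert set(ctrl) == {"BIBI", "BIBT"}
        assert set(treat) == {"BTBT", "BTBI"}

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError, match="contrast"):
            dm.contrast_groups("litter", "brahman")


class TestPrepareCounts:
    def test_destrand_merges_forward_and_reverse(self):
        sheet = _sheet(2)
        design = _design(sheet)
        callsets = [
            _callset(s, [("chr1", 100, "+", 10, 5), ("chr1", 101, "-", 10, 7)])
            for s in design.samples
        ]
        params = dm.DMRParams(min_per_group=2)
        united = dm.prepare_counts(callsets, sheet, design, params)
        assert united.units.shape[0] == 1
        assert united.units.loc[0, "start0"] == 100
        assert (united.coverage == 20).all()
        assert (united.n_meth == 12).all()

    def test_destrand_conserves_total_counts(self):
        rng = np.random.default_rng(0)
        sheet = _sheet(2)
        design = _design(sheet)
        callsets = []
        for s in design.samples:
            rows = []
            for i in range(30):
                cov_f, cov_r = rng.integers(10, 40, size=2)
                rows.append(("chr1", 50 * i, "+", cov_f, rng.integers(0, cov_f + 1)))
                rows.append(("chr1", 50 * i + 1, "-", cov_r, rng.integers(0, cov_r + 1)))
            callsets.append(_callset(s, rows))
        # disable the high-coverage cap so the merge itself is isolated
        params = dm.DMRParams(min_per_group=2, max_cov_percentile=100)
        united = dm.prepare_counts(callsets, sheet, design, params)
        # identical coverage medians across samples -> scale 1, counts conserved
        total_in = sum(cs.df["coverage"].sum() for cs in callsets)
        assert united.coverage.sum() == total_in

    def test_min_per_group_rule(self):
        sheet = _sheet(6)
        design = _design(sheet)
        callsets = []
        for j, s in enumerate(design.samples):
            rows = [("chr1", 100, "+", 20, 10)]
            # second unit: covered by only 4 of 6 BIBI samples
            group = sheet.set_index("sample_id").loc[s, "group"]
            if not (group == "BIBI" and j >= 4):
                rows.append(("chr1", 500, "+", 20, 10))
            callsets.append(_callset(s, rows))
        united = dm.prepare_counts(callsets, sheet, design, dm.DMRParams(min_per_group=5))
        assert united.units["start0"].tolist() == [100]

    def test_identity_normalization_keeps_counts(self):
        sheet = _sheet(2)
        design = _design(sheet)
        callsets = [_callset(s, [("chr1", 100, "+", 30, 15)]) for s in design.samples]
        united = dm.prepare_counts(callsets, sheet, design, dm.DMRParams(min_per_group=2))
        assert (united.coverage == 30).all()

    def test_low_coverage_sites_filtered(self):
        sheet = _sheet(2)
        design = _design(sheet)
        callsets = [
            _callset(s, [("chr1", 100, "+", 9, 5), ("chr1", 200, "+", 15, 5)])
            for s in design.samples
        ]
        params = dm.DMRParams(min_per_group=2, max_cov_percentile=100)
        united = dm.prepare_counts(callsets, sheet, design, params)
        assert united.units["start0"].tolist() == [200]

    def test_group_smaller_than_min_per_group_rejected(self):
        sheet = _sheet(3)
        design = _design(sheet)
        callsets = [_callset(s, [("chr1", 100, "+", 20, 10)]) for s in design.samples]
        with pytest.raises(ValueError, match="min_per_group"):
            dm.prepare_counts(callsets, sheet, design, dm.DMRParams(min_per_group=5))


class TestTileCounts:
    def _united(self, positions, sheet=None):
        sheet = sheet if sheet is not None else _sheet(2)
        design = _design(sheet)
        callsets = [
            _callset(s, [("chr1", p, "+", 20, 10) for p in positions])
            for s in design.samples
        ]
        params = dm.DMRParams(min_per_group=2)
        return dm.tile_counts(
            dm.prepare_counts(callsets, sheet, design, params), design, sheet, params
        ), design

    def test_sites_aggregate_into_half_open_windows(self):
        tiled, _ = self._united([100, 900])
        assert tiled.units.shape[0] == 1
        assert (tiled.units.loc[0, "start0"], tiled.units.loc[0, "end0"]) == (0, 1_000)
        assert (tiled.coverage == 40).all()

    def test_boundary_site_goes_to_next_window(self):
        tiled, _ = self._united([999, 1_000])
        assert tiled.units["start0"].tolist() == [0, 1_000]

    def test_empty_windows_absent(self):
        tiled, _ = self._united([100, 5_100])
        assert tiled.units["start0"].tolist() == [0, 5_000]


class TestLogisticDiffTest:
    def _united_from_counts(self, per_sample, design):
        """per_sample: list of (coverage, n_meth) aligned with design.samples."""
        cov = np.array([[c for c, _ in per_sample]])
        meth = np.array([[m for _, m in per_sample]])
        units = pd.DataFrame({"chrom": ["chr1"], "start0": [0], "end0": [1_000]})
        return dm.UnitedCounts(units, cov, meth, list(design.samples), level="window")

    def test_identical_groups_null_result(self):
        sheet = _sheet(3)
        design = _design(sheet)
        united = self._united_from_counts([(30, 12)] * 6, design)
        res = dm.logistic_diff_test(united, design)
        assert abs(res.loc[0, "beta1"]) < 1e-6
        assert res.loc[0, "p"] > 0.99
        assert res.loc[0, "meth_diff_pct"] == 0.0

    def test_complete_separation_uses_fisher_fallback(self):
        sheet = _sheet(2)
        design = _design(sheet)
        united = self._united_from_counts([(10, 0), (10, 0), (10, 10), (10, 10)], design)
        res = dm.logistic_diff_test(united, design)
        assert res.loc[0, "meth_diff_pct"] == 100.0
        assert res.loc[0, "p"] < 1e-6
        oracle = sps.fisher_exact([[20, 0], [0, 20]])[1]
        assert res.loc[0, "p"] == pytest.approx(oracle)

    def test_label_swap_antisymmetry_exact(self):
        rng = np.random.default_rng(3)
        sheet = _sheet(3)
        design = _design(sheet)
        swapped = dm.make_design(sheet, ("BTBT",), ("BIBI",))
        counts = [(int(c), int(m)) for c, m in
                  zip(rng.integers(15, 40, 6), rng.integers(2, 14, 6))]
        u1 = self._united_from_counts(counts, design)
        u2 = self._united_from_counts(counts, swapped)
        r1 = dm.logistic_diff_test(u1, design)
        r2 = dm.logistic_diff_test(u2, swapped)
        assert r1.loc[0, "meth_diff_pct"] == pytest.approx(-r2.loc[0, "meth_diff_pct"])
        assert r1.loc[0, "p"] == pytest.approx(r2.loc[0, "p"], rel=1e-9)

    def test_agrees_with_statsmodels_glm(self):
        """Independent oracle: per-unit fits must match statsmodels GLM
        (binomial) coefficients and the LR chi-square p-value."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        sheet = _sheet(3)
        design = _design(sheet)
        X = np.column_stack([np.ones(6), design.T, design.Sex])
        for _ in range(5):
            cov = rng.integers(12, 45, 6)
            meth = rng.binomial(cov, rng.uniform(0.2, 0.8))
            united = self._united_from_counts(list(zip(cov, meth)), design)
            res = dm.logistic_diff_test(united, design)
            endog = np.column_stack([meth, cov - meth])
            full = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, X[:, [0, 2]], family=sm.families.Binomial()).fit()
            lrt = 2 * (full.llf - null.llf)
            p_oracle = sps.chi2.sf(lrt, 1)
            assert res.loc[0, "beta1"] == pytest.approx(full.params[1], abs=1e-5)
            assert res.loc[0, "alpha_sex"] == pytest.approx(full.params[2], abs=1e-5)
            assert res.loc[0, "p"] == pytest.approx(p_oracle, rel=1e-5, abs=1e-12)

    def test_beta1_recovery_over_simulated_units(self):
        # balanced sexes, zero sex effect, known group log-odds difference
        rng = np.random.default_rng(5)
        sheet = _sheet(6)
        design = _design(sheet)
        true_b1 = np.log((0.6 / 0.4) / (0.4 / 0.6))  # logit(0.6) - logit(0.4)
        n_units = 200
        cov = rng.integers(25, 35, size=(n_units, 12))
        p = np.where(design.T == 1, 0.6, 0.4)
        meth = rng.binomial(cov, p)
        units = pd.DataFrame(
            {"chrom": "chr1", "start0": np.arange(n_units) * 1_000,
             "end0": np.arange(1, n_units + 1) * 1_000}
        )
        united = dm.UnitedCounts(units, cov, meth, list(design.samples), level="window")
        res = dm.logistic_diff_test(united, design)
        est = res["beta1"].mean()
        se = res["beta1"].std() / np.sqrt(n_units)
        assert abs(est - true_b1) < 3 * se


class TestCallDmrs:
    @pytest.mark.parametrize(
        "diff,q,kept",
        [(9.0, 0.001, False), (12.0, 0.005, True), (12.0, 0.02, False), (-15.0, 0.01, True)],
    )
    def test_thresholds(self, diff, q, kept):
        res = pd.DataFrame(
            {"chrom": ["chr1"], "start0": [0], "end0": [1_000],
             "meth_diff_pct": [diff], "p": [q / 2], "q": [q],
             "direction": ["hyper" if diff > 0 else "hypo"]}
        )
        out = dm.call_dmrs(res)
        assert (out.shape[0] == 1) is kept

    def test_direction_follows_sign(self):
        res = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start0": [0, 1_000], "end0": [1_000, 2_000],
             "meth_diff_pct": [15.0, -15.0], "p": [1e-5, 1e-5], "q": [1e-4, 1e-4],
             "direction": ["hyper", "hypo"]}
        )
        out = dm.call_dmrs(res)
        assert out["direction"].tolist() == ["hyper", "hypo"]

    def test_overlapping_tiling_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            dm.DMRParams(win_size=1_000, step=500)
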