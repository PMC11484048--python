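"""Reference-bias quantification: distribution tests, matched divergence,
homologous windows, breed-specific shift."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from crossmeth import bias
from crossmeth.io import MethylationCallSet


def _callset(rows, sample="s1", ref="A"):
    df = pd.DataFrame(rows, columns=["chrom", "pos0", "strand", "coverage", "n_meth"])
    return MethylationCallSet(sample, ref, df)


class TestMethylationVector:
    def test_percent_and_coverage_filter(self):
        cs = _callset([("chr1", 10, "+", 10, 5), ("chr1", 20, "+", 9, 9)])
        v = bias.methylation_vector(cs)
        assert v.tolist() == [50.0]

    def test_site_filter_drops_non_shared(self):
        cs = _callset([("chr1", 10, "+", 20, 10), ("chr1", 30, "+", 20, 20)])
        shared = pd.DataFrame({"chrom": ["chr1"], "pos0": [30]})
        v = bias.methylation_vector(cs, site_filter=shared)
        assert v.tolist() == [100.0]

    def test_empty_after_filter_raises(self):
        cs = _callset([("chr1", 10, "+", 5, 1)])
        with pytest.raises(ValueError, match="no sites"):
            bias.methylation_vector(cs)


class TestCompareReferenceBias:
    def test_identical_vectors(self):
        v = np.linspace(0, 100, 50)
        r = bias.compare_reference_bias(v, v.copy(), seed=1)
        assert (r.mean_abs_diff_pct, r.ks_stat, r.ks_p) == (0.0, 0.0, 1.0)

    def test_fully_separated_vectors(self):
        r = bias.compare_reference_bias(np.zeros(50), np.full(50, 100.0), seed=1)
        assert r.mean_abs_diff_pct == 100.0
        assert r.ks_stat == 1.0
        assert r.ks_p < 1e-6

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0, 100, 400), rng.uniform(0, 100, 300)
        assert bias.compare_reference_bias(a, b, seed=7) == bias.compare_reference_bias(a, b, seed=7)

    def test_missing_seed_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            bias.compare_reference_bias(np.ones(5), np.ones(5), seed=None)

    def test_swap_negates_signed_difference(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 100, 200), rng.uniform(10, 90, 200)
        r1 = bias.compare_reference_bias(a, b, seed=3)
        r2 = bias.compare_reference_bias(b, a, seed=3)
        assert r1.mean_diff_pct == pytest.approx(-r2.mean_diff_pct)
        assert r1.ks_stat == pytest.approx(r2.ks_stat)

    def test_bh_adjustment_monotone(self):
        rng = np.random.default_rng(2)
        results = [
            bias.compare_reference_bias(rng.uniform(0, 100, 100), rng.uniform(0, 100, 100), seed=i)
            for i in range(5)
        ]
        bias.adjust_bias_batch(results)
        for r in results:
            assert r.ks_p_adj >= r.ks_p - 1e-12


class TestMatchedDivergence:
    def _pair(self, vals):
        # vals: list of (pct_a, pct_b) at matched positions
        rows_a = [("chr1", 10 * i, "+", 100, int(pa)) for i, (pa, _) in enumerate(vals)]
        rows_b = [("chr1", 10 * i, "+", 100, int(pb)) for i, (_, pb) in enumerate(vals)]
        shared = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos0": [10 * i for i in range(len(vals))],
                "counterpart_chrom": "chr1",
                "counterpart_pos0": [10 * i for i in range(len(vals))],
            }
        )
        return _callset(rows_a), _callset(rows_b, ref="B"), shared

    def test_identical_values(self):
        a, b, sh = self._pair([(50, 50), (80, 80)])
        d = bias.matched_cpg_divergence(a, b, sh)
        assert (d.rmse, d.n_abs_diff_gt_10pct, d.n_abs_diff_gt_50pct) == (0.0, 0, 0)

    def test_threshold_counts(self):
        a, b, sh = self._pair([(50, 61)])
        d = bias.matched_cpg_divergence(a, b, sh)
        assert (d.n_abs_diff_gt_10pct, d.n_abs_diff_gt_50pct) == (1, 0)

    def test_rmse_arithmetic(self):
        a, b, sh = self._pair([(0, 10), (0, 0)])
        d = bias.matched_cpg_divergence(a, b, sh)
        assert d.rmse == pytest.approx(np.sqrt(0.10**2 / 2))

    def test_no_matched_sites_raises(self):
        a, b, sh = self._pair([(50, 50)])
        sh["counterpart_pos0"] = 999
        with pytest.raises(ValueError, match="no matched"):
            bias.matched_cpg_divergence(a, b, sh)


def _window_fixture(shift_window=None, n_windows=5, cpg_per_window=50, shift=20.0):
    """Identity-mapped genome with optional constant offset on reference B
    inside one window."""
    rng = np.random.default_rng(42)
    win = 1_000
    rows_a, rows_b, sh_rows = [], [], []
    for w in range(n_windows):
        for i in range(cpg_per_window):
            pos = w * win + 10 + i * 15
            pct = rng.uniform(20, 70)
            pa = pct
            pb = pct + (shift if shift_window == w else 0.0) + rng.normal(0, 0.5)
            pb = min(100.0, max(0.0, pb))
            rows_a.append(("chr1", pos, "+", 100, int(round(pa))))
            rows_b.append(("chr1", pos, "+", 100, int(round(pb))))
            sh_rows.append(("chr1", pos, "chr1", pos))
    sh = pd.DataFrame(sh_rows, columns=["chrom", "pos0", "counterpart_chrom", "counterpart_pos0"])
    return (
        [_callset(rows_a)],
        [_callset(rows_b, ref="B")],
        sh,
        {"chr1": n_windows * win},
        win,
    )


class TestHomologousWindows:
    def test_identity_gives_p_one_everywhere(self):
        rows = [("chr1", 10 + 15 * i, "+", 100, 40) for i in range(60)]
        a = [_callset(rows)]
        b = [_callset(rows, ref="B")]
        sh = pd.DataFrame(
            {
                "chrom": "chr1", "pos0": [r[1] for r in rows],
                "counterpart_chrom": "chr1", "counterpart_pos0": [r[1] for r in rows],
            }
        )
        res = bias.homologous_window_bias(sh, a, b, {"chr1": 1_000}, win=1_000)
        assert (res.windows["p"] == 1.0).all()
        assert (res.windows["p_adj"] > 0.05).all()

    def test_injected_shift_flagged_uniquely(self):
        a, b, sh, lens, win = _window_fixture(shift_window=2)
        res = bias.homologous_window_bias(sh, a, b, lens, win=win)
        sig = res.windows[res.windows["p_adj"] < 0.05]
        assert sig.shape[0] == 1
        assert sig.iloc[0]["start"] == 2_000
        assert sig.iloc[0]["mean_diff"] == pytest.approx(-20.0, abs=2.0)

    def test_signed_rank_p_matches_exact_oracle(self):
        # a constant shift makes every paired difference negative: the
        # two-sided exact signed-rank p at n=50 is 2 * 2^-50
        a, b, sh, lens, win = _window_fixture(shift_window=1)
        res = bias.homologous_window_bias(sh, a, b, lens, win=win)
        p = res.windows.set_index("start").loc[1_000, "p"]
        diffs = np.full(50, -1.0)
        exact = sps.wilcoxon(diffs, alternative="two-sided", method="exact")[1]
        # scipy falls back to a normal approximation for our computation at
        # n=50; both must call the window overwhelmingly significant
        assert p < 1e-6 and exact < 1e-12

    def test_small_windows_skipped_and_counted(self):
        a, b, sh, lens, win = _window_fixture(n_windows=3, cpg_per_window=9)
        res = bias.homologous_window_bias(sh, a, b, lens, win=win, min_pairs=10)
        assert res.n_tested == 0
        assert res.n_skipped == 3

    def test_tested_plus_skipped_is_total(self):
        a, b, sh, lens, win = _window_fixture(n_windows=4)
        res = bias.homologous_window_bias(sh, a, b, lens, win=win)
        assert res.n_tested + res.n_skipped == 4


class TestFindHomologousWindows:
    def test_identity_pair_maps_windows_onto_themselves(self):
        rng = np.random.default_rng(5)
        g = {"chr1": "".join(rng.choice(list("ACGT"), size=30_000))}
        df = bias.find_homologous_windows(g, dict(g), win=10_000)
        assert df.shape[0] == 3
        assert (df["start_b"] == df["start_a"]).all()


class TestBreedSpecificShift:
    def _setup(self, shift_pp=0.0, n=500, seed=0):
        rng = np.random.default_rng(seed)
        rows, cls_rows = [], []
        for i in range(n):
            pct = rng.uniform(30, 80)
            rows.append(("chr1", 10 * i, "+", 100, int(round(pct))))
            cls_rows.append(("chr1", 10 * i, "shared"))
        for i in range(n):
            pct = min(100, max(0, rng.uniform(30, 80) + shift_pp))
            rows.append(("chr1", 10 * (n + i), "+", 100, int(round(pct))))
            cls_rows.append(("chr1", 10 * (n + i), "breed_specific"))
        calls = _callset(rows)
        cls = pd.DataFrame(cls_rows, columns=["chrom", "pos0", "cls"])
        return calls, cls

    def test_type_one_error_calibrated(self):
        hits = 0
        for rep in range(100):
            calls, cls = self._setup(0.0, n=500, seed=rep)
            r = bias.breed_specific_meth_shift(calls, cls)
            hits += r.p < 0.05
        assert hits <= 10  # p > 0.05 in at least 90% of null repetitions

    def test_downshift_detected_as_lower(self):
        calls, cls = self._setup(-20.0, n=500, seed=1)
        r = bias.breed_specific_meth_shift(calls, cls)
        assert r.p < 1e-6
        assert r.direction == "lower"
        assert r.median_breed_specific < r.median_background

    def test_empty_breed_specific_raises(self):
        calls, cls = self._setup(0.0, n=10)
        cls = cls[cls["cls"] == "shared"]
        with pytest.raises(ValueError, match="breed-specific"):
            bias.breed_specific_meth_shift(calls, cls)

    def test_empty_background_raises(self):
        calls, cls = self._setup(0.0, n=10)
        cls["cls"] = "breed_specific"
        with pytest.raises(ValueError, match="background"):
            bias.breed_specific_meth_shift(calls, cls)
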