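"""Paired tests, delta correlations, multiplicity control, KDE."""

import numpy as np
import pandas as pd
import pytest

from tinnet import longstats as ls
from tinnet.containers import ScoreTable


class TestPairedT:
    def test_hand_computed_example(self):
        res = ls.paired_t([50, 60, 70, 80], [40, 55, 65, 70])
        assert res.t == pytest.approx(5.196, abs=1e-3)
        assert res.df == 3

    def test_identical_vectors(self):
        res = ls.paired_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.t == 0.0 and res.p == 1.0

    def test_incomplete_pairs_dropped(self):
        res = ls.paired_t([50, 60, np.nan, 80, 70],
                          [40, 55, 65, np.nan, 60])
        assert res.n_pairs == 3 and res.df == 2

    def test_constant_shift_degenerate(self):
        res = ls.paired_t([1, 2, 3, 4], [0, 1, 2, 3])
        assert res.degenerate and res.t is None

    def test_equals_one_sample_t_on_differences(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        a = rng.normal(50, 10, 12)
        b = a - rng.normal(5, 3, 12)
        res = ls.paired_t(a, b)
        t_ref, p_ref = stats.ttest_1samp(a - b, 0.0)
        assert res.t == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)


class TestDeltaCorrelation:
    def test_exact_linear_relation(self):
        x = np.arange(10, dtype=float)
        res = ls.delta_correlation(x, 2 * x, n_perm=99)
        assert res.r == pytest.approx(1.0)

    def test_constant_deltas_degenerate(self):
        res = ls.delta_correlation(np.ones(6), np.arange(6.0), n_perm=99)
        assert res.degenerate and res.r is None

    def test_param_and_perm_p_agree_for_gaussian_data(self):
        rng = np.random.default_rng(1)
        diffs = []
        for rep in range(30):
            x = rng.standard_normal(16)
            y = 0.5 * x + rng.standard_normal(16)
            res = ls.delta_correlation(x, y, n_perm=1999, seed=rep)
            diffs.append(abs(res.p_param - res.p_perm))
        assert np.mean(diffs) < 0.02

    def test_spearman_option_rank_invariant(self):
        x = np.array([1, 2, 3, 4, 5, 6.0])
        res_a = ls.delta_correlation(x, np.exp(x), method="spearman",
                                     n_perm=99)
        assert res_a.r == pytest.approx(1.0)


class TestMultiplicity:
    def test_holm_hand_example(self):
        np.testing.assert_allclose(ls.fwer_adjust([0.01, 0.04]),
                                   [0.02, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ls.fwer_adjust([0.3]), [0.3])
        np.testing.assert_allclose(ls.fdr_adjust([0.5]), [0.5])

    def test_bh_hand_example(self):
        np.testing.assert_allclose(ls.fdr_adjust([0.001, 0.02, 0.03, 0.04]),
                                   [0.004, 0.04, 0.04, 0.04])

    def test_ordering_holm_ge_bh_ge_raw(self):
        rng = np.random.default_rng(2)
        p = rng.random(20)
        holm = ls.fwer_adjust(p)
        bh = ls.fdr_adjust(p)
        assert (holm >= bh - 1e-12).all()
        assert (bh >= p - 1e-12).all()

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(ls.fwer_adjust([1.0, 1.0, 1.0]),
                                   [1.0, 1.0, 1.0])


class TestNodalCompare:
    def _frames(self, shift_roi=None, n=10, n_roi=20, seed=0):
        rng = np.random.default_rng(seed)
        a = pd.DataFrame(rng.standard_normal((n, n_roi)),
                         columns=[f"roi{i}" for i in range(n_roi)])
        b = pd.DataFrame(rng.standard_normal((n, n_roi)),
                         columns=a.columns)
        if shift_roi is not None:
            b[shift_roi] += 5.0
        return a, b

    def test_identical_groups_no_flags(self):
        a, _ = self._frames()
        out = ls.nodal_compare(a, a.copy(), fdr_q=0.05)
        assert not out.flag_fdr.any()

    def test_strongly_shifted_roi_flagged(self):
        a, b = self._frames(shift_roi="roi7")
        out = ls.nodal_compare(a, b, fdr_q=0.05)
        assert out.loc[out.node == "roi7", "flag_fdr"].item()

    def test_null_mean_flag_count_bounded(self):
        counts = []
        for s in range(30):
            a, b = self._frames(n_roi=30, seed=100 + s)
            out = ls.nodal_compare(a, b, fdr_q=0.05)
            counts.append(out.flag_fdr.sum())
        assert np.mean(counts) <= 30 * 0.05 + 0.5

    def test_degenerate_roi_reported(self):
        a, b = self._frames()
        a["roi3"] = 1.0
        b["roi3"] = 1.0
        out = ls.nodal_compare(a, b)
        row = out[out.node == "roi3"].iloc[0]
        assert row.degenerate and not row.flag_fdr


class TestDeltaRegression:
    def _deltas(self, n=12, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "dQ": rng.standard_normal(n),
            "dE_glob": rng.standard_normal(n),
            "dC_glob": rng.standard_normal(n),
        })
        df["delta_score"] = 3 * df.dQ + noise * rng.standard_normal(n)
        return df

    def test_exact_construction_recovered(self):
        res = ls.regress_delta_scores(self._deltas())
        assert res.params["dQ"] == pytest.approx(3.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_minimal_sample_size_boundary(self):
        res = ls.regress_delta_scores(self._deltas(n=5))
        assert res.df_resid == 1

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            ls.regress_delta_scores(self._deltas(n=4))

    def test_null_r_squared_follows_beta_reference(self):
        """Under a pure-noise outcome, R^2 ~ Beta(p/2, (n-p-1)/2)."""
        from scipy import stats

        rng = np.random.default_rng(5)
        n, p = 20, 3
        r2 = []
        for s in range(200):
            df = self._deltas(n=n, seed=200 + s)
            df["delta_score"] = rng.standard_normal(n)
            r2.append(ls.regress_delta_scores(df).r_squared)
        ref = stats.beta(p / 2, (n - p - 1) / 2)
        ks = stats.kstest(r2, ref.cdf).pvalue
        assert ks > 0.01

    def test_collinear_predictors_warn(self):
        df = self._deltas()
        df["dE_glob"] = 2 * df.dQ
        with pytest.warns(UserWarning, match="ill-conditioned"):
            ls.regress_delta_scores(df)


class TestKDE:
    def test_mode_near_zero_for_standard_normal(self):
        """Consistency: the KDE mode concentrates at 0 (median over a
        few draws; a single draw's argmax wanders on the flat peak)."""
        modes = []
        for s in range(5):
            rng = np.random.default_rng(s)
            res = ls.kde_summary(rng.standard_normal(5000))
            modes.append(res.grid[np.argmax(res.density)])
        assert abs(np.median(modes)) < 0.1

    def test_integrates_to_one(self):
        rng = np.random.default_rng(1)
        res = ls.kde_summary(rng.normal(3, 2, 500))
        area = np.trapezoid(res.density, res.grid)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_bimodal_mixture_two_modes(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(-3, 0.5, 800),
                            rng.normal(3, 0.5, 800)])
        res = ls.kde_summary(x)
        assert len(res.modes()) == 2

    def test_constant_series_degenerate(self):
        res = ls.kde_summary(np.full(50, 2.5))
        assert res.degenerate and res.spike_at == 2.5


class TestDeltaRecords:
    def test_consecutive_pairs_and_normalization(self):
        metrics = pd.DataFrame([
            {"subject": "s1", "session": "pre", "density": 0.1,
             "metric": "Q", "node": "", "value": 0.5},
            {"subject": "s1", "session": "post", "density": 0.1,
             "metric": "Q", "node": "", "value": 0.4},
            {"subject": "s2", "session": "pre", "density": 0.1,
             "metric": "Q", "node": "", "value": 0.6},
            {"subject": "s2", "session": "post", "density": 0.1,
             "metric": "Q", "node": "", "value": 0.3},
        ])
        scores = ScoreTable.from_wide({"s1": {"pre": 50, "post": 40},
                                       "s2": {"pre": 60, "post": 30}})
        rec = ls.build_delta_records(metrics, scores, "Q", 0.1)
        assert len(rec) == 2
        s1 = rec[rec.subject == "s1"].iloc[0]
        assert s1.delta_metric == pytest.approx(-0.1)
        assert s1.delta_score == pytest.approx(-10.0)
        assert s1.normalized == pytest.approx(-0.2)

    def test_subjects_missing_a_session_excluded(self):
        metrics = pd.DataFrame([
            {"subject": "s1", "session": "pre", "density": 0.1,
             "metric": "Q", "node": "", "value": 0.5},
            {"subject": "s1", "session": "post", "density": 0.1,
             "metric": "Q", "node": "", "value": 0.4},
        ])
        scores = ScoreTable.from_wide({"s1": {"pre": 50},
                                       "s2": {"pre": 60, "post": 30}})
        rec = ls.build_delta_records(metrics, scores, "Q", 0.1)
        assert rec.empty
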