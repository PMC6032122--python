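"""Psychometric function, ML fitting, binning and baseline selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fixsens.psychofit import (GlobalFit, axial_difference, baseline_trials,
                               bin_by_latency, fit_ml, fit_mu, global_fit,
                               neg_log_likelihood, predict)


def make_trials(mu, s, lam, n, rng, c_lo=None, c_hi=None, sf=1.0, subject="s01"):
    """Bernoulli trials from the logistic at contrasts spanning the slope."""
    c_lo = mu - 3 * s if c_lo is None else c_lo
    c_hi = mu + 3 * s if c_hi is None else c_hi
    c = rng.uniform(c_lo, c_hi, n)
    y = (rng.random(n) < predict(c, mu, s, lam)).astype(int)
    return pd.DataFrame({"subject": subject, "sf_cpd": sf, "log10_contrast": c,
                         "correct": y})


class TestPredict:
    def test_threshold_is_75_percent(self):
        # at c = mu with no lapses the logistic sits exactly at 75%
        assert predict(-1.5, mu=-1.5, s=0.1, lam=0.0) == pytest.approx(0.75)

    def test_saturating_limit(self):
        assert predict(10.0, mu=-1.5, s=0.1, lam=0.08) == pytest.approx(1 - 0.08 / 2)

    def test_guessing_floor(self):
        assert predict(-30.0, mu=-1.5, s=0.1, lam=0.08) == pytest.approx(0.5)

    @given(st.floats(-3, 0), st.floats(0.02, 0.3), st.floats(0, 0.2))
    def test_monotone_in_contrast(self, mu, s, lam):
        c = np.linspace(mu - 5 * s, mu + 5 * s, 50)
        p = predict(c, mu, s, lam)
        assert np.all(np.diff(p) >= 0)
        assert np.all((p >= 0.5) & (p <= 1 - lam / 2 + 1e-12))

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            predict(0.0, mu=0.0, s=0.0)


class TestFitMu:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(2)
        df = make_trials(mu=-1.0, s=0.09, lam=0.055, n=2000, rng=rng)
        mu_hat, _, flag = fit_mu(df.log10_contrast.to_numpy(),
                                 df.correct.to_numpy(), s=0.09, lam=0.055)
        assert flag == ""
        assert mu_hat == pytest.approx(-1.0, abs=0.05 * 1.0)

    def test_duplicating_trials_leaves_estimate_unchanged(self):
        rng = np.random.default_rng(3)
        df = make_trials(mu=-1.5, s=0.08, lam=0.0, n=400, rng=rng)
        c = df.log10_contrast.to_numpy()
        y = df.correct.to_numpy()
        m1, _, _ = fit_mu(c, y, s=0.08, lam=0.0)
        m2, _, _ = fit_mu(np.r_[c, c], np.r_[y, y], s=0.08, lam=0.0)
        assert m2 == pytest.approx(m1, abs=1e-5)

    def test_matches_dense_grid_search_oracle(self):
        # two-contrast dataset: the ML threshold must agree with a
        # brute-force 1-D likelihood scan
        c = np.r_[np.full(60, -1.2), np.full(60, -0.9)]
        y = np.r_[(np.arange(60) < 35).astype(int), (np.arange(60) < 55).astype(int)]
        s, lam = 0.1, 0.02
        grid = np.arange(-2.0, 0.0, 1e-4)
        nll = [neg_log_likelihood(c, y, m, s, lam) for m in grid]
        oracle = grid[int(np.argmin(nll))]
        mu_hat, _, _ = fit_mu(c, y, s=s, lam=lam)
        assert mu_hat == pytest.approx(oracle, abs=1e-4)

    def test_all_correct_data_flagged(self):
        c = np.linspace(-1.0, -0.5, 50)
        y = np.ones(50, dtype=int)
        _, _, flag = fit_mu(c, y, s=0.1, lam=0.0)
        assert flag == "boundary"

    def test_asymptotic_unbiasedness(self):
        # frozen-(s, lam) threshold fit: bias shrinks to the 2% level at n=1e4
        rng = np.random.default_rng(4)
        df = make_trials(mu=-1.0, s=0.08, lam=0.055, n=10_000, rng=rng)
        mu_hat, _, _ = fit_mu(df.log10_contrast.to_numpy(), df.correct.to_numpy(),
                              s=0.08, lam=0.055)
        assert abs(mu_hat - (-1.0)) < 0.02


class TestFitMl:
    def test_lapse_recovery_from_ceiling(self):
        # ceiling at 0.95 implies lam = 0.1
        rng = np.random.default_rng(5)
        df = make_trials(mu=-1.0, s=0.08, lam=0.1, n=8000, rng=rng, c_hi=-0.4)
        params, _, _ = fit_ml(df.log10_contrast, df.correct,
                              free=("mu", "lam"), fixed={"s": 0.08})
        assert params.lam == pytest.approx(0.1, abs=0.04)


class TestGlobalFit:
    def test_joint_recovery_of_lapse_and_slopes(self):
        rng = np.random.default_rng(6)
        mus = {0.1: -1.3, 0.33: -1.7, 1.0: -2.0, 2.0: -2.1, 5.0: -1.8}
        # contrasts must reach well past threshold for the lapse to be
        # identifiable from the ceiling
        parts = [make_trials(m, 0.08, 0.055, 3000, rng, sf=sf, c_hi=m + 0.6)
                 for sf, m in mus.items()]
        trials = pd.concat(parts, ignore_index=True)
        gf = global_fit(trials)
        assert 0.03 <= gf.lam <= 0.08
        for sf, m in mus.items():
            assert gf.s[sf] == pytest.approx(0.08, rel=0.2)
            assert gf.mu[sf] == pytest.approx(m, abs=0.05)

    def test_slope_exchangeability(self):
        # identical psychometrics at every sf: slope estimates agree
        rng = np.random.default_rng(7)
        parts = [make_trials(-1.5, 0.1, 0.04, 4000, rng, sf=sf)
                 for sf in (0.1, 0.33, 1.0, 2.0, 5.0)]
        gf = global_fit(pd.concat(parts, ignore_index=True))
        s = np.array(list(gf.s.values()))
        assert s.max() - s.min() < 0.04

    def test_missing_sf_level_rejected(self):
        rng = np.random.default_rng(8)
        trials = make_trials(-1.5, 0.1, 0.0, 100, rng, sf=1.0)
        with pytest.raises(ValueError):
            global_fit(trials, sfs=[0.1, 1.0])


class TestBinning:
    def test_window_arithmetic(self):
        trials = pd.DataFrame({"tau_s": [0.049], "x": [1]})
        centers = [tc for tc, sub in bin_by_latency(trials, width=0.1, step=0.002,
                                                    trange=(-0.1, 0.4))
                   if len(sub) == 1]
        assert centers[0] == pytest.approx(0.0, abs=1e-9)
        assert centers[-1] == pytest.approx(0.098, abs=1e-9)

    def test_empty_range(self):
        trials = pd.DataFrame({"tau_s": [0.0]})
        assert list(bin_by_latency(trials, trange=(0.5, 0.0))) == []

    def test_uniform_density_fills_bins(self):
        rng = np.random.default_rng(9)
        trials = pd.DataFrame({"tau_s": rng.uniform(-0.5, 0.5, 1000)})
        counts = [len(sub) for tc, sub in
                  bin_by_latency(trials, width=0.1, step=0.05, trange=(-0.3, 0.3))]
        assert np.allclose(counts, 100, atol=35)

    def test_overlapping_bins_share_trials(self):
        # tau=0.02 falls in [c-0.05, c+0.05) for centers 0.0..0.06
        trials = pd.DataFrame({"tau_s": [0.02]})
        n_hit = sum(len(sub) for _, sub in
                    bin_by_latency(trials, width=0.1, step=0.02, trange=(0.0, 0.08)))
        assert n_hit == 4


class TestBaseline:
    def test_no_event_sentinel_is_baseline(self):
        trials = pd.DataFrame({"tau_s": [np.inf]})
        assert len(baseline_trials(trials)) == 1

    def test_perisaccadic_trial_excluded(self):
        trials = pd.DataFrame({"tau_s": [0.05]})
        assert len(baseline_trials(trials)) == 0

    def test_zone_boundaries(self):
        trials = pd.DataFrame({"tau_s": [-0.2, -0.05, 0.0, 0.3, 0.6]})
        kept = baseline_trials(trials)["tau_s"].tolist()
        assert kept == [-0.2, 0.6]

    def test_is_baseline_column_takes_precedence(self):
        # an extra event inside the zone disqualifies even when the
        # nearest one is outside
        trials = pd.DataFrame({"tau_s": [-0.2], "is_baseline": [False]})
        assert len(baseline_trials(trials)) == 0


class TestOrientationFold:
    def test_parallel(self):
        assert axial_difference(45.0, 45.0) == 0.0

    def test_orthogonal_axial_fold(self):
        assert axial_difference(45.0, 135.0) == 90.0

    def test_axial_equivalence(self):
        # a saccade direction and its opposite give the same fold
        d = axial_difference(45.0, 200.0)
        assert d == axial_difference(45.0, 20.0)

    @given(st.floats(0, 360), st.floats(0, 360))
    def test_range(self, a, b):
        d = axial_difference(a, b)
        assert 0.0 <= d <= 90.0


class TestSrInvariance:
    def test_contrast_rescaling_leaves_sr_unchanged(self):
        # multiplying all linear contrasts by a constant shifts log10
        # thresholds of bin and baseline equally; SR is their difference
        rng = np.random.default_rng(10)
        df = make_trials(-1.2, 0.08, 0.0, 1500, rng)
        base = make_trials(-1.0, 0.08, 0.0, 1500, rng)
        shift = 0.7

        def sr(bin_df, base_df):
            m1, _, _ = fit_mu(bin_df.log10_contrast, bin_df.correct, 0.08, 0.0)
            m0, _, _ = fit_mu(base_df.log10_contrast, base_df.correct, 0.08, 0.0)
            return -(m1 - m0)

        a = sr(df, base)
        df2, base2 = df.copy(), base.copy()
        df2.log10_contrast += shift
        base2.log10_contrast += shift
        assert sr(df2, base2) == pytest.approx(a, abs=1e-4)
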