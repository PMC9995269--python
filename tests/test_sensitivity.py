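import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rainfor import (
    SynthConfig, binned_response, elnino_stratify, estimate, find_pairs,
    generate_bundle, pair_delta_p, season_map, significance,
)
from rainfor.grids import cover_loss
from rainfor.sensitivity import season_selector, seasonal_estimate
from conftest import END_YEARS, START_YEARS, cube_da


def pairs_frame(sensitivities, dp_def=None, dp_ctl=None):
    s = np.asarray(sensitivities, dtype=float)
    n = s.size
    return pd.DataFrame({
        "sensitivity": s,
        "rel_sensitivity": s,
        "delta_f": np.full(n, 10.0),
        "delta_p": s * 10.0,
        "dp_def": s * 10.0 if dp_def is None else np.asarray(dp_def, float),
        "dp_ctl": np.zeros(n) if dp_ctl is None else np.asarray(dp_ctl, float),
        "scale": np.full(n, 0.05),
    })


class TestEstimate:
    def test_median_and_se_arithmetic(self):
        df = pairs_frame([-0.2, -0.3, -0.25])
        est = estimate(df)
        assert est.median == pytest.approx(-0.25)
        assert est.se == pytest.approx(np.std([-0.2, -0.3, -0.25], ddof=1) / np.sqrt(3))
        assert est.n == 3

    def test_single_pair_se_missing(self):
        est = estimate(pairs_frame([-0.4]))
        assert est.median == pytest.approx(-0.4)
        assert np.isnan(est.se)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate(pairs_frame([]))

    def test_bootstrap_se_close_to_analytic_for_gaussian(self):
        rng = np.random.default_rng(0)
        df = pairs_frame(rng.normal(-0.25, 0.5, 2000))
        est = estimate(df, seed=1)
        # SE of the median of a Gaussian is ~1.2533 * SE of the mean
        assert est.boot_se == pytest.approx(1.2533 * est.se, rel=0.15)


class TestSignificance:
    def test_degenerate_groups_flagged(self):
        df = pairs_frame([0.0, 0.0, 0.0], dp_def=[1.0, 1.0, 1.0], dp_ctl=[1.0, 1.0, 1.0])
        p_t, p_mw = significance(df)
        assert np.isnan(p_t) and np.isnan(p_mw)

    def test_null_calibration(self):
        """When deforested and control changes share a distribution, the
        Welch t-test rejects at alpha=0.05 at the nominal rate."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            df = pairs_frame(np.zeros(60), dp_def=rng.normal(0, 1, 60),
                             dp_ctl=rng.normal(0, 1, 60))
            p_t, _ = significance(df)
            rejections += p_t < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_power_with_injected_effect(self, noisy_bundle, window_loss):
        loss = window_loss(noisy_bundle)
        ps = find_pairs(loss, noisy_bundle.mask)
        df = pair_delta_p(ps, noisy_bundle.precip, START_YEARS, END_YEARS)
        p_t, p_mw = significance(df)
        assert p_t < 0.01 and p_mw < 0.01

    def test_tests_agree_when_well_powered(self):
        rng = np.random.default_rng(7)
        agree = 0
        n_rep = 50
        for _ in range(n_rep):
            df = pairs_frame(np.zeros(200), dp_def=rng.normal(-1.0, 2.0, 200),
                             dp_ctl=rng.normal(0.0, 2.0, 200))
            p_t, p_mw = significance(df)
            agree += (p_t < 0.05) == (p_mw < 0.05)
        assert agree / n_rep >= 0.8


class TestSeasonMap:
    def test_sinusoid_peaking_in_february(self):
        months = np.arange(12)
        clim = 100.0 + 50.0 * np.cos(2 * np.pi * (months - 1) / 12)
        vals = np.tile(clim[:, None, None], (2, 1, 1)).reshape(24, 1, 1)
        smap = season_map(cube_da(vals))
        wet = set(smap["month"].values[smap.values[:, 0, 0] == 2])
        dry = set(smap["month"].values[smap.values[:, 0, 0] == 0])
        assert wet == {1, 2, 3}
        assert dry == {7, 8, 9}

    def test_constant_climatology_tie_break(self):
        smap = season_map(cube_da(np.full((24, 1, 1), 80.0)))
        dry = set(smap["month"].values[smap.values[:, 0, 0] == 0])
        wet = set(smap["month"].values[smap.values[:, 0, 0] == 2])
        assert dry == {1, 2, 3} and wet == {10, 11, 12}

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_partition_and_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        clim = rng.uniform(0, 300, 12)
        vals = np.tile(clim[:, None, None], (3, 1, 1)).reshape(36, 1, 1)
        smap = season_map(cube_da(vals))
        codes = smap.values[:, 0, 0]
        assert (codes == 0).sum() == 3 and (codes == 2).sum() == 3 and (codes == 1).sum() == 6
        order = np.argsort(clim, kind="stable")
        assert set(np.nonzero(codes == 0)[0]) == set(order[:3])
        assert set(np.nonzero(codes == 2)[0]) == set(order[-3:])

    def test_missing_month_unclassified(self):
        vals = np.tile(np.arange(12.0)[:, None, None], (2, 1, 1)).reshape(24, 1, 1)
        vals[3] = np.nan
        smap = season_map(cube_da(vals))
        assert np.isnan(smap.values[:, 0, 0]).all()


class TestSeasonalEstimate:
    def test_uniform_effect_same_in_all_seasons(self):
        cfg = SynthConfig(shape=(24, 24), sigma=0.0, cover_noise=0.0, beta=-0.25, seed=9)
        b = generate_bundle(cfg)
        loss = cover_loss(b.cover, START_YEARS, END_YEARS)
        ps = find_pairs(loss, b.mask)
        smap = season_map(b.precip)
        ests = seasonal_estimate(ps, b.precip, smap, START_YEARS, END_YEARS)
        for season, est in ests.items():
            assert est.median == pytest.approx(-0.25, abs=1e-9), season

    def test_dry_only_effect_concentrates_in_dry_season(self):
        """An effect confined to the 3 driest months appears at 4x strength
        in the dry-season estimate and vanishes from the wet season."""
        cfg = SynthConfig(shape=(24, 24), sigma=0.0, cover_noise=0.0, beta=-0.25,
                          response_months="dry", seed=10)
        b = generate_bundle(cfg)
        loss = cover_loss(b.cover, START_YEARS, END_YEARS)
        ps = find_pairs(loss, b.mask)
        smap = season_map(b.precip)
        ests = seasonal_estimate(ps, b.precip, smap, START_YEARS, END_YEARS)
        annual = estimate(pair_delta_p(ps, b.precip, START_YEARS, END_YEARS))
        assert ests["dry"].median == pytest.approx(-0.25, abs=1e-6)
        assert ests["wet"].median == pytest.approx(0.0, abs=1e-9)
        assert ests["dry"].median == pytest.approx(4 * annual.median, rel=1e-6)


class TestBinnedResponse:
    def test_single_bin_matches_global_median(self):
        df = pairs_frame([-0.2, -0.3, -0.25])
        b = binned_response(df, edges=[0.1, np.inf])
        assert b.median[0] == pytest.approx(np.median([-0.2, -0.3, -0.25]))

    def test_empty_bin_is_missing_not_zero(self):
        df = pairs_frame([-0.2, -0.3])  # all delta_f = 10
        b = binned_response(df, edges=[0.1, 5.0, 20.0, np.inf])
        assert np.isnan(b.median[0]) and np.isnan(b.median[2])
        assert b.n[1] == 2

    def test_left_closed_right_open(self):
        df = pairs_frame([-0.2])
        df["delta_f"] = 5.0
        b = binned_response(df, edges=[0.1, 5.0, np.inf])
        assert b.n[1] == 1 and b.n[0] == 0

    def test_saturating_truth_decreasing_magnitude(self):
        cfg = SynthConfig(shape=(48, 48), sigma=0.0, cover_noise=0.0, beta=-0.25,
                          response="saturating", half_saturation=30.0,
                          n_clusters=30, max_loss=60.0, seed=11)
        b = generate_bundle(cfg)
        loss = cover_loss(b.cover, START_YEARS, END_YEARS)
        ps = find_pairs(loss, b.mask)
        df = pair_delta_p(ps, b.precip, START_YEARS, END_YEARS)
        br = binned_response(df, edges=[0.1, 5, 10, 20, np.inf])
        mags = np.abs(br.median[np.isfinite(br.median)])
        assert (np.diff(mags) < 0).all()

    def test_requires_increasing_edges(self):
        with pytest.raises(ValueError):
            binned_response(pairs_frame([-0.2]), edges=[5.0, 1.0])


class TestElninoStratify:
    WINDOWS = {
        "incl_nino": (range(2003, 2006), range(2015, 2018)),
        "excl_nino": (range(2003, 2006), range(2011, 2014)),
    }

    def test_additive_anomaly_leaves_estimates_identical(self):
        """A purely additive basin-wide anomaly is removed exactly by the
        paired differencing, so window choice does not matter."""
        kw = dict(shape=(24, 24), sigma=0.0, cover_noise=0.0, beta=-0.25,
                  elnino_years=(2015, 2016), elnino_anomaly=-20.0, seed=12)
        b = generate_bundle(SynthConfig(**kw))
        ests = elnino_stratify(b.cover, b.mask, b.precip, self.WINDOWS)
        assert ests["incl_nino"].median == pytest.approx(-0.25, abs=1e-9)
        assert ests["excl_nino"].median == pytest.approx(-0.25, abs=1e-9)

    def test_beta_multiplier_strengthens_nino_window(self):
        kw = dict(shape=(32, 32), sigma=5.0, beta=-0.25,
                  elnino_years=(2015, 2016, 2017), elnino_beta_multiplier=1.5, seed=13)
        b = generate_bundle(SynthConfig(**kw))
        ests = elnino_stratify(b.cover, b.mask, b.precip, self.WINDOWS)
        assert abs(ests["incl_nino"].median) > abs(ests["excl_nino"].median)

    def test_requires_two_windows(self, noiseless_bundle):
        b = noiseless_bundle
        with pytest.raises(ValueError):
            elnino_stratify(b.cover, b.mask, b.precip, {"only": (START_YEARS, END_YEARS)})
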