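import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import steppescan as ss
from steppescan.admix_dating import WeightedLDCurve, _pairwise_complete_cov
from steppescan.errors import ConfigError, DatingError


class TestAnalyticConversions:
    @pytest.mark.parametrize("g,expected", [(20, 2.5), (53, 0.94), (50, 1.0)])
    def test_expected_tract_length(self, g, expected):
        assert ss.expected_tract_length_cM(g) == pytest.approx(expected, abs=0.005)

    def test_invalid_generations(self):
        with pytest.raises(ConfigError):
            ss.expected_tract_length_cM(0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.integers(min_value=1, max_value=1000))
    def test_tract_length_identity(self, g):
        assert ss.expected_tract_length_cM(g) * 2 * g == pytest.approx(100.0)

    def test_turkic_period_conversions(self):
        assert ss.years_to_generations(600) == 20
        assert int(ss.years_to_generations(1600)) == 53  # printed rounded down
        assert ss.years_to_generations(0) == 0

    @pytest.mark.parametrize("g,year", [(0, 2000), (20, 1400), (70, -100)])
    def test_calendar_anchor(self, g, year):
        assert ss.generations_to_calendar(g) == year

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=0, max_value=5000, allow_nan=False))
    def test_calendar_roundtrip(self, years):
        g = ss.years_to_generations(years)
        assert ss.generations_to_calendar(g) == pytest.approx(2000 - years)


class TestProjectionProportion:
    @pytest.mark.parametrize(
        "x1,x2,x3,alpha", [(-1, 1, 0, 0.5), (-1, 1, -1, 1.0), (-1, 1, 1, 0.0)]
    )
    def test_projection_formula(self, x1, x2, x3, alpha):
        coords = ss.ProjectionCoordinates(x1, x2, x3)
        assert ss.projection_admixture_proportion(coords) == pytest.approx(alpha)

    def test_degenerate_axis(self):
        with pytest.raises(ConfigError, match="degenerate"):
            ss.projection_admixture_proportion(ss.ProjectionCoordinates(1, 1, 0))

    def test_outside_span_warns_but_returns(self, caplog):
        coords = ss.ProjectionCoordinates(-1, 1, 2)
        with caplog.at_level("WARNING"):
            val = ss.projection_admixture_proportion(coords)
        assert val == pytest.approx(-0.5)
        assert "outside" in caplog.text


def synthetic_curve(A, g, c, n_bins=60, d_min=0.5, width=0.25):
    mids = d_min + width * np.arange(n_bins) + width / 2
    y = A * np.exp(-g * mids / 100.0) + c
    return WeightedLDCurve(mids, y, np.full(n_bins, 100), ("r1", "r2"))


class TestLDDecayFit:
    def test_exact_recovery_on_model_family(self):
        est = ss.fit_ld_decay(synthetic_curve(3.0, 15.0, 0.1))
        assert est.g_hat == pytest.approx(15.0, abs=1e-6)
        assert est.amplitude == pytest.approx(3.0, rel=1e-6)
        assert est.affine == pytest.approx(0.1, abs=1e-6)

    def test_scale_equivariance(self):
        base = synthetic_curve(2.0, 25.0, 0.05)
        est1 = ss.fit_ld_decay(base)
        scaled = WeightedLDCurve(base.bin_mid_cM, 7.0 * base.value,
                                 base.pair_count, base.ref_pair)
        est2 = ss.fit_ld_decay(scaled)
        assert est2.g_hat == pytest.approx(est1.g_hat, abs=1e-9)
        assert est2.amplitude == pytest.approx(7.0 * est1.amplitude, rel=1e-6)

    def test_calendar_attached(self):
        est = ss.fit_ld_decay(synthetic_curve(1.0, 20.0, 0.0))
        assert est.calendar_year == pytest.approx(2000 - 30 * est.g_hat)

    def test_flat_curve_reports_no_admixture_ld(self):
        flat = synthetic_curve(0.0, 10.0, 0.2)
        with pytest.raises(DatingError, match="no admixture LD"):
            ss.fit_ld_decay(flat)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ConfigError, match="bins"):
            ss.fit_ld_decay(synthetic_curve(1.0, 10.0, 0.0, n_bins=5))


class TestWeightedLDCurve:
    def test_zero_weights_give_zero_curve(self, admixture_sim_g20):
        _, geno, _ = admixture_sim_g20
        # duplicate source1 panel under both reference labels -> w identically 0
        pops = geno.sample_populations.copy()
        pops[pops == "source2"] = "source1x"
        idx1 = np.flatnonzero(geno.sample_populations == "source1")
        dos = geno.dosages.copy()
        dos[pops == "source1x"] = dos[idx1]
        geno0 = ss.GenotypeDataset(geno.samples, pops, geno.snps, dos)
        curve = ss.weighted_ld_curve(geno0, "admixed", "source1", "source1x",
                                     d_max_cM=10.0)
        assert np.allclose(curve.value, 0.0)

    def test_identical_references_rejected(self, admixture_sim_g20):
        _, geno, _ = admixture_sim_g20
        with pytest.raises(ConfigError):
            ss.weighted_ld_curve(geno, "admixed", "source1", "source1")

    def test_curve_decays_with_distance(self, admixture_sim_g20):
        _, geno, _ = admixture_sim_g20
        curve = ss.weighted_ld_curve(geno, "admixed", "source1", "source2",
                                     d_max_cM=10.0)
        rho = stats.spearmanr(curve.bin_mid_cM, curve.value).statistic
        assert rho < -0.5

    def test_unadmixed_panel_has_no_amplitude(self):
        """A pure source-1 panel shows no weighted-LD decay signal: the fitted
        amplitude is indistinguishable from bin noise."""
        cfg = ss.AdmixtureSimConfig(g=20, alpha=1.0, seed=3)
        geno, _ = ss.simulate_admixed_haplotypes(cfg)
        curve = ss.weighted_ld_curve(geno, "admixed", "source1", "source2",
                                     d_max_cM=20.0)
        noise_sd = curve.value.std(ddof=1)
        try:
            est = ss.fit_ld_decay(curve)
            assert abs(est.amplitude) < 2 * noise_sd
        except DatingError:
            pass  # amplitude at the zero boundary: also "no signal"

    def test_pairwise_complete_cov_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(30, 6)).astype(float)
        X[rng.random(X.shape) < 0.2] = np.nan
        got = _pairwise_complete_cov(X)
        expected = np.empty((6, 6))
        for i in range(6):
            for j in range(6):
                rows = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
                expected[i, j] = np.cov(X[rows, i], X[rows, j])[0, 1]
        np.testing.assert_allclose(got, expected, rtol=1e-10)


class TestTractDating:
    def test_exponential_tracts_invert_to_g(self):
        rng = np.random.default_rng(4)
        lengths_M = rng.exponential(0.1, size=4000)
        est = ss.date_from_tract_lengths(lengths_M, alpha=0.5, mode="ancestry",
                                         lengths_unit="morgans", seed=1)
        assert est.ci_low <= 20.0 <= est.ci_high
        assert est.g_hat == pytest.approx(20.0, rel=0.10)

    def test_single_path_mode_inverts_mean_length(self):
        lengths = ss.draw_ibd_segment_lengths(53, 100_000, seed=9)
        est = ss.date_from_tract_lengths(lengths, mode="ibd_single_path",
                                         lengths_unit="cM", seed=2)
        assert est.g_hat == pytest.approx(53.0, rel=0.10)

    def test_recovery_from_simulated_tracts(self, admixture_sim_g20):
        cfg, _, tracts = admixture_sim_g20
        est = ss.date_from_tract_lengths(tracts, ancestry=1, alpha=cfg.alpha,
                                         seed=3)
        assert est.g_hat == pytest.approx(cfg.g, rel=0.25)

    def test_needs_enough_tracts(self):
        with pytest.raises(ConfigError, match="30"):
            ss.date_from_tract_lengths(np.full(10, 2.5), mode="ibd_single_path")

    def test_ancestry_mode_requires_alpha(self):
        with pytest.raises(ConfigError, match="alpha"):
            ss.date_from_tract_lengths(np.full(50, 2.5), mode="ancestry")


class TestBenchmarkHarness:
    SMALL = ss.AdmixtureSimConfig(g=5, n_haplotypes=8,
                                  chromosome_lengths_M=[1.0, 1.0],
                                  n_snps_per_chromosome=100,
                                  population_size=20, seed=0)

    def test_identity_estimator_stub(self):
        res = ss.benchmark_rmse_bias([5, 10], reps=2,
                                     estimator=lambda geno, tracts, cfg: cfg.g,
                                     sim_config=self.SMALL, seed=1)
        assert res.rmse == 0.0 and res.bias == 0.0

    def test_constant_offset_stub(self):
        res = ss.benchmark_rmse_bias([5, 10], reps=2,
                                     estimator=lambda geno, tracts, cfg: cfg.g + 5,
                                     sim_config=self.SMALL, seed=1)
        assert res.bias == pytest.approx(5.0)
        assert res.rmse == pytest.approx(5.0)

    def test_failures_recorded_and_excluded(self):
        calls = []

        def flaky(geno, tracts, cfg):
            calls.append(1)
            if len(calls) % 2:
                raise DatingError("boom")
            return cfg.g

        res = ss.benchmark_rmse_bias([5], reps=4, estimator=flaky,
                                     sim_config=self.SMALL, seed=2)
        assert res.n_failed == 2
        assert res.estimates["g_hat"].isna().sum() == 2
        assert res.rmse == 0.0

    def test_tracts_estimator_schema(self):
        cfg = ss.AdmixtureSimConfig(g=5, n_haplotypes=20,
                                    chromosome_lengths_M=[3.0] * 4,
                                    n_snps_per_chromosome=200,
                                    population_size=50, seed=0)
        res = ss.benchmark_rmse_bias([10, 20], reps=2, estimator="tracts",
                                     sim_config=cfg, seed=3)
        assert np.isfinite(res.rmse) and np.isfinite(res.bias)
        assert res.rmse >= abs(res.bias)
        assert set(res.estimates.columns) == {"g_true", "rep", "g_hat"}
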