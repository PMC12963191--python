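import numpy as np
import pytest
from scipy.stats import lognorm

from tissuemech.benchmarks import SyntheticFieldSpec, generate_field, lognormal_exceedance, two_cohort_fixture
from tissuemech.exposure import (
    auc,
    exceedance_curve,
    reference_thresholds,
    strain_benchmark_flags,
    thresholds_from_json,
    thresholds_to_json,
    tissue_exposure,
    weighted_percentile,
)


class TestWeightedPercentile:
    def test_single_sample(self):
        assert weighted_percentile([3.7], [2.0], 75) == 3.7

    def test_equal_volumes_matches_sorted_rank(self):
        vals = np.arange(1, 10001, dtype=float)
        got = weighted_percentile(vals, np.ones_like(vals), 75)
        assert got == pytest.approx(7500, rel=1e-3)

    def test_unequal_volumes_cumulative_rule(self):
        # 75% of the volume sits at value 1 -> threshold 1
        assert weighted_percentile([1.0, 2.0], [3.0, 1.0], 75) == pytest.approx(1.0)

    def test_matches_brute_force_replication(self):
        """Integer volumes: equals the unweighted percentile of replicated samples."""
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 10, 50)
        vols = rng.integers(1, 6, 50).astype(float)
        expanded = np.repeat(vals, vols.astype(int))
        for q in (25, 50, 75, 90):
            got = weighted_percentile(vals, vols, q)
            ref = np.quantile(expanded, q / 100)
            spacing = np.diff(np.sort(expanded)).max()
            assert abs(got - ref) <= spacing

    def test_lognormal_quantile_recovery(self):
        """n = 1e5 equal-volume lognormal samples: 75th percentile within a
        3-sigma Monte Carlo band of the analytic quantile."""
        mu, sigma, n = 0.3, 0.8, 100_000
        rng = np.random.default_rng(42)
        vals = rng.lognormal(mu, sigma, n)
        got = weighted_percentile(vals, np.ones(n), 75)
        q = lognorm.ppf(0.75, s=sigma, scale=np.exp(mu))
        # asymptotic SE of the sample quantile: sqrt(p(1-p)/n)/f(q)
        se = np.sqrt(0.75 * 0.25 / n) / lognorm.pdf(q, s=sigma, scale=np.exp(mu))
        assert abs(got - q) < 3 * se

    def test_validation(self):
        with pytest.raises(ValueError):
            weighted_percentile([], [], 75)
        with pytest.raises(ValueError):
            weighted_percentile([1.0], [0.0], 75)
        with pytest.raises(ValueError):
            weighted_percentile([1.0], [1.0], 0)


class TestExceedanceAndAuc:
    def test_constant_sample_step(self):
        c = exceedance_curve([2.0, 2.0], [1.0, 3.0])
        assert c(1.9) == 1.0 and c(2.0) == 1.0 and c(2.01) == 0.0

    def test_counting_fractions(self):
        c = exceedance_curve([1, 2, 3, 4], np.ones(4))
        assert c(2.5) == pytest.approx(0.5)
        assert c(0.0) == 1.0
        assert c(99) == 0.0

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(8)
        c = exceedance_curve(rng.uniform(0, 5, 200), rng.uniform(0.1, 2, 200))
        grid = np.linspace(-1, 6, 500)
        S = c(grid)
        assert np.all(np.diff(S) <= 1e-15)

    def test_auc_zero_equals_weighted_mean(self):
        """Exact identity E[X] = int_0^inf S(x) dx (rel 1e-10)."""
        rng = np.random.default_rng(12)
        vals = rng.gamma(2.0, 1.5, 500)
        vols = rng.uniform(0.1, 3.0, 500)
        assert auc(vals, vols, 0.0) == pytest.approx(np.average(vals, weights=vols), rel=1e-10)

    def test_auc_above_max_is_zero(self):
        assert auc([1.0, 2.0], [1.0, 1.0], 5.0) == 0.0

    def test_uniform_closed_form(self):
        """Uniform [0, a] at threshold 0.75a: AUC exposure (a-T)^2/2a over a/2
        = 6.25%, volume exposure 25%."""
        a = 4.0
        n = 200_000
        rng = np.random.default_rng(99)
        vals = rng.uniform(0, a, n)
        out = tissue_exposure(vals, np.ones(n), 0.75 * a)
        assert out["exposure_auc_pct"] == pytest.approx(6.25, abs=0.1)
        assert out["exposure_volume_pct"] == pytest.approx(25.0, abs=0.5)


class TestTissueExposure:
    def test_threshold_extremes(self):
        vals = np.array([1.0, 2.0, 3.0])
        vols = np.ones(3)
        assert tissue_exposure(vals, vols, 0.0)["exposure_auc_pct"] == pytest.approx(100.0)
        assert tissue_exposure(vals, vols, 10.0)["exposure_auc_pct"] == 0.0
        assert tissue_exposure(vals, vols, 10.0)["exposure_volume_pct"] == 0.0

    def test_fraction_above_own_75th_percentile(self):
        rng = np.random.default_rng(21)
        vals = rng.lognormal(0, 1, 40_000)
        vols = np.ones_like(vals)
        T = weighted_percentile(vals, vols, 75)
        out = tissue_exposure(vals, vols, T)
        assert out["exposure_volume_pct"] == pytest.approx(25.0, abs=0.5)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(31)
        vals = rng.gamma(3, 2, 1000)
        vols = rng.uniform(0.5, 1.5, 1000)
        base = tissue_exposure(vals, vols, 4.0)
        scaled = tissue_exposure(7.3 * vals, vols, 7.3 * 4.0)
        assert scaled["exposure_auc_pct"] == pytest.approx(base["exposure_auc_pct"], rel=1e-12)
        assert scaled["exposure_volume_pct"] == pytest.approx(base["exposure_volume_pct"], rel=1e-12)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(41)
        vals = rng.lognormal(0, 0.5, 2000)
        vols = np.ones_like(vals)
        grid = np.linspace(0, vals.max() * 1.1, 50)
        aucs = [tissue_exposure(vals, vols, t)["exposure_auc_pct"] for t in grid]
        fracs = [tissue_exposure(vals, vols, t)["exposure_volume_pct"] for t in grid]
        assert np.all(np.diff(aucs) <= 1e-12)
        assert np.all(np.diff(fracs) <= 1e-12)

    def test_zero_field_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            tissue_exposure(np.zeros(5), np.ones(5), 1.0)


class TestStrainBands:
    def test_pure_bands(self):
        assert strain_benchmark_flags([0.05] * 4, np.ones(4)) == pytest.approx(
            {"therapeutic_pct": 100.0, "damage_pct": 0.0}
        )
        assert strain_benchmark_flags([0.10] * 4, np.ones(4))["damage_pct"] == 100.0

    def test_counting(self):
        out = strain_benchmark_flags([0.02, 0.05, 0.10], np.ones(3))
        assert out["therapeutic_pct"] == pytest.approx(100 / 3)
        assert out["damage_pct"] == pytest.approx(100 / 3)


class TestReferenceThresholds:
    def test_table_shape_and_roundtrip(self, tmp_path):
        spec = SyntheticFieldSpec(
            layers={lay: ("lognormal", (0.0, 0.5), 10.0) for lay in ("epidermis", "dermis", "adipose", "muscle")},
            n=500,
            seed=3,
        )
        tables = {p: generate_field(spec) for p in (2.0, 6.0, 8.0, 10.0)}
        thr = reference_thresholds(tables)
        assert len(thr) == 4 * 4 * 2  # tissues x pressures x quantities
        assert (thr["threshold"] >= 0).all()
        path = tmp_path / "thr.json"
        thresholds_to_json(thr, path)
        back = thresholds_from_json(path)
        assert np.allclose(back["threshold"], thr["threshold"])

    def test_missing_layer_detected(self):
        spec = SyntheticFieldSpec(layers={"dermis": ("uniform", (0, 1), 1.0)}, n=50, seed=0)
        with pytest.raises(ValueError, match="no ROI elements"):
            reference_thresholds({10.0: generate_field(spec)})


class TestThresholdPressureMonotonicity:
    def test_thresholds_non_decreasing_with_pressure(self, mini_study):
        """Higher pressure -> higher per-tissue 75th-percentile thresholds."""
        tables = {p: mini_study["tables"][("model1", p, 1.0)] for p in (2.0, 8.0, 10.0)}
        thr = reference_thresholds(tables)
        for (tissue, quantity), grp in thr.groupby(["tissue", "quantity"]):
            vals = grp.sort_values("pressure_kPa")["threshold"].to_numpy()
            assert np.all(np.diff(vals) >= -1e-12), (tissue, quantity, vals)


class TestEndToEndSynthetic:
    def test_two_cohort_recovery(self):
        """The pipeline recovers the designed deep-layer exposure shift of a
        synthetic two-cohort contrast within Monte-Carlo error."""
        effect, seed, n, sigma = 1.3, 7, 20_000, 0.6
        a, b = two_cohort_fixture(effect, seed, n=n, sigma=sigma)
        sel_a = a[a.layer == "muscle"]
        sel_b = b[b.layer == "muscle"]
        T = weighted_percentile(sel_a.eps_eff, sel_a.volume_mm3, 75)
        out = tissue_exposure(sel_b.eps_eff, sel_b.volume_mm3, T)
        expected = 100 * lognormal_exceedance(np.log(0.10) + np.log(effect), sigma, T)
        se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
        assert abs(out["exposure_volume_pct"] - expected) < 3 * se + 1.0

    def test_identical_cohorts_match(self):
        a, b = two_cohort_fixture(1.0, seed=11, n=20_000)
        for lay in ("adipose", "muscle"):
            sa, sb = a[a.layer == lay], b[b.layer == lay]
            T = weighted_percentile(sa.eps_eff, sa.volume_mm3, 75)
            ea = tissue_exposure(sa.eps_eff, sa.volume_mm3, T)["exposure_volume_pct"]
            eb = tissue_exposure(sb.eps_eff, sb.volume_mm3, T)["exposure_volume_pct"]
            assert abs(ea - eb) < 1.5  # ~3 sigma of 25% fraction at n=2e4

    def test_weaker_cohort_less_exposed(self):
        a, b = two_cohort_fixture(0.7, seed=13, n=10_000)
        sa, sb = a[a.layer == "adipose"], b[b.layer == "adipose"]
        T = weighted_percentile(sa.eps_eff, sa.volume_mm3, 75)
        assert (
            tissue_exposure(sb.eps_eff, sb.volume_mm3, T)["exposure_volume_pct"]
            <= tissue_exposure(sa.eps_eff, sa.volume_mm3, T)["exposure_volume_pct"]
        )
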