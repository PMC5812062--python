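import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from holoshear import (
    build_psd,
    concentration_by_aspect,
    concentration_profile,
    fit_junge,
    fit_junge_segments,
    orientation_pdf,
    subsample_cast,
)
from holoshear.jeffery import analytic_bin_probabilities
from holoshear.synthetic import jeffery_angle_quantile, sample_junge_diameters


class TestSubsampling:
    def test_downcast_every_third(self):
        assert subsample_cast(list(range(1, 10)), "down") == [1, 4, 7]

    def test_upcast_every_second(self):
        assert subsample_cast(list(range(1, 7)), "up") == [1, 3, 5]

    def test_stride_exceeds_field_of_view(self):
        """At 15 Hz and 5-6 cm/s descent the platform moves 3.3-4.0 mm per
        frame, so every third frame moves 9.9-12 mm > the 9.4 mm FOV."""
        for w in (0.05, 0.06):
            per_frame = w / 15.0
            assert 3.3e-3 <= per_frame <= 4.0e-3
            assert 3 * per_frame > 9.4e-3


class TestConcentration:
    def test_defining_formula(self):
        """100 particles over 10 holograms in one bin at V = 3.53 mL gives
        Pv = 2.83 per mL."""
        particles = pd.DataFrame({"depth_m": np.full(100, 5.1)})
        prof = concentration_profile(particles, np.full(10, 5.1))
        assert len(prof) == 1
        assert prof["pv_per_ml"][0] == pytest.approx(100 / (10 * 3.53), rel=1e-9)

    def test_uniform_scene_recovers_flat_profile(self):
        """A synthetic cast with constant per-hologram counts recovers the
        generating concentration in every bin."""
        rng = np.random.default_rng(0)
        depths = np.repeat(np.arange(0.1, 10.0, 0.05), 1)  # one hologram per 5 cm
        counts = rng.poisson(20.0 * 3.53, depths.size)
        particles = pd.DataFrame({"depth_m": np.repeat(depths, counts)})
        prof = concentration_profile(particles, depths)
        assert prof["pv_per_ml"].mean() == pytest.approx(20.0, rel=0.05)
        assert prof["pv_per_ml"].std() < 3.0

    def test_bins_without_holograms_omitted(self):
        particles = pd.DataFrame({"depth_m": [5.1]})
        prof = concentration_profile(particles, np.array([5.1]))
        assert prof["depth_m"].to_numpy() == pytest.approx([5.1])

    def test_subsampling_preserves_concentration_in_expectation(self):
        """Stride-3 subsampling changes n and P proportionally, leaving Pv
        unbiased on a synthetic cast."""
        rng = np.random.default_rng(1)
        depths = np.arange(0.0, 20.0, 0.004)  # dense hologram train
        counts = rng.poisson(15.0 * 3.53, depths.size)
        full = concentration_profile(
            pd.DataFrame({"depth_m": np.repeat(depths, counts)}), depths
        )
        sub_d = depths[::3]
        sub_c = counts[::3]
        sub = concentration_profile(
            pd.DataFrame({"depth_m": np.repeat(sub_d, sub_c)}), sub_d
        )
        assert sub["pv_per_ml"].mean() == pytest.approx(full["pv_per_ml"].mean(), rel=0.02)


class TestAspectBreakdown:
    def test_single_bin_holds_all_mass(self):
        particles = pd.DataFrame(
            {"depth_m": np.full(40, 1.1), "aspect_ratio": np.repeat([2.0, 4.0, 8.0, 12.0], 10)}
        )
        out = concentration_by_aspect(particles)
        for col in ("r_1_3", "r_3_6", "r_6_10", "r_gt_10"):
            assert out[col].sum() == pytest.approx(100.0)

    def test_columns_sum_to_100(self):
        rng = np.random.default_rng(2)
        particles = pd.DataFrame(
            {
                "depth_m": rng.uniform(0, 10, 5000),
                "aspect_ratio": np.exp(rng.uniform(0, np.log(20), 5000)),
            }
        )
        out = concentration_by_aspect(particles)
        for col in out.columns[1:]:
            assert out[col].sum() == pytest.approx(100.0)

    def test_layered_chains_concentrate_in_upper_bins(self):
        """Long chains placed only in the upper layer dominate the r>10
        column there."""
        upper = pd.DataFrame({"depth_m": np.random.default_rng(3).uniform(0, 2, 200),
                              "aspect_ratio": np.full(200, 15.0)})
        lower = pd.DataFrame({"depth_m": np.random.default_rng(4).uniform(2, 10, 800),
                              "aspect_ratio": np.full(800, 2.0)})
        out = concentration_by_aspect(pd.concat([upper, lower]), bin_height=2.0)
        assert out.loc[out["depth_m"] < 2.0, "r_gt_10"].sum() == pytest.approx(100.0)

    def test_empty_class_flagged(self):
        particles = pd.DataFrame({"depth_m": [1.0], "aspect_ratio": [2.0]})
        out = concentration_by_aspect(particles)
        assert "r_gt_10" in out.attrs["empty_classes"]


class TestSizeDistributions:
    def test_single_particle_density(self):
        """One particle in 1 L divided by its bin width."""
        psd = build_psd(np.array([100.0]), volume_sampled_l=1.0)
        k = np.searchsorted(psd.bin_edges_um, 100.0) - 1
        assert psd.density[k] == pytest.approx(1.0 / psd.bin_widths_um[k])
        assert psd.counts.sum() == 1

    def test_doubling_volume_halves_density(self):
        rng = np.random.default_rng(5)
        d = rng.uniform(20, 900, 1000)
        a = build_psd(d, 1.0)
        b = build_psd(d, 2.0)
        assert np.allclose(b.density, a.density / 2.0)

    def test_out_of_range_particles_logged(self):
        psd = build_psd(np.array([5.0, 100.0, 2000.0]), 1.0)
        assert psd.n_excluded == 2

    @pytest.mark.parametrize("gamma", [0.5, 1.8, 3.0, 5.9, 7.0])
    def test_fit_exact_on_noiseless_power_law(self, gamma):
        """Densities placed exactly on n(D) = D^-gamma return gamma to
        machine precision."""
        edges = np.logspace(np.log10(11.6), 3.0, 25)
        centers = np.sqrt(edges[:-1] * edges[1:])
        from holoshear.stats import SizeDistribution

        psd = SizeDistribution(
            bin_edges_um=edges,
            density=centers**-gamma,
            counts=np.ones(24, dtype=int),
            volume_l=1.0,
            n_excluded=0,
        )
        assert fit_junge(psd).gamma == pytest.approx(gamma, abs=1e-12)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(0)
        d = sample_junge_diameters(rng, 50_000, 1.8, (11.6e-6, 1000e-6)) * 1e6
        assert fit_junge(build_psd(d, 1.0)).gamma == pytest.approx(1.8, abs=0.05)

    def test_two_segment_recovery(self):
        """Segmented fits recover both the shallow small-particle slope and
        the steep large-particle slope around a 250 um knee."""
        rng = np.random.default_rng(1)
        lo = sample_junge_diameters(rng, 50_000, 1.8, (11.6e-6, 250e-6)) * 1e6
        hi = sample_junge_diameters(rng, 50_000, 5.9, (250e-6, 1000e-6)) * 1e6
        # slopes are amplitude-free, so each segment is sampled at its own
        # statistical weight and fitted over its own size range
        f_lo = fit_junge(build_psd(lo, 1.0, d_range=(11.6, 250.0)))
        f_hi = fit_junge(build_psd(hi, 1.0, d_range=(250.0, 1000.0)))
        assert f_lo.gamma == pytest.approx(1.8, abs=0.1)
        assert f_hi.gamma == pytest.approx(5.9, abs=0.1)

    def test_two_segment_fit_exact_on_piecewise_density(self):
        """fit_junge_segments recovers both slopes exactly from a noiseless
        piecewise power law with a knee at 250 um."""
        from holoshear.stats import SizeDistribution

        edges = np.logspace(np.log10(11.6), 3.0, 31)
        centers = np.sqrt(edges[:-1] * edges[1:])
        dens = np.where(centers < 250.0, centers**-1.8,
                        250.0 ** (5.9 - 1.8) * centers**-5.9)
        psd = SizeDistribution(bin_edges_um=edges, density=dens,
                               counts=np.ones(30, dtype=int), volume_l=1.0, n_excluded=0)
        f_lo, f_hi = fit_junge_segments(psd, knee_um=250.0)
        assert f_lo.gamma == pytest.approx(1.8, abs=0.02)
        assert f_hi.gamma == pytest.approx(5.9, abs=0.02)

    def test_insufficient_bins_yield_no_fit(self):
        psd = build_psd(np.array([100.0, 101.0]), 1.0)
        assert fit_junge(psd, (90.0, 110.0)) is None


class TestOrientationPDFs:
    @staticmethod
    def _table(theta, depth=None, aspect=10.0):
        n = len(theta)
        return pd.DataFrame(
            {
                "theta_deg": theta,
                "depth_m": np.full(n, 1.0) if depth is None else depth,
                "aspect_ratio": np.full(n, aspect),
            }
        )

    def test_uniform_sample_gives_flat_density(self):
        rng = np.random.default_rng(0)
        out = orientation_pdf(self._table(rng.uniform(-89.99, 90.0, 200_000)))
        assert np.allclose(out["pdf_per_deg"], 1 / 180.0, atol=3e-4)

    def test_delta_sample_fills_single_bin(self):
        out = orientation_pdf(self._table(np.zeros(50)))
        pdf = out.set_index("angle_bin_center_deg")["pdf_per_deg"]
        assert pdf[0.0] == pytest.approx(1 / 20.0)
        assert pdf.drop(0.0).abs().max() == 0.0

    def test_every_depth_bin_normalises_to_one(self):
        rng = np.random.default_rng(1)
        out = orientation_pdf(
            self._table(rng.uniform(-90, 90, 5000), depth=rng.uniform(0, 12, 5000))
        )
        sums = out.groupby("depth_bin_m")["pdf_per_deg"].sum() * 20.0
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_aspect_ratio_filter(self):
        mixed = pd.DataFrame(
            {
                "theta_deg": [0.0, 0.0, 50.0],
                "depth_m": [1.0, 1.0, 1.0],
                "aspect_ratio": [2.0, 10.0, 10.0],
            }
        )
        out = orientation_pdf(mixed, r_min=3.0)
        assert out["count"].sum() == 2  # the r = 2 particle is excluded

    def test_low_count_bins_flagged(self):
        out = orientation_pdf(self._table(np.zeros(10)), low_count_threshold=30)
        assert out["low_count_flag"].all()

    def test_jeffery_population_matches_model_pdf(self):
        """Angles drawn from the laminar-shear occupancy law and histogrammed
        by orientation_pdf agree with the closed-form model (chi-squared
        test at alpha = 0.01 across seeds)."""
        r = 6.0
        expected_p = analytic_bin_probabilities(r)
        passes = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            theta = jeffery_angle_quantile(rng.random(5000), r)
            out = orientation_pdf(self._table(theta))
            counts = out["count"].to_numpy()
            chi2 = ((counts - 5000 * expected_p) ** 2 / (5000 * expected_p)).sum()
            if chi2 < sps.chi2.ppf(0.99, df=8):
                passes += 1
        assert passes >= 8
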