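"""Profile estimators: radial profiles, ring fits, FWHM, peak-to-peak,
normalization and expansion-correction arithmetic."""

import numpy as np
import pytest

from trexmetrics.exceptions import (
    DomainError,
    NoPairError,
    NoRingError,
    UndefinedWidthError,
)
from trexmetrics.profiles import (
    GAUSSIAN_FWHM_FACTOR,
    ExpansionContext,
    LineProfile,
    correct_for_expansion,
    fit_ring_radius,
    fwhm,
    local_expansion_factor,
    peak_normalize,
    peak_to_peak,
    radial_profile,
    ring_diameters,
)
from trexmetrics.synthetic import gen_profile, gen_ring_image


class TestRadialProfile:
    def test_uniform_image_gives_flat_profile(self):
        img = np.full((41, 41), 7.5)
        prof = radial_profile(img, (20, 20), 15)
        assert np.allclose(prof.mean_intensity[prof.counts > 0], 7.5)

    def test_single_bright_pixel_lands_in_its_annulus(self):
        img = np.zeros((41, 41))
        img[20, 30] = 100.0          # distance 10 from center
        prof = radial_profile(img, (20, 20), 15)
        nz = np.flatnonzero(np.nan_to_num(prof.mean_intensity) > 0)
        assert list(nz) == [10]

    def test_ring_image_profile_peaks_at_ring_radius(self):
        img, _ = gen_ring_image(shape_px=(128, 128), centers_px=[(64, 64)],
                                ring_radius_px=50, shell_sigma_px=3, seed=0)
        prof = radial_profile(img, (64, 64), 60)
        assert abs(int(np.nanargmax(prof.mean_intensity)) - 50) <= 1

    def test_total_intensity_is_conserved(self, rng):
        img = rng.uniform(0, 100, (64, 64))
        r_max = 20
        prof = radial_profile(img, (31.5, 30.2), r_max)
        total = np.nansum(prof.mean_intensity * prof.counts)
        yy, xx = np.indices(img.shape)
        r = np.hypot(xx - 31.5, yy - 30.2)
        expected = img[np.rint(r) <= r_max].sum()
        assert total == pytest.approx(expected, rel=1e-12)

    def test_center_outside_image_rejected(self):
        with pytest.raises(DomainError):
            radial_profile(np.zeros((10, 10)), (20, 5), 5)


class TestFitRingRadius:
    def test_noiseless_shell_radius(self):
        img, _ = gen_ring_image(shape_px=(128, 128), centers_px=[(64, 64)],
                                ring_radius_px=50, shell_sigma_px=3, seed=0)
        prof = radial_profile(img, (64, 64), 60)
        fit = fit_ring_radius(prof)
        assert fit.converged
        # shell-centroid oracle: intensity-weighted mean radius over window
        lo, hi = fit.window
        y = prof.mean_intensity[lo:hi + 1] - fit.offset
        oracle = float(np.sum(prof.radii_px[lo:hi + 1] * y) / np.sum(y))
        assert fit.radius_px == pytest.approx(oracle, abs=0.25)
        assert fit.radius_px == pytest.approx(50.0, abs=0.1)

    def test_invariant_to_affine_intensity_rescaling(self):
        img, _ = gen_ring_image(ring_radius_px=40, shell_sigma_px=4, seed=3)
        prof1 = radial_profile(img, (64, 64), 60)
        prof2 = radial_profile(3.7 * img + 120.0, (64, 64), 60)
        f1, f2 = fit_ring_radius(prof1), fit_ring_radius(prof2)
        assert f1.radius_px == pytest.approx(f2.radius_px, abs=1e-6)

    def test_flat_profile_raises_no_ring(self):
        img = np.full((64, 64), 5.0)
        prof = radial_profile(img, (32, 32), 20)
        with pytest.raises(NoRingError):
            fit_ring_radius(prof)

    def test_ring_recovery_bias_under_noise(self):
        # 100 seeded noisy rings at SNR 5: mean bias below 2%
        truth_r = 38.5
        radii = []
        for s in range(100):
            img, _ = gen_ring_image(shape_px=(101, 101), centers_px=[(50, 50)],
                                    ring_radius_px=truth_r, shell_sigma_px=5,
                                    amplitude=500.0, background=50.0,
                                    noise_sd=100.0, seed=s)
            prof = radial_profile(img, (50, 50), 49)
            fit = fit_ring_radius(prof)
            if fit.converged:
                radii.append(fit.radius_px)
        assert len(radii) >= 95
        bias = abs(np.mean(radii) - truth_r) / truth_r
        assert bias < 0.02


class TestRingDiameters:
    def test_batch_mean_matches_expanded_npc_size(self):
        # rings at the 107 nm reference scaled 9.5x: diameter 1.0165 um
        pixel_nm = 13.2
        truth_d_nm = 107.0 * 9.5
        r_px = truth_d_nm / 2 / pixel_nm
        centers = [(50.0 + 105 * i, 50.0 + 105 * j)
                   for i in range(4) for j in range(4)]
        img, _ = gen_ring_image(shape_px=(420, 420), pixel_size_nm=pixel_nm,
                                centers_px=centers, ring_radius_px=r_px,
                                shell_sigma_px=4.0, noise_sd=0.0, seed=0)
        table, summary = ring_diameters(img, np.array(centers), pixel_nm)
        assert summary["n_converged"] == len(centers)
        assert summary["mean_diameter_nm"] == pytest.approx(truth_d_nm, rel=0.01)

    def test_duplicate_centers_give_identical_fits(self):
        img, _ = gen_ring_image(ring_radius_px=40, shell_sigma_px=4, seed=1)
        table, _ = ring_diameters(img, np.array([(64, 64), (64, 64)]), 10.0,
                                  r_max_px=60)
        assert table.loc[0, "diameter_nm"] == table.loc[1, "diameter_nm"]

    def test_background_centers_counted_as_failures(self):
        img = np.zeros((256, 256))
        img[:128] = 0.0
        ring, _ = gen_ring_image(shape_px=(128, 128), centers_px=[(64, 64)],
                                 ring_radius_px=30, shell_sigma_px=3, seed=0)
        img[:128, :128] = ring
        table, summary = ring_diameters(
            img, np.array([(64.0, 64.0), (200.0, 200.0)]), 10.0, r_max_px=45)
        assert summary["n_converged"] == 1
        assert summary["n_failed"] == 1
        assert summary["mean_diameter_nm"] == pytest.approx(600.0, rel=0.01)

    def test_empty_center_list_rejected(self):
        with pytest.raises(DomainError):
            ring_diameters(np.zeros((64, 64)), np.empty((0, 2)), 10.0)


class TestFwhm:
    def test_gaussian_closed_form(self):
        profile, _ = gen_profile("gaussian", {"sigma_nm": 100.0},
                                 n_samples=201, spacing_nm=10.0, seed=0)
        m = fwhm(profile)
        assert m.fwhm == pytest.approx(GAUSSIAN_FWHM_FACTOR * 100.0,
                                       abs=0.5 * profile.spacing)

    def test_boxcar_width(self):
        profile, _ = gen_profile("plateau", {"width_nm": 200.0},
                                 n_samples=101, spacing_nm=10.0, seed=0)
        m = fwhm(profile)
        assert m.fwhm == pytest.approx(200.0, abs=profile.spacing)

    def test_noisy_gaussian_matches_oversampled_oracle(self):
        profile, _ = gen_profile("gaussian",
                                 {"sigma_nm": 100.0, "amplitude": 1.0},
                                 n_samples=201, spacing_nm=10.0,
                                 noise_sd=0.05, seed=42)
        m = fwhm(profile)
        # oracle: numerical FWHM on a 100x oversampled interpolation
        x, y = profile.positions, profile.intensities
        xf = np.linspace(x[0], x[-1], 100 * len(x))
        yf = np.interp(xf, x, y)
        n_edge = max(1, int(round(0.1 * len(y))))
        base = float(np.mean(np.concatenate([y[:n_edge], y[-n_edge:]])))
        half = base + 0.5 * (yf.max() - base)
        above = np.flatnonzero(yf >= half)
        oracle = xf[above[-1]] - xf[above[0]]
        assert m.fwhm == pytest.approx(oracle, abs=2 * profile.spacing)

    def test_boundary_peak_rejected(self):
        profile = LineProfile(positions=np.arange(10.0),
                              intensities=np.arange(10.0))
        with pytest.raises(UndefinedWidthError):
            fwhm(profile)


class TestPeakToPeak:
    def test_two_gaussian_separation(self):
        profile, _ = gen_profile("two_peak",
                                 {"separation_nm": 450.0, "sigma_nm": 40.0},
                                 n_samples=201, spacing_nm=10.0, seed=0)
        m = peak_to_peak(profile)
        assert m.peak_to_peak == pytest.approx(450.0, abs=profile.spacing)
        assert m.n_peaks == 2

    def test_single_gaussian_raises_no_pair(self):
        profile, _ = gen_profile("gaussian", {"sigma_nm": 50.0}, seed=0)
        with pytest.raises(NoPairError):
            peak_to_peak(profile)

    def test_noisy_central_null_pit_profile(self):
        profile, truth = gen_profile("two_peak",
                                     {"separation_nm": 450.0, "sigma_nm": 40.0,
                                      "amplitude": 1.0},
                                     n_samples=201, spacing_nm=10.0,
                                     noise_sd=0.03, seed=11)
        m = peak_to_peak(profile)
        sep = float(truth.truth_records.loc[0, "separation_nm"])
        assert m.peak_to_peak == pytest.approx(sep, abs=2 * profile.spacing)


class TestPeakNormalize:
    def test_normalizes_and_is_idempotent(self):
        profile, _ = gen_profile("gaussian", {"sigma_nm": 50.0,
                                              "amplitude": 200.0}, seed=0)
        norm = peak_normalize(profile)
        assert norm.intensities.max() == pytest.approx(1.0)
        again = peak_normalize(norm)
        assert np.allclose(again.intensities, norm.intensities)

    def test_gain_invariance(self):
        profile, _ = gen_profile("gaussian", {"sigma_nm": 50.0}, seed=0)
        a = peak_normalize(LineProfile(profile.positions,
                                       3.0 * profile.intensities))
        b = peak_normalize(LineProfile(profile.positions,
                                       11.0 * profile.intensities))
        assert np.allclose(a.intensities, b.intensities)

    def test_metrics_invariant_under_normalization(self):
        profile, _ = gen_profile("two_peak",
                                 {"separation_nm": 450.0, "sigma_nm": 40.0,
                                  "amplitude": 7.0, "background": 0.5},
                                 seed=0)
        before = peak_to_peak(profile).peak_to_peak
        after = peak_to_peak(peak_normalize(profile)).peak_to_peak
        assert before == pytest.approx(after, abs=1e-9)
        g, _ = gen_profile("gaussian", {"sigma_nm": 80.0, "amplitude": 5.0},
                           seed=0)
        assert fwhm(g).fwhm == pytest.approx(fwhm(peak_normalize(g)).fwhm,
                                             abs=1e-6)

    def test_all_zero_profile_rejected(self):
        profile = LineProfile(np.arange(10.0), np.zeros(10))
        with pytest.raises(DomainError):
            peak_normalize(profile)


class TestExpansionArithmetic:
    def test_correction_to_pre_expansion_dimensions(self):
        ctx = ExpansionContext(expansion_factor=10.0, reference_size_nm=100.0)
        assert correct_for_expansion(1.08, ctx) == pytest.approx(0.108)
        assert correct_for_expansion(1.16, ctx) == pytest.approx(0.116)
        ident = ExpansionContext(expansion_factor=1.0)
        assert correct_for_expansion(3.14, ident) == pytest.approx(3.14)

    def test_correction_round_trip(self):
        ctx = ExpansionContext(expansion_factor=9.5)
        assert correct_for_expansion(0.5 * 9.5, ctx) == pytest.approx(0.5)

    def test_local_expansion_factor_of_npc_rings(self):
        ctx = ExpansionContext(expansion_factor=9.5, reference_size_nm=107.0)
        factor, percent = local_expansion_factor(939.0, ctx)
        assert round(factor, 1) == 8.8
        assert round(percent) == 92

    def test_exact_expansion_gives_100_percent(self):
        ctx = ExpansionContext(expansion_factor=9.5, reference_size_nm=107.0)
        _, percent = local_expansion_factor(107.0 * 9.5, ctx)
        assert percent == pytest.approx(100.0)
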