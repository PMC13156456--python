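import numpy as np
import pytest

from hp_lvpool.cohort_stats import pearson
from hp_lvpool.exponential_model import fit_exponential, sort_roi
from hp_lvpool.phantom import (PhantomSpec, make_cohort, make_study,
                               measure_delivery_metric, read_study,
                               write_study)
from hp_lvpool.preprocess import flip_angle_correct, sum_pyruvate


def small_cohort_spec(grid=48):
    return PhantomSpec(grid_size=grid, lv_center=(grid / 2.0, grid / 2.0))


class TestSpecValidation:
    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            PhantomSpec(grid_size=8)
        with pytest.raises(ValueError):
            PhantomSpec(planted_B=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(n_pyr_frames=44, n_met_frames=20)

    def test_ellipse_outside_grid_rejected(self):
        spec = PhantomSpec(grid_size=24, lv_center=(4.0, 12.0),
                           endo_radii=(8.6, 8.4))
        with pytest.raises(ValueError, match="does not fit"):
            make_study(spec)


class TestMakeStudy:
    def test_noiseless_profile_exactly_exponential(self, noiseless_study,
                                                   small_spec):
        pyr = flip_angle_correct(noiseless_study.pyruvate)
        profile = sort_roi(sum_pyruvate(pyr), noiseless_study.masks.endo)
        n = profile.n
        expected = small_spec.planted_Imax * np.exp(
            -small_spec.planted_B * np.arange(n))
        np.testing.assert_allclose(profile.values, expected, rtol=1e-9)
        fit = fit_exponential(profile)
        assert abs(fit.b_value - small_spec.planted_B) \
            <= 1e-8 * small_spec.planted_B
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_brighter_voxels_nearer_center(self, noiseless_study, small_spec):
        sum_img = sum_pyruvate(noiseless_study.pyruvate)
        rr, cc = np.nonzero(noiseless_study.masks.endo)
        d = np.hypot(rr - small_spec.lv_center[0], cc - small_spec.lv_center[1])
        vals = sum_img[rr, cc]
        assert pearson(d, vals) < -0.9

    def test_b_regimes_qualitative(self):
        # steep / moderate / shallow sorted profiles at the three
        # representative (B, ROI-size) combinations: a larger B gives a
        # steeper profile and, at its ROI size, fewer voxels above the
        # 20% threshold
        cases = {0.0180: (8.0, 7.96), 0.0105: (8.95, 8.9),
                 0.0028: (9.05, 8.85)}  # ~200 / ~240 / ~250 voxels
        counts, slopes = {}, {}
        for b, radii in cases.items():
            spec = PhantomSpec(grid_size=64, lv_center=(32.0, 32.0),
                               endo_radii=radii, planted_B=b,
                               noise_sigma=0.0, seed=1)
            study = make_study(spec)
            pyr = flip_angle_correct(study.pyruvate)
            sum_img = sum_pyruvate(pyr)
            profile = sort_roi(sum_img, study.masks.endo)
            thr = 0.20 * profile.i_max + profile.i_min
            counts[b] = int((profile.values >= thr).sum())
            half = profile.n // 2
            slopes[b] = profile.values[0] / profile.values[half]
        assert counts[0.0180] < counts[0.0105] < counts[0.0028]
        assert slopes[0.0180] > slopes[0.0105] > slopes[0.0028]

    def test_pre_onset_frames_noise_only(self, noisy_study):
        t0 = noisy_study.truth["bolus"][0]
        baseline = noisy_study.pyruvate.frames[:int(t0)]
        sigma = noisy_study.truth["noise_sigma"]
        assert abs(baseline.mean()) < 5 * sigma / np.sqrt(baseline.size)
        # and the noiseless counterpart is exactly zero pre-onset
        clean = make_study(PhantomSpec(grid_size=64, lv_center=(32, 32),
                                       noise_sigma=0.0, seed=0))
        assert np.all(clean.pyruvate.frames[:8] == 0.0)

    def test_bolus_peak_frame_matches_gamma_argmax(self, noiseless_study):
        per_frame = noiseless_study.pyruvate.frames.sum(axis=(1, 2))
        t0, k, beta, _ = noiseless_study.truth["bolus"]
        t = np.linspace(t0 + 1e-6, 43, 20000)
        g = (t - t0) ** k * np.exp(-(t - t0) / beta)
        analytic_peak = t[np.argmax(g)]
        assert abs(np.argmax(per_frame) - analytic_peak) <= 1.0
        assert np.argmax(per_frame) == noiseless_study.truth[
            "bolus_peak_frame"]

    def test_metabolites_confined_to_myocardium(self, noisy_study):
        lac = noisy_study.lactate.frames
        sig = lac[18]  # past metabolite onset
        myo_mean = sig[noisy_study.masks.myo].mean()
        outside = sig[~noisy_study.masks.epic].mean()
        assert myo_mean > 10 * abs(outside)
        # metabolite baseline frames are noise-only
        sigma = noisy_study.truth["noise_sigma"]
        assert abs(lac[:14].mean()) < 5 * sigma / np.sqrt(lac[:14].size)

    def test_determinism(self):
        spec = PhantomSpec(grid_size=48, lv_center=(24, 24),
                           endo_radii=(7.0, 7.0), noise_sigma=0.3, seed=42)
        a = make_study(spec)
        b = make_study(spec)
        np.testing.assert_array_equal(a.pyruvate.frames, b.pyruvate.frames)
        np.testing.assert_array_equal(a.lactate.frames, b.lactate.frames)
        c = make_study(PhantomSpec(grid_size=48, lv_center=(24, 24),
                                   endo_radii=(7.0, 7.0), noise_sigma=0.3,
                                   seed=43))
        assert not np.array_equal(a.pyruvate.frames, c.pyruvate.frames)


class TestMakeCohort:
    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 4"):
            make_cohort(3, 13.0, -0.6, 0)
        with pytest.raises(ValueError, match="negative"):
            make_cohort(8, 13.0, 0.4, 0)
        with pytest.raises(ValueError, match="negative"):
            make_cohort(8, 13.0, 0.0, 0)

    def test_minimum_size_runs_end_to_end(self):
        studies, truth = make_cohort(4, 13.0, -0.6, 5,
                                     base_spec=small_cohort_spec())
        assert len(studies) == 4 and len(truth) == 4

    def test_determinism_elementwise(self):
        s1, t1 = make_cohort(5, 13.0, -0.6, 17,
                             base_spec=small_cohort_spec())
        s2, t2 = make_cohort(5, 13.0, -0.6, 17,
                             base_spec=small_cohort_spec())
        np.testing.assert_array_equal(s1[3].pyruvate.frames,
                                      s2[3].pyruvate.frames)
        assert t1.equals(t2)

    def test_planted_b_in_table_range(self):
        _, truth = make_cohort(30, 13.0, -0.6, 2,
                               base_spec=small_cohort_spec())
        assert truth.planted_B.between(0.0028, 0.0183).all()
        assert truth.n_roi.gt(0).all()

    def test_outcome_matches_measured_lacbic(self):
        from hp_lvpool.cli_io import analyze_study
        studies, truth = make_cohort(6, 13.0, -0.6, 8,
                                     base_spec=small_cohort_spec(64))
        for study, (_, row) in zip(studies, truth.iterrows()):
            m = analyze_study(study)
            assert m.lac_bic == pytest.approx(row.outcome, rel=0.05)

    def test_null_coupling_no_association(self):
        studies, truth = make_cohort(40, 13.0, -0.6, 3, null_coupling=True,
                                     base_spec=small_cohort_spec())
        r = pearson(truth.metric_alpha_star.to_numpy(),
                    truth.outcome.to_numpy())
        assert abs(r) < 0.1

    def test_window_width_grows_as_rho_shrinks(self):
        from hp_lvpool.cli_io import build_metrics_table
        from hp_lvpool.cohort_stats import sweep
        widths = {}
        for rho in (-0.8, -0.3):
            studies, _ = make_cohort(106, 13.0, rho, 5)
            tab = build_metrics_table(studies)
            res = sweep(tab[tab.model == "numfit"], "numfit")
            assert res.argmin_alpha == 13.0
            widths[rho] = res.optimal_window[1] - res.optimal_window[0]
        assert widths[-0.3] > widths[-0.8]

    def test_realized_correlation_iid_monte_carlo(self):
        # 50 replicate cohorts with plain i.i.d. outcome noise: the mean
        # realized correlation at alpha* stays within +-0.05 of the target
        rho = -0.6
        realized = []
        for rep in range(50):
            _, truth = make_cohort(106, 13.0, rho, 1000 + rep,
                                   base_spec=small_cohort_spec(),
                                   orthogonal_noise=False)
            realized.append(pearson(truth.metric_alpha_star.to_numpy(),
                                    truth.outcome.to_numpy()))
        assert abs(np.mean(realized) - rho) <= 0.05


class TestSerialization:
    def test_round_trip(self, tmp_path, noisy_study):
        write_study(noisy_study, tmp_path, "demo")
        back = read_study(tmp_path, "demo")
        np.testing.assert_allclose(back.pyruvate.frames,
                                   noisy_study.pyruvate.frames, rtol=1e-5,
                                   atol=1e-4)
        np.testing.assert_array_equal(back.masks.endo,
                                      noisy_study.masks.endo)
        assert back.truth["planted_B"] == noisy_study.truth["planted_B"]
        assert back.truth["bolus"] == noisy_study.truth["bolus"]
        assert back.pyruvate.flip_angle == 5.0
        assert back.lactate.frame_interval == 2

    def test_metric_measurement_stable_after_round_trip(self, tmp_path,
                                                        noisy_study):
        b0, p0, s0 = measure_delivery_metric(noisy_study, 13.0)
        write_study(noisy_study, tmp_path, "demo")
        b1, p1, s1 = measure_delivery_metric(read_study(tmp_path, "demo"),
                                             13.0)
        assert b1 == pytest.approx(b0, rel=1e-3)
        assert p1 == pytest.approx(p0, rel=1e-3)
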