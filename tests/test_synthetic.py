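"""Ground-truth properties of the synthetic acquisition generators."""

import numpy as np
import pytest

from fuskit.connectivity import correlation_matrix, extract_roi_timecourses
from fuskit.stimulus import build_protocol, percent_cbv
from fuskit.synthetic import (
    GroundTruth,
    PhantomSpec,
    default_phantom_spec,
    generate_compound_stack,
    generate_phantom,
    generate_resting_movie,
    generate_stimulation_movie,
    response_shape,
)


def _two_region_spec(overlap=False):
    layout = {
        "A": np.zeros((20, 20), bool),
        "B": np.zeros((20, 20), bool),
    }
    layout["A"][4:8, 4:8] = True
    layout["B"][10:14, 10:14] = True
    if overlap:
        layout["B"][7, 7] = True
    return PhantomSpec(grid_shape=(20, 20), region_layout=layout)


class TestPhantom:
    def test_two_disjoint_regions_give_two_labels(self):
        ph = generate_phantom(_two_region_spec(), seed=0)
        assert sorted(np.unique(ph.atlas.labels)) == [0, 1, 2]
        assert ph.atlas.region_names == ["A", "B"]
        # mask covers all region pixels and labels match the layout
        assert ph.mask[ph.atlas.labels > 0].all()
        assert np.array_equal(ph.atlas.region_mask("A"), _two_region_spec().region_layout["A"])

    def test_same_seed_bit_identical(self):
        spec = default_phantom_spec((32, 32))
        a = generate_phantom(spec, seed=3)
        b = generate_phantom(spec, seed=3)
        assert np.array_equal(a.baseline, b.baseline)
        assert np.array_equal(a.vessel_mask, b.vessel_mask)
        assert np.array_equal(a.atlas.labels, b.atlas.labels)

    def test_zero_vessel_density_gives_smooth_baseline(self):
        spec = default_phantom_spec((32, 32), vessel_density=0.0)
        ph = generate_phantom(spec, seed=5)
        assert np.array_equal(ph.baseline, ph.smooth_baseline)
        assert not ph.vessel_mask.any()

    def test_overlapping_regions_rejected_by_name(self):
        with pytest.raises(ValueError, match="'A' and 'B'"):
            generate_phantom(_two_region_spec(overlap=True), seed=0)

    def test_baseline_positive_inside_mask(self, phantom64):
        assert (phantom64.baseline[phantom64.mask] > 0).all()

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="16x16"):
            PhantomSpec(grid_shape=(8, 8), region_layout={})


class TestRestingMovie:
    def test_programmed_correlation_recovered(self, phantom64):
        truth = GroundTruth(
            programmed_correlations={("V1", "V2ML"): 0.7},
            noise_sd=0.01,
            fluct_amp=0.02,
            seed=3,
        )
        movie = generate_resting_movie(phantom64, truth, n_frames=450, dt=2.8)
        tcs = extract_roi_timecourses(movie, phantom64.atlas)
        cm = correlation_matrix(tcs, discard_initial=0.0)
        i = cm.roi_names.index("V1")
        j = cm.roi_names.index("V2ML")
        assert 0.60 <= cm.r[i, j] <= 0.80

    def test_noise_free_unit_correlation(self, phantom32):
        truth = GroundTruth(
            programmed_correlations={("V1", "V2ML"): 1.0}, noise_sd=0.0, seed=4
        )
        movie = generate_resting_movie(phantom32, truth, n_frames=128, dt=2.8)
        tcs = {t.roi_name: t.values for t in extract_roi_timecourses(movie, phantom32.atlas)}
        r = np.corrcoef(tcs["V1"], tcs["V2ML"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_null_correlations_stay_near_zero(self, phantom32):
        truth = GroundTruth(programmed_correlations={}, noise_sd=0.01, seed=9)
        movie = generate_resting_movie(phantom32, truth, n_frames=2048, dt=2.8)
        tcs = extract_roi_timecourses(movie, phantom32.atlas)
        cm = correlation_matrix(tcs, discard_initial=0.0)
        off = cm.r[np.triu_indices(len(cm.roi_names), k=1)]
        assert np.mean(np.abs(off)) < 0.1

    def test_infeasible_matrix_rejected_with_pair(self, phantom32):
        truth = GroundTruth(
            programmed_correlations={
                ("V1", "V2ML"): 0.9,
                ("V1", "SC"): 0.9,
                ("V2ML", "SC"): -0.9,
            },
            noise_sd=0.0,
            seed=0,
        )
        with pytest.raises(ValueError, match="positive semidefinite"):
            generate_resting_movie(phantom32, truth, n_frames=128, dt=2.8)

    def test_correlation_within_three_standard_errors(self, phantom64):
        """Sample r of the generated series matches the programmed value
        within 3 SE at the generated length."""
        target, n = 0.5, 400
        truth = GroundTruth(
            programmed_correlations={("CA1", "Thal"): target}, noise_sd=0.005, seed=21
        )
        movie = generate_resting_movie(phantom64, truth, n_frames=n, dt=2.8)
        tcs = {t.roi_name: t.values for t in extract_roi_timecourses(movie, phantom64.atlas)}
        r = np.corrcoef(tcs["CA1"], tcs["Thal"])[0, 1]
        se = (1 - target**2) / np.sqrt(n - 3)
        assert abs(r - target) < 3 * se

    def test_multiplicative_model_reconstruction(self, phantom32):
        """Movie decomposes exactly as baseline * (1 + fluctuation)."""
        truth = GroundTruth(noise_sd=0.01, seed=2)
        movie = generate_resting_movie(phantom32, truth, n_frames=64, dt=2.8)
        fluct = movie.data / phantom32.baseline[None] - 1.0
        recon = phantom32.baseline[None] * (1.0 + fluct)
        assert np.allclose(recon, movie.data, rtol=1e-12)
        # fluctuations are zero outside the brain mask
        assert np.abs(fluct[:, ~phantom32.mask]).max() < 1e-12

    def test_fixed_seed_bit_identical(self, phantom32):
        truth = GroundTruth(programmed_correlations={("V1", "SC"): 0.4}, seed=8)
        a = generate_resting_movie(phantom32, truth, n_frames=96, dt=2.8)
        b = generate_resting_movie(phantom32, truth, n_frames=96, dt=2.8)
        assert np.array_equal(a.data, b.data)


class TestStimulationMovie:
    def test_sustained_amplitude_exact_after_normalization(self, phantom32, short_protocol):
        truth = GroundTruth(
            programmed_response={"V1": (4.0, "sustained")}, noise_sd=0.0, seed=0
        )
        movie, gt = generate_stimulation_movie(phantom32, truth, short_protocol)
        roi = phantom32.atlas.region_mask("V1")
        series = movie.data[:, roi].mean(axis=1)
        pct = percent_cbv(series, short_protocol)
        assert pct[short_protocol.stim_mask()].mean() == pytest.approx(4.0, abs=1e-9)
        assert gt["V1"]["stim_mean_pct"] == pytest.approx(4.0)

    def test_initial_peak_ground_truth_tmax(self, phantom32):
        protocol = build_protocol(10, 30, 20, 2, 0.4)
        truth = GroundTruth(
            programmed_response={"SC": (2.0, "initial-peak")},
            peak_time=6.0,
            noise_sd=0.0,
            seed=0,
        )
        _, gt = generate_stimulation_movie(phantom32, truth, protocol)
        assert gt["SC"]["tmax_s"] == pytest.approx(6.0, abs=protocol.dt / 2)

    def test_late_peak_after_offset(self, phantom32):
        protocol = build_protocol(10, 30, 25, 2, 0.4)
        truth = GroundTruth(
            programmed_response={"SC": (2.0, "late-peak")},
            late_peak_delay=5.0,
            noise_sd=0.0,
            seed=0,
        )
        _, gt = generate_stimulation_movie(phantom32, truth, protocol)
        assert gt["SC"]["tmax_s"] == pytest.approx(35.0, abs=protocol.dt / 2 + 1e-9)

    def test_unknown_region_rejected(self, phantom32, short_protocol):
        truth = GroundTruth(programmed_response={"nonexistent": (1.0, "sustained")})
        with pytest.raises(ValueError, match="nonexistent"):
            generate_stimulation_movie(phantom32, truth, short_protocol)

    def test_response_shapes_unit_peak(self):
        t = np.linspace(0, 60, 1201)
        for kind in ("initial-peak", "late-peak", "sustained"):
            s = response_shape(kind, t, stim_duration=30.0)
            assert s.max() == pytest.approx(1.0, abs=1e-3)
        assert response_shape("none", t, 30.0).max() == 0.0


class TestCompoundStack:
    def test_zero_blood_gives_zero_truth(self, phantom32):
        stack, blood_power = generate_compound_stack(phantom32, 64, 500.0, blood_amp=0.0, seed=1)
        assert np.all(blood_power == 0)

    def test_stack_duration_matches_acquisition(self, phantom32):
        stack, _ = generate_compound_stack(phantom32, 200, 500.0, seed=1)
        assert stack.duration == pytest.approx(0.4)

    def test_tissue_only_stack_is_rank_one(self, phantom32):
        stack, _ = generate_compound_stack(phantom32, 64, 500.0, blood_amp=0.0, seed=1)
        s = np.linalg.svd(stack.casorati(), compute_uv=False)
        assert s[1] / s[0] < 1e-12

    def test_bad_frame_rate_rejected(self, phantom32):
        with pytest.raises(ValueError, match="frame_rate"):
            generate_compound_stack(phantom32, 64, 0.0, seed=1)
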