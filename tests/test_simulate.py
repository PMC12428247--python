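"""Generator contracts: mixture calibration, waveform, cohorts, image stacks."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from catrace.errors import InfeasiblePresetError, LayoutError, ValidationError
from catrace.extraction import extract_roi_traces, normalize, process_cohort
from catrace.io import traces_to_frame
from catrace.kinetics import extract_cell_metrics, max_rmr
from catrace.simulate import (
    CohortPreset,
    KineticShape,
    StackLayout,
    calibrate_mixture,
    fold_profile,
    generate_cohort,
    generate_image_stack,
    generate_trace,
)


def _preset(**kw):
    base = dict(
        group="ASD",
        stage="Diff1wk",
        stimulus="ATP",
        mu_peak=1.58,
        mu_ttp=57.0,
        responder_frac=0.1363,
        mu_iono_peak=2.73,
        mu_iono_ttp=81.69,
    )
    base.update(kw)
    return CohortPreset(**base)


class TestCalibrateMixture:
    def test_closed_form_solution(self):
        preset = _preset()
        r_mu, nr_mu = calibrate_mixture(preset, threshold=2.0)
        expected = (1.58 - (1 - 0.1363) * 1.3) / 0.1363
        assert r_mu == pytest.approx(expected, abs=1e-12)
        # mixture mean identity holds exactly
        mix = 0.1363 * r_mu + (1 - 0.1363) * nr_mu
        assert mix == pytest.approx(1.58, abs=1e-12)

    def test_degenerate_all_responders(self):
        preset = _preset(responder_frac=1.0, mu_peak=4.23)
        r_mu, _ = calibrate_mixture(preset)
        assert r_mu == 4.23

    def test_inconsistent_mean_and_fraction_rejected(self):
        preset = _preset(mu_peak=1.2, responder_frac=0.9)
        with pytest.raises(InfeasiblePresetError):
            calibrate_mixture(preset, threshold=2.0)

    @given(
        mu=st.floats(2.1, 5.0),
        f=st.floats(0.2, 1.0),
        nr=st.floats(1.0, 1.9),
    )
    def test_mixture_mean_identity_property(self, mu, f, nr):
        preset = _preset(mu_peak=mu, responder_frac=f, nonresponder_mu=nr)
        try:
            r_mu, nr_mu = calibrate_mixture(preset, threshold=2.0)
        except InfeasiblePresetError:
            return
        assert f * r_mu + (1 - f) * nr_mu == pytest.approx(mu, abs=1e-12)


class TestWaveform:
    def test_constructed_peak_recovered(self, protocol):
        shape = KineticShape(peak_fold=3.0, time_to_peak=30.0, iono_peak_fold=4.0)
        preset = _preset(noise_sd=0.0, bleach_rate=0.0)
        tr = generate_trace(shape, preset, protocol, np.random.default_rng(0))
        nt = normalize(
            replace_background(tr), protocol
        )
        peak, ttp = max_rmr(nt, protocol)
        assert peak == pytest.approx(3.0, abs=1e-9)
        assert ttp == pytest.approx(30.0, abs=protocol.frame_interval)
        rmr = protocol.rmr_mask(tr.times)
        assert tr.times[rmr][np.argmax(nt.fold[rmr])] == pytest.approx(
            50.0, abs=protocol.frame_interval
        )

    def test_unit_amplitude_is_flat_until_ionomycin(self, protocol):
        shape = KineticShape(peak_fold=1.0, time_to_peak=30.0, iono_peak_fold=3.0)
        fold = fold_profile(shape, protocol)
        pre_iono = protocol.times < protocol.t_ionomycin
        np.testing.assert_allclose(fold[pre_iono], 1.0, atol=1e-12)

    def test_peak_beyond_window_rejected(self, protocol):
        shape = KineticShape(peak_fold=2.0, time_to_peak=200.0)
        with pytest.raises(ValidationError):
            fold_profile(shape, protocol)

    def test_baseline_is_exactly_one(self, protocol):
        shape = KineticShape(peak_fold=2.5, time_to_peak=40.0, iono_peak_fold=3.5)
        fold = fold_profile(shape, protocol)
        np.testing.assert_array_equal(fold[protocol.times < protocol.t_stimulus], 1.0)

    def test_amplitude_monotonicity_noise_free(self, protocol):
        """Increasing the drawn peak strictly increases the extracted max."""
        preset = _preset(noise_sd=0.0)
        extracted = []
        for a in (1.5, 2.0, 3.0, 4.5):
            shape = KineticShape(peak_fold=a, time_to_peak=25.0, iono_peak_fold=5.0)
            tr = generate_trace(shape, preset, protocol, np.random.default_rng(0))
            nt = normalize(replace_background(tr), protocol)
            extracted.append(max_rmr(nt, protocol)[0])
        assert np.all(np.diff(extracted) > 0)

    def test_seed_determinism_byte_identical(self, protocol, tmp_path):
        preset = _preset(n_cells_per_replicate=3, n_replicates=1, n_lines=1)
        a = traces_to_frame(generate_cohort(preset, protocol, seed=99)).to_csv(index=False)
        b = traces_to_frame(generate_cohort(preset, protocol, seed=99)).to_csv(index=False)
        assert a == b


def replace_background(tr):
    """Subtract the stored scalar background (helper for waveform tests)."""
    from catrace.extraction import subtract_background

    return subtract_background(tr, method="column")


class TestGenerateCohort:
    def test_cohort_size(self, protocol):
        preset = _preset(n_lines=2, n_replicates=3, n_cells_per_replicate=5)
        cohort = generate_cohort(preset, protocol, seed=1)
        assert len(cohort) == 30
        assert len({tr.cell_id for tr in cohort}) == 30
        assert {tr.line_id for tr in cohort} == {"ASD1", "ASD2"}

    def test_empirical_responder_fraction(self, protocol):
        """Over many cells the drawn responder share matches the preset within
        a few binomial standard errors."""
        preset = _preset(
            mu_peak=2.55,
            responder_frac=0.5737,
            noise_sd=0.0,
            n_cells_per_replicate=400,
            n_replicates=2,
            n_lines=2,
        )
        cohort = generate_cohort(preset, protocol, seed=5)
        metrics = extract_cell_metrics(process_cohort(cohort, protocol), protocol)
        frac = metrics["responder"].mean()
        se = np.sqrt(0.5737 * (1 - 0.5737) / len(metrics))
        assert abs(frac - 0.5737) < 4 * se + 0.01

    def test_empirical_mean_peak(self, protocol):
        """CLT check: the mean drawn peak approaches the preset mixture mean."""
        preset = _preset(
            mu_peak=2.55,
            responder_frac=0.5737,
            noise_sd=0.0,
            n_cells_per_replicate=400,
            n_replicates=2,
            n_lines=2,
        )
        cohort = generate_cohort(preset, protocol, seed=6)
        metrics = extract_cell_metrics(process_cohort(cohort, protocol), protocol)
        n = len(metrics)
        assert abs(metrics["max_rmr_fold"].mean() - 2.55) < 3 * 0.6 / np.sqrt(n) + 0.05

    def test_infeasible_preset_propagates(self, protocol):
        preset = _preset(mu_peak=1.2, responder_frac=0.9)
        with pytest.raises(InfeasiblePresetError):
            generate_cohort(preset, protocol, seed=1)


@pytest.fixture(scope="module")
def rendered(protocol):
    preset = _preset(noise_sd=5.0, n_cells_per_replicate=4, n_replicates=1, n_lines=1)
    cohort = generate_cohort(preset, protocol, seed=11)
    stack, masks = generate_image_stack(cohort, StackLayout())
    return cohort, stack, masks


class TestImageStack:
    def test_stack_dimensions(self, rendered, protocol):
        cohort, stack, masks = rendered
        assert stack.shape[0] == protocol.n_frames
        assert stack.dtype == np.uint16
        assert set(np.unique(masks)) == {0, 1, 2, 3, 4}

    def test_roi_means_reproduce_traces_within_quantization(self, rendered, protocol):
        cohort, stack, masks = rendered
        back = extract_roi_traces(stack, masks, protocol)
        assert len(back) == len(cohort)
        for src, got in zip(cohort, back):
            assert np.max(np.abs(got.raw - src.raw)) <= 1.0

    def test_background_pixels_match_preset(self, rendered):
        cohort, stack, masks = rendered
        outside = stack[:, masks == 0]
        assert np.all(np.abs(outside.astype(float) - 50.0) <= 1.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            generate_image_stack([])

    def test_overlapping_layout_rejected(self):
        with pytest.raises(LayoutError):
            StackLayout(radius=8, spacing=10)
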