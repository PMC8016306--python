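"""Synthetic-data generators: protocol waveforms, sensor channels, images,
sessions; all pure functions of (spec, seed)."""

import numpy as np
import pytest

from tactillusion.mechanics import ForceDisplacement
from tactillusion.psychophysics import StimulusPair, TrialRecord, percent_correct
from tactillusion.synthetic_data import (
    ObserverSpec,
    ProtocolSpec,
    SessionSpec,
    gen_displacement_trace,
    gen_force_trace,
    gen_ink_image,
    gen_session,
)


class TestForceTrace:
    def test_triangle_waveform_exact(self):
        spec = ProtocolSpec(kind="triangle", peak_force=2.0, ramp_duration=1.0,
                            noise_sd=0.0)
        tr = gen_force_trace(spec)
        assert tr.values.max() == pytest.approx(2.0)
        assert tr.timestamps[np.argmax(tr.values)] == pytest.approx(1.0)
        assert tr.timestamps[-1] == pytest.approx(2.0)
        assert tr.values[0] == tr.values[-1] == pytest.approx(0.0)

    def test_constant_rate_duration(self):
        spec = ProtocolSpec(kind="constant-rate", peak_force=2.0, rate=1.0,
                            noise_sd=0.0, hold_duration=0.0)
        tr = gen_force_trace(spec)
        assert tr.timestamps[-1] == pytest.approx(2.0)
        assert tr.values[-1] == pytest.approx(2.0)

    def test_seeded_noise_reproducible(self):
        spec = ProtocolSpec(kind="constant-rate", rate=2.0, noise_sd=0.05)
        a = gen_force_trace(spec, seed=3)
        b = gen_force_trace(spec, seed=3)
        c = gen_force_trace(spec, seed=4)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(kind="sawtooth")
        with pytest.raises(ValueError):
            ProtocolSpec(peak_force=-1.0)


class TestDisplacementTrace:
    def test_linear_surrogate_terminal_displacement(self):
        fd = ForceDisplacement(np.array([0.0, 3.0]), np.array([0.0, 3.0]))
        tr = gen_force_trace(ProtocolSpec(kind="constant-rate", rate=1.0,
                                          noise_sd=0.0), seed=0)
        d = gen_displacement_trace(tr, fd, noise_sd=0.0)
        assert d.values.max() == pytest.approx(2.0, abs=1e-6)

    def test_softer_surrogate_displaces_more(self):
        tr = gen_force_trace(ProtocolSpec(kind="constant-rate", rate=1.0,
                                          noise_sd=0.0), seed=0)
        stiff = ForceDisplacement(np.array([0.0, 3.0]), np.array([0.0, 1.5]))
        soft = ForceDisplacement(np.array([0.0, 3.0]), np.array([0.0, 6.0]))
        d_stiff = gen_displacement_trace(tr, stiff, noise_sd=0.0)
        d_soft = gen_displacement_trace(tr, soft, noise_sd=0.0)
        assert d_soft.values.max() > d_stiff.values.max()

    def test_force_beyond_curve_range_rejected(self):
        fd = ForceDisplacement(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        tr = gen_force_trace(ProtocolSpec(kind="constant-rate", peak_force=2.0,
                                          rate=1.0, noise_sd=0.0), seed=0)
        with pytest.raises(ValueError):
            gen_displacement_trace(tr, fd, noise_sd=0.0)


class TestInkImage:
    def test_blob_pixel_budget_and_bar(self):
        image, truth = gen_ink_image(1.0, scale_cm_per_px=0.01, seed=0)
        assert truth["mask"].sum() == pytest.approx(1e4, rel=0.01)
        assert truth["bar_pixels"] == 500
        assert image.bar_pixels == 500

    def test_truth_area_matches_mask(self):
        _, truth = gen_ink_image(0.75, scale_cm_per_px=0.02, seed=1)
        assert truth["area_cm2"] == pytest.approx(
            truth["mask"].sum() * 0.02**2)

    def test_seed_reproducibility(self):
        a, _ = gen_ink_image(1.0, seed=9)
        b, _ = gen_ink_image(1.0, seed=9)
        assert np.array_equal(a.raster, b.raster)

    def test_degenerate_area_rejected(self):
        with pytest.raises(ValueError):
            gen_ink_image(0.0)


class TestSession:
    def test_design_counts_per_participant(self):
        spec = SessionSpec(conditions={
            "passive-same-rate": ObserverSpec(dprime=0.4, repetitions=2),
            "active-same-rate": ObserverSpec(dprime=3.5, repetitions=3),
        }, participants=1, seed=0)
        trials = gen_session(spec)
        counts = trials.groupby("condition").size()
        assert counts["passive-same-rate"] == 18  # 9 ordered pairs x 2
        assert counts["active-same-rate"] == 27  # 9 ordered pairs x 3

    def test_presentation_order_is_permutation_of_design(self):
        spec = SessionSpec(conditions={
            "c": ObserverSpec(dprime=1.0, repetitions=2)}, participants=1, seed=1)
        trials = gen_session(spec)
        pair_counts = trials.groupby(["first", "second"]).size()
        assert (pair_counts == 2).all() and len(pair_counts) == 9

    def test_zero_sensitivity_yields_chance(self):
        spec = SessionSpec(conditions={
            "c": ObserverSpec(dprime=0.0, criterion=0.9, repetitions=60)},
            participants=4, seed=2)
        trials = gen_session(spec)
        recs = [TrialRecord.from_response(StimulusPair(r.first, r.second),
                                          r.condition, r.response)
                for r in trials.itertuples()]
        pc, flag = percent_correct(recs)
        assert not flag
        assert pc == pytest.approx(50.0, abs=6.0)

    def test_seed_determinism(self):
        spec = SessionSpec(participants=2, seed=5)
        a = gen_session(spec)
        b = gen_session(spec)
        assert a.equals(b)
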