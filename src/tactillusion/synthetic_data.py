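"""Synthetic study inputs with known ground truth.

Every input the analysis pipeline consumes can be generated here with a
declared statistical structure and a seed: force traces following the
experimental protocols (triangle waves peaking at 1/2/3 N; constant-rate
ramps at 0.5/1/2 N/s to 2 N), laser-displacement traces consistent with a
force-displacement relation, ink-stamp images with a known physical
contact area and a 5.0 cm reference bar, full same-different sessions
from the differencing observer, and calibration target curves computed by
the mechanics module at known layer moduli.

All generators are pure functions of (spec, seed) and return ground truth
sufficient to score every downstream stage without human data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import psychophysics as psy
from .calibration import (
    CalibrationModelConfig,
    CalibrationTargets,
    DeflectionTarget,
    ForceDisplacementTarget,
    predict_deflections,
    predict_forces,
)
from .contact_area import DEFAULT_BAR_LENGTH_CM, InkImage
from .mechanics import ForceDisplacement
from .signals import Trace

__all__ = [
    "ProtocolSpec",
    "ObserverSpec",
    "SessionSpec",
    "TRIANGLE_PEAKS_N",
    "CONSTANT_RATES_NPS",
    "DEFAULT_CONDITION_OBSERVERS",
    "ILLUSION_STIMULI",
    "DISTINCT_STIMULUS",
    "gen_force_trace",
    "gen_displacement_trace",
    "gen_ink_image",
    "gen_session",
    "gen_study_dir",
    "gen_calibration_targets",
]

#: triangle-wave peak forces (N) used in the biomechanical measurements
TRIANGLE_PEAKS_N = (1.0, 2.0, 3.0)

#: constant-rate protocols (N/s), all terminating at 2 N
CONSTANT_RATES_NPS = (0.5, 1.0, 2.0)

#: the three illusion case spheres and the distinct comparison sphere
ILLUSION_STIMULI = ("10kPa-4mm", "90kPa-6mm", "90kPa-8mm")
DISTINCT_STIMULUS = "10kPa-8mm"


@dataclass(frozen=True)
class ProtocolSpec:
    """One force-delivery protocol.

    ``kind='triangle'``: ramp to ``peak_force`` over ``ramp_duration``
    seconds and back down symmetrically.  ``kind='constant-rate'``: load
    at ``rate`` N/s until ``peak_force`` then hold briefly.
    """

    kind: str = "triangle"  # or "constant-rate"
    peak_force: float = 2.0  # N
    rate: float = 1.0  # N/s, constant-rate only
    ramp_duration: float = 1.0  # s per leg, triangle only
    sample_rate: float = 300.0  # Hz
    noise_sd: float = 0.01  # N
    hold_duration: float = 0.5  # s, constant-rate terminal hold

    def __post_init__(self):
        if self.kind not in ("triangle", "constant-rate"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.peak_force <= 0 or self.rate <= 0 or self.ramp_duration <= 0:
            raise ValueError("forces, rates and durations must be positive")
        if self.sample_rate <= 0 or self.noise_sd < 0:
            raise ValueError("invalid sample rate or noise SD")


def gen_force_trace(spec: ProtocolSpec, seed: int | None = None) -> Trace:
    """Sample a force trace for one indentation.

    The noiseless backbone is the exact protocol waveform; additive
    Gaussian sensor noise at ``spec.noise_sd`` is superimposed.
    """
    fs = spec.sample_rate
    if spec.kind == "triangle":
        n_leg = int(round(spec.ramp_duration * fs))
        t = np.arange(2 * n_leg + 1) / fs
        up = spec.peak_force * np.arange(n_leg + 1) / n_leg
        down = up[-2::-1]
        values = np.concatenate([up, down])
    else:
        ramp_t = spec.peak_force / spec.rate
        n_ramp = int(round(ramp_t * fs))
        n_hold = int(round(spec.hold_duration * fs))
        t = np.arange(n_ramp + n_hold + 1) / fs
        values = np.concatenate([
            spec.peak_force * np.arange(n_ramp + 1) / n_ramp,
            np.full(n_hold, spec.peak_force),
        ])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    return Trace(t, values, fs)


def gen_displacement_trace(force_trace: Trace,
                           stiffness_source: ForceDisplacement,
                           noise_sd: float = 0.002,
                           seed: int | None = None,
                           sample_rate: float = 1500.0) -> Trace:
    """Emulate the laser-displacement channel for a force trace.

    The displacement backbone is the inverse of the force-displacement
    relation evaluated on the (noiseless part of the) force signal,
    resampled to the laser sample rate and time-aligned with the force
    trace; Gaussian sensor noise is added on top.

    Raises
    ------
    ValueError
        If the force trace exceeds the solved force-displacement range.
    """
    t_laser = np.arange(0.0, force_trace.timestamps[-1] + 0.5 / sample_rate,
                        1.0 / sample_rate)
    force = np.interp(t_laser, force_trace.timestamps, force_trace.values)
    force = np.clip(force, 0.0, None)  # sensor noise can dip below zero
    disp = stiffness_source.displacement_at(force)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        disp = disp + rng.normal(0.0, noise_sd, size=disp.shape)
    return Trace(t_laser, disp, sample_rate)


def gen_ink_image(true_area_cm2: float,
                  scale_cm_per_px: float = 0.01,
                  bar_length_cm: float = DEFAULT_BAR_LENGTH_CM,
                  aspect: float = 1.3,
                  speckle_fraction: float = 0.002,
                  seed: int | None = None) -> tuple[InkImage, dict]:
    """Render a synthetic ink stamp with a known contact area.

    An elliptical ink blob of ``true_area_cm2`` (fingerprint-like aspect
    ratio) is rasterized onto white paper together with a horizontal
    reference bar of ``bar_length_cm``; salt-and-pepper speckle emulates
    stray ink and paper texture.  Returns the image plus a ground-truth
    dict with the exact rasterized mask and area, and the ROI enclosing
    the blob.

    Raises
    ------
    ValueError
        If the blob (or bar) would not fit a reasonable canvas.
    """
    if true_area_cm2 <= 0:
        raise ValueError("true_area_cm2 must be positive")
    area_px = true_area_cm2 / scale_cm_per_px**2
    b = np.sqrt(area_px / (np.pi * aspect))  # semi-minor (x)
    a = aspect * b  # semi-major (y)
    bar_px = int(round(bar_length_cm / scale_cm_per_px))
    margin = 20
    width = max(int(4 * b), bar_px + 2 * margin)
    height = int(4 * a) + 60
    if width > 4096 or height > 4096:
        raise ValueError("blob or bar too large for the canvas at this scale")
    cy, cx = height // 2 + 20, width // 2
    yy, xx = np.mgrid[0:height, 0:width]
    mask = ((xx - cx) / b) ** 2 + ((yy - cy) / a) ** 2 <= 1.0

    rng = np.random.default_rng(seed)
    img = np.full((height, width, 3), 245, dtype=np.uint8)
    img[..., 0] -= rng.integers(0, 6, size=(height, width), dtype=np.uint8)
    ink = np.array([40, 45, 120], dtype=np.uint8)  # dark blue washable ink
    img[mask] = ink + rng.integers(-15, 15, size=(int(mask.sum()), 3))
    # reference bar along the top margin
    bar_y0, bar_y1 = 8, 14
    bar_x0 = (width - bar_px) // 2
    img[bar_y0:bar_y1, bar_x0:bar_x0 + bar_px] = (30, 30, 30)
    # speckle: stray dark dots and white pinholes
    n_speck = int(speckle_fraction * height * width)
    sy = rng.integers(30, height, size=n_speck)
    sx = rng.integers(0, width, size=n_speck)
    img[sy[: n_speck // 2], sx[: n_speck // 2]] = (60, 60, 90)
    img[sy[n_speck // 2:], sx[n_speck // 2:]] = (250, 250, 250)

    image = InkImage(raster=img, bar_pixels=float(bar_px),
                     bar_length=bar_length_cm)
    truth = {
        "mask": mask,
        "area_cm2": float(mask.sum()) * scale_cm_per_px**2,
        "requested_area_cm2": float(true_area_cm2),
        "scale_cm_per_px": float(scale_cm_per_px),
        "bar_pixels": float(bar_px),
        "roi_center": (float(cx), float(cy)),
        "roi_radius": float(1.6 * a),
    }
    return image, truth


@dataclass(frozen=True)
class ObserverSpec:
    """Differencing-observer parameters for one condition."""

    dprime: float
    criterion: float = 1.5
    repetitions: int = 2  # presentations of each ordered pair

    def __post_init__(self):
        if self.dprime < 0 or self.repetitions < 1:
            raise ValueError("dprime must be >= 0 and repetitions >= 1")


#: condition-specific observer defaults: placeholders spanning chance to
#: high sensitivity in the qualitative order passive-same < passive-inverse
#: < passive-direct < active (2 presentations per pair in passive tasks,
#: 3 in the active task)
DEFAULT_CONDITION_OBSERVERS: dict[str, ObserverSpec] = {
    "passive-same-rate": ObserverSpec(dprime=0.4, repetitions=2),
    "passive-inverse-rate": ObserverSpec(dprime=1.2, repetitions=2),
    "passive-direct-rate": ObserverSpec(dprime=2.5, repetitions=2),
    "active-same-rate": ObserverSpec(dprime=3.5, repetitions=3),
}


@dataclass(frozen=True)
class SessionSpec:
    """A full synthetic psychophysical study."""

    conditions: Mapping[str, ObserverSpec] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_OBSERVERS))
    stimuli: tuple[str, ...] = ILLUSION_STIMULI
    participants: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.participants < 1 or not self.conditions or not self.stimuli:
            raise ValueError("invalid session specification")


def gen_session(spec: SessionSpec) -> pd.DataFrame:
    """Simulate a full same-different study.

    Each participant completes every condition: all ordered stimulus pairs
    (n² of them), each presented ``repetitions`` times in a randomized
    order, with responses drawn from the differencing observer at the
    condition's (d', k).  Returns a trial table with columns participant,
    condition, first, second, response, correct.
    """
    rng = np.random.default_rng(spec.seed)
    pairs = psy.enumerate_pairs(spec.stimuli)
    rows = []
    for p in range(spec.participants):
        for cond, obs in spec.conditions.items():
            design = pairs * obs.repetitions
            order = rng.permutation(len(design))
            trial_seed = int(rng.integers(0, 2**31 - 1))
            trials = psy.simulate_observer(
                obs.dprime, obs.criterion,
                [design[i] for i in order], n_trials=1,
                seed=trial_seed, condition=cond)
            for t in trials:
                rows.append({
                    "participant": p, "condition": cond,
                    "first": t.pair.first, "second": t.pair.second,
                    "response": t.response, "correct": t.correct,
                })
    return pd.DataFrame(rows)


#: generating mean contact areas (cm^2) at the 2 N reference load for the
#: illusion set and the distinct sphere, with between-indentation and
#: between-participant spreads
AREA_MODEL = {
    "passive": {"illusion_cm2": 0.90, "distinct_cm2": 1.68, "trial_sd": 0.12},
    "active": {"illusion_cm2": 0.87, "distinct_cm2": 1.48, "trial_sd": 0.10},
    "participant_sd": 0.05,
    "force_exponent": 1.0 / 3.0,  # Hertz-like growth of area with load
}


def gen_study_dir(out_dir, seed: int = 0, participants: int = 3,
                  indentations: int = 2,
                  force_levels: Sequence[float] = TRIANGLE_PEAKS_N,
                  modes: Sequence[str] = ("passive", "active"),
                  scale_cm_per_px: float = 0.02,
                  session: SessionSpec | None = None) -> dict:
    """Write a complete synthetic study directory.

    Produces ``images/`` (ink stamps + sidecar JSON with bar pixels, ROI,
    stimulus id, force, participant), ``traces/`` (CSV force traces for
    the constant-rate protocols), ``trials.csv`` (the psychophysical
    session) and ``truth.json`` with every generating parameter.  Mean
    areas follow the study conditions: the three illusion case spheres
    share one area level and the distinct sphere a higher one, both
    growing with the force level.
    """
    import json
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "traces").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    stimuli = list(ILLUSION_STIMULI) + [DISTINCT_STIMULUS]
    truth_rows = []
    for mode in modes:
        mdl = AREA_MODEL[mode]
        for pid in range(participants):
            offset = rng.normal(0.0, AREA_MODEL["participant_sd"])
            for sid in stimuli:
                base = (mdl["distinct_cm2"] if sid == DISTINCT_STIMULUS
                        else mdl["illusion_cm2"])
                for force in force_levels:
                    for rep in range(indentations):
                        area = (base + offset) * \
                            (force / 2.0) ** AREA_MODEL["force_exponent"] + \
                            rng.normal(0.0, mdl["trial_sd"] / 2.0)
                        area = max(area, 0.2)
                        img_seed = int(rng.integers(0, 2**31 - 1))
                        image, gt = gen_ink_image(area, scale_cm_per_px,
                                                  seed=img_seed)
                        name = f"{mode}_p{pid}_{sid}_{force:g}N_r{rep}"
                        Image.fromarray(image.raster).save(
                            out / "images" / f"{name}.png")
                        sidecar = {
                            "bar_pixels": gt["bar_pixels"],
                            "bar_length_cm": 5.0,
                            "roi_center": gt["roi_center"],
                            "roi_radius": gt["roi_radius"],
                            "stimulus_id": sid,
                            "force_N": force,
                            "participant": pid,
                            "mode": mode,
                        }
                        (out / "images" / f"{name}.json").write_text(
                            json.dumps(sidecar))
                        truth_rows.append({"image": f"{name}.png",
                                           "area_cm2": gt["area_cm2"]})
    # constant-rate force traces per protocol
    for rate in CONSTANT_RATES_NPS:
        tr = gen_force_trace(ProtocolSpec(kind="constant-rate", rate=rate),
                             seed=int(rng.integers(0, 2**31 - 1)))
        pd.DataFrame({"time_s": tr.timestamps, "value": tr.values}).to_csv(
            out / "traces" / f"rate_{rate:g}Nps.csv", index=False)
    session = session or SessionSpec(participants=participants,
                                     seed=int(rng.integers(0, 2**31 - 1)))
    trials = gen_session(session)
    trials.to_csv(out / "trials.csv", index=False)
    truth = {
        "seed": seed,
        "area_model": AREA_MODEL,
        "observers": {k: {"dprime": v.dprime, "criterion": v.criterion,
                          "repetitions": v.repetitions}
                      for k, v in session.conditions.items()},
        "images": truth_rows,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth


def gen_calibration_targets(moduli: dict[str, float],
                            noise_sd: float = 0.0,
                            seed: int | None = None,
                            config: CalibrationModelConfig | None = None,
                            travels: Sequence[float] = (0.4, 0.8, 1.2),
                            fd_displacements: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
                            ) -> tuple[CalibrationTargets, dict]:
    """Calibration target curves computed by the mechanics module.

    Stands in for the published deflection and force-displacement
    measurements the original calibration used: the plane-strain model at
    the given layer ``moduli`` (kPa) produces surface-deflection profiles
    at the requested indenter ``travels``, and the axisymmetric model
    produces the force-displacement curve; Gaussian noise at ``noise_sd``
    (mm on deflections, relative on forces) can be added.  Returns the
    targets plus the generating truth.
    """
    config = config or CalibrationModelConfig()
    rng = np.random.default_rng(seed)

    probe = CalibrationTargets(
        deflection_curves=tuple(
            DeflectionTarget(t, np.linspace(0.0, config.extent, 31),
                             np.linspace(1.0, 2.0, 31))
            for t in travels),
        fd_curve=ForceDisplacementTarget(np.asarray(fd_displacements),
                                         np.linspace(0.1, 1.0, len(fd_displacements))),
    )
    defl = predict_deflections(moduli, probe, config)
    curves = []
    for tgt, d in zip(probe.deflection_curves, defl):
        vals = d + (rng.normal(0.0, noise_sd, size=d.shape) if noise_sd > 0 else 0.0)
        curves.append(DeflectionTarget(tgt.indenter_travel, tgt.locations, vals))
    forces = predict_forces(moduli, probe.fd_curve, config)
    if noise_sd > 0:
        forces = forces * (1.0 + rng.normal(0.0, noise_sd, size=forces.shape))
    forces = np.maximum.accumulate(forces)  # keep the target monotone
    targets = CalibrationTargets(
        deflection_curves=tuple(curves),
        fd_curve=ForceDisplacementTarget(np.asarray(fd_displacements, float), forces),
        provenance="synthetic",
    )
    truth = {"moduli_kPa": dict(moduli), "noise_sd": noise_sd, "seed": seed}
    return targets, truth
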