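"""Shared fixtures.

The finite-element artifacts (illusion solutions, Hertz benchmark,
calibration recovery) are expensive, so they are solved once per session
and shared between the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import tactillusion.calibration as cal
import tactillusion.mechanics as mech
import tactillusion.synthetic_data as synth

ILLUSION_PAIR = ("10kPa-4mm", "90kPa-8mm")
DISTINCT_ID = "10kPa-8mm"
LOADS = (0.25, 0.5, 1.0, 2.0)


def _tip(sid: str) -> mech.StimulusTip:
    g, r = sid.split("-")
    return mech.StimulusTip(radius=float(r[:-2]), shear_modulus=float(g[:-3]))


@pytest.fixture(scope="session")
def coarse_fingertip():
    return mech.build_fingertip_model(mech.default_fingertip_config(coarse=True))


@pytest.fixture(scope="session")
def illusion_solutions(coarse_fingertip):
    """Passive-mode solutions for the illusion pair and the distinct sphere."""
    out = {}
    for sid in (*ILLUSION_PAIR, DISTINCT_ID):
        out[sid] = mech.solve_contact(mech.ContactProblem(
            fingertip=coarse_fingertip, stimulus=_tip(sid), mode="passive",
            load_schedule=LOADS, stimulus_mesh_scale=2.0))
    return out


@pytest.fixture(scope="session")
def active_solutions(coarse_fingertip):
    """Active-mode solutions (proprioceptive force-displacement cue)."""
    out = {}
    for sid in ILLUSION_PAIR:
        out[sid] = mech.solve_contact(mech.ContactProblem(
            fingertip=coarse_fingertip, stimulus=_tip(sid), mode="active",
            load_schedule=LOADS, stimulus_mesh_scale=2.0))
    return out


@pytest.fixture(scope="session")
def hertz_benchmark():
    """Near-rigid sphere on a single-material half-space at small load.

    Returns the least-squares Hertz fit (contact radius, peak pressure)
    and the closed-form values for an incompressible substrate.
    """
    G_sub, R, F = 10.0, 5.0, 0.01
    mat = mech.NeoHookeanMaterial.from_moduli(G_sub, bulk_ratio=1e5)
    layers = (mech.LayerSpec("top", 0.6, mat), mech.LayerSpec("mid", 2.4, mat),
              mech.LayerSpec("deep", 9.0, mat))
    cfg = mech.FingertipConfig(layers=layers, pad_radius=12.0,
                               interface_extent=3.0, n_interface_nodes=41,
                               layer_divisions=(5, 6, 5))
    model = mech.build_fingertip_model(cfg)
    tip = mech.StimulusTip(radius=R, shear_modulus=G_sub * 1e4,
                           fine_edge=0.15, coarse_edge=1.0)
    sol = mech.solve_contact(mech.ContactProblem(
        fingertip=model, stimulus=tip, mode="passive", load_schedule=(F,)))
    r, p = sol[0].contact_pressure[:, 0], sol[0].contact_pressure[:, 1]
    # p(r)^2 = p0^2 (1 - r^2/a^2) is linear in r^2
    coef, *_ = np.linalg.lstsq(np.column_stack([np.ones_like(r), r**2]),
                               p**2, rcond=None)
    p0_fit = float(np.sqrt(coef[0]))
    a_fit = float(np.sqrt(-coef[0] / coef[1]))
    e_star = 3.0 * G_sub / (1.0 - 0.5**2)  # E = 3G, nu = 1/2
    a_th = (3.0 * F * 1000.0 * R / (4.0 * e_star)) ** (1.0 / 3.0)
    p0_th = 3.0 * F * 1000.0 / (2.0 * np.pi * a_th**2)
    return {"a_fit": a_fit, "p0_fit": p0_fit, "a_theory": a_th,
            "p0_theory": p0_th, "state": sol[0]}


@pytest.fixture(scope="session")
def calibration_recovery():
    """Noiseless two-step calibration against model-generated targets."""
    cfg = cal.CalibrationModelConfig()
    true_moduli = {"epidermis": 40.0, "dermis": 24.0, "subcutaneous": 10.0}
    targets, _ = synth.gen_calibration_targets(true_moduli, noise_sd=0.0,
                                               seed=0, config=cfg)
    fit = cal.fit_layer_ratios(targets, config=cfg)
    scale = cal.scale_to_force_displacement((0.6, 0.25), targets.fd_curve,
                                            config=cfg)
    return {"true_moduli": true_moduli, "true_ratios": (0.6, 0.25),
            "true_scale": 4.0, "fit": fit, "scale": scale, "config": cfg,
            "targets": targets}
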