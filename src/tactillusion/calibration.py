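"""Two-step material calibration of the layered fingertip model.

Step 1 fits the *ratios* of layer shear moduli (dermis:epidermis and
subcutaneous:epidermis) by grid search: the plane-strain model is indented
by a rigid cylinder to a set of prescribed displacements and the predicted
surface-deflection profiles are compared against target profiles with R²;
the selected ratios are the mean of all grid points reaching R² >= 0.8.
Under displacement control the deflection field depends only on the
modulus ratios (the equilibrium equations are homogeneous in the modulus),
which is what makes the two-step split exact.

Step 2 fixes the absolute scale: the axisymmetric model is indented to the
displacements of a target force-displacement curve and a single positive
scale factor on all layer moduli is chosen to minimize the squared force
error (golden-section search on the scale; the predicted force is itself
proportional to the scale, again by homogeneity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mechanics import (
    FingertipConfig,
    SolverError,
    SolverParams,
    build_fingertip_model,
    default_layers,
    solve_rigid_indentation,
    surface_deflection_profile,
)

__all__ = [
    "CalibrationError",
    "FitFailureError",
    "DeflectionTarget",
    "ForceDisplacementTarget",
    "CalibrationTargets",
    "CalibrationModelConfig",
    "RatioGrid",
    "LayerRatioFit",
    "r_squared",
    "predict_deflections",
    "predict_forces",
    "fit_layer_ratios",
    "scale_to_force_displacement",
    "calibrate",
]


class CalibrationError(ValueError):
    """Invalid calibration data."""


class FitFailureError(RuntimeError):
    """No grid point reached the acceptance threshold."""


@dataclass(frozen=True)
class DeflectionTarget:
    """Surface-deflection profile at one indenter displacement.

    ``locations`` are lateral positions (mm), ``deflections`` the normal
    surface deflection (mm, positive into the tissue).
    """

    indenter_travel: float  # mm
    locations: np.ndarray
    deflections: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "locations", np.asarray(self.locations, float))
        object.__setattr__(self, "deflections", np.asarray(self.deflections, float))
        if self.locations.size < 3 or self.locations.size != self.deflections.size:
            raise CalibrationError("deflection target needs >= 3 aligned samples")
        if self.indenter_travel < 0:
            raise CalibrationError("indenter travel must be non-negative")


@dataclass(frozen=True)
class ForceDisplacementTarget:
    """Observed fingertip force-displacement samples."""

    displacement: np.ndarray  # mm
    force: np.ndarray  # N

    def __post_init__(self):
        object.__setattr__(self, "displacement", np.asarray(self.displacement, float))
        object.__setattr__(self, "force", np.asarray(self.force, float))
        if self.displacement.size == 0:
            raise CalibrationError("empty force-displacement target")
        if self.displacement.size != self.force.size:
            raise CalibrationError("displacement and force must align")
        if np.any(self.displacement < 0):
            raise CalibrationError("displacements must be non-negative")
        if np.any(np.diff(self.displacement) <= 0) or np.any(np.diff(self.force) < 0):
            raise CalibrationError("force-displacement target must be monotone")


@dataclass(frozen=True)
class CalibrationTargets:
    """Everything the two-step calibration consumes."""

    deflection_curves: tuple[DeflectionTarget, ...]
    fd_curve: ForceDisplacementTarget
    provenance: str = "synthetic"  # or "user-supplied"

    def __post_init__(self):
        if not self.deflection_curves:
            raise CalibrationError("need at least one deflection target")


@dataclass(frozen=True)
class CalibrationModelConfig:
    """Reduced-size models used during calibration.

    The plane-strain model serves the deflection (ratio) fit, the
    axisymmetric model the force-displacement (scale) fit; both are
    deliberately coarse so a grid search stays cheap.
    """

    indenter_radius: float = 0.5  # mm, sharp ratio-fit probe (cylinder)
    fd_indenter_radius: float = 5.0  # mm, force-displacement probe (sphere)
    extent: float = 6.0  # mm of finely meshed surface
    n_surface_nodes: int = 31
    fit_band: tuple[float, float] = (0.8, 2.0)  # mm, R² evaluation window
    pad_radius: float = 12.0
    layer_divisions: tuple[int, ...] = (2, 3, 3)
    dermis_thickness: float = 1.2
    subcutaneous_thickness: float = 4.0
    epidermis_reference_modulus: float = 10.0  # kPa, arbitrary ratio-fit scale
    solver: SolverParams = field(default_factory=lambda: SolverParams(
        max_newton=12, min_step=1e-3, init_step=0.05, max_step=0.5))

    def fingertip_config(self, formulation: str,
                         moduli: dict[str, float]) -> FingertipConfig:
        layers = default_layers(moduli=moduli,
                                dermis_thickness=self.dermis_thickness,
                                subcutaneous_thickness=self.subcutaneous_thickness)
        return FingertipConfig(
            formulation=formulation, layers=layers,
            pad_radius=self.pad_radius, interface_extent=self.extent,
            n_interface_nodes=self.n_surface_nodes,
            layer_divisions=self.layer_divisions,
        )


@dataclass(frozen=True)
class RatioGrid:
    """Search grid over (dermis:epidermis, subcutaneous:epidermis)."""

    dermis: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    subcutaneous: tuple[float, ...] = (0.1, 0.25, 0.4, 0.55, 0.7)

    def __post_init__(self):
        if len(self.dermis) < 2 or len(self.subcutaneous) < 2:
            raise CalibrationError("grid needs >= 2 points per ratio axis")

    @property
    def spacing(self) -> tuple[float, float]:
        return (float(np.max(np.diff(self.dermis))),
                float(np.max(np.diff(self.subcutaneous))))


@dataclass(frozen=True)
class LayerRatioFit:
    """Result of the deflection (ratio) grid search."""

    grid: RatioGrid
    r2: np.ndarray  # (n_dermis, n_subcut)
    selected_dermis_ratio: float
    selected_subcutaneous_ratio: float
    threshold: float = 0.8


def _golden_section(f, lo: float, hi: float, tol: float = 1e-8) -> float:
    """Deterministic golden-section minimizer of a unimodal 1-D function."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def r_squared(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    Raises
    ------
    CalibrationError
        On length mismatch or a constant observed curve (undefined R²).
    """
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    if pred.shape != obs.shape or pred.size == 0:
        raise CalibrationError("predicted and observed curves must align")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise CalibrationError("observed curve is constant; R² undefined")
    ss_res = float(((obs - pred) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def predict_deflections(moduli: dict[str, float], targets: CalibrationTargets,
                        config: CalibrationModelConfig) -> list[np.ndarray]:
    """Plane-strain surface deflections at the targets' indenter travels,
    resampled onto each target's locations."""
    model = build_fingertip_model(config.fingertip_config("plane-strain", moduli))
    travels = [t.indenter_travel for t in targets.deflection_curves]
    states = solve_rigid_indentation(model, config.indenter_radius, travels,
                                     params=config.solver)
    states_by_travel = dict(zip(sorted(travels), states))
    out = []
    for tgt in targets.deflection_curves:
        prof = surface_deflection_profile(states_by_travel[tgt.indenter_travel], model)
        out.append(np.interp(tgt.locations, prof.locations, prof.values))
    return out


def predict_forces(moduli: dict[str, float], fd: ForceDisplacementTarget,
                   config: CalibrationModelConfig) -> np.ndarray:
    """Axisymmetric reaction forces (N) at the target displacements."""
    model = build_fingertip_model(config.fingertip_config("axisymmetric", moduli))
    states = solve_rigid_indentation(model, config.fd_indenter_radius,
                                     fd.displacement, params=config.solver)
    return np.array([s.load for s in states])


def fit_layer_ratios(targets: CalibrationTargets,
                     grid: RatioGrid | None = None,
                     config: CalibrationModelConfig | None = None,
                     threshold: float = 0.8) -> LayerRatioFit:
    """Grid-search the layer-modulus ratios against deflection targets.

    Evaluates the plane-strain model at every (dermis, subcutaneous)
    ratio pair, scores the pooled deflection curves with R², and returns
    the mean of all grid points with R² >= ``threshold``.

    Raises
    ------
    FitFailureError
        If no grid point reaches the threshold (the best R² is reported).
    """
    grid = grid or RatioGrid()
    config = config or CalibrationModelConfig()
    g_e = config.epidermis_reference_modulus
    # evaluate R² inside the sensitivity band only: in-contact deflections
    # are clamped to the indenter shape and far-field tails vanish for
    # every model, so both regions carry no layer information
    lo, hi = config.fit_band
    band = [(t.locations >= lo) & (t.locations <= hi)
            for t in targets.deflection_curves]
    observed = np.concatenate([t.deflections[m]
                               for t, m in zip(targets.deflection_curves, band)])
    r2 = np.full((len(grid.dermis), len(grid.subcutaneous)), -np.inf)
    for i, rd in enumerate(grid.dermis):
        for j, rs in enumerate(grid.subcutaneous):
            moduli = {"epidermis": g_e, "dermis": rd * g_e, "subcutaneous": rs * g_e}
            try:
                pred = predict_deflections(moduli, targets, config)
            except SolverError:
                continue  # unsolvable extreme ratio: scored -inf
            pred = np.concatenate([p[m] for p, m in zip(pred, band)])
            r2[i, j] = r_squared(pred, observed)
    mask = r2 >= threshold
    if not mask.any():
        raise FitFailureError(
            f"no ratio grid point reached R² >= {threshold}; best R² = {r2.max():.4f}")
    di, sj = np.nonzero(mask)
    sel_d = float(np.mean(np.asarray(grid.dermis)[di]))
    sel_s = float(np.mean(np.asarray(grid.subcutaneous)[sj]))
    return LayerRatioFit(grid=grid, r2=r2, selected_dermis_ratio=sel_d,
                         selected_subcutaneous_ratio=sel_s, threshold=threshold)


def scale_to_force_displacement(ratios: LayerRatioFit | tuple[float, float],
                                fd_targets: ForceDisplacementTarget,
                                config: CalibrationModelConfig | None = None
                                ) -> dict[str, float]:
    """Scale the fitted ratios to absolute layer moduli (kPa).

    The axisymmetric model is solved once at a reference epidermis modulus;
    because the reaction force under displacement control is proportional
    to a global modulus scale, the squared-force objective is a smooth 1-D
    function of the scale, minimized by golden-section search.

    Raises
    ------
    CalibrationError
        If the force-displacement target is empty or non-monotone (checked
        on construction of :class:`ForceDisplacementTarget`).
    """
    config = config or CalibrationModelConfig()
    if isinstance(ratios, LayerRatioFit):
        rd, rs = ratios.selected_dermis_ratio, ratios.selected_subcutaneous_ratio
    else:
        rd, rs = ratios
    g_ref = config.epidermis_reference_modulus
    moduli_ref = {"epidermis": g_ref, "dermis": rd * g_ref, "subcutaneous": rs * g_ref}
    f_ref = predict_forces(moduli_ref, fd_targets, config)
    f_obs = fd_targets.force

    def sse(log_scale: float) -> float:
        return float(((np.exp(log_scale) * f_ref - f_obs) ** 2).sum())

    scale = float(np.exp(_golden_section(sse, np.log(1e-3), np.log(1e3))))
    return {"epidermis": scale * g_ref,
            "dermis": scale * rd * g_ref,
            "subcutaneous": scale * rs * g_ref,
            "scale": scale}


def calibrate(targets: CalibrationTargets,
              grid: RatioGrid | None = None,
              config: CalibrationModelConfig | None = None) -> dict:
    """Run both calibration steps; returns ratios, moduli and fit report."""
    fit = fit_layer_ratios(targets, grid=grid, config=config)
    moduli = scale_to_force_displacement(fit, targets.fd_curve, config=config)
    return {
        "ratio_fit": fit,
        "moduli_kPa": {k: moduli[k] for k in ("epidermis", "dermis", "subcutaneous")},
        "scale": moduli["scale"],
        "r2_max": float(fit.r2.max()),
    }
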