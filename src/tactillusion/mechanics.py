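"""Hyperelastic finite-element contact model of fingertip-sphere touch.

A layered 2D model of the distal finger pad (epidermis, dermis,
subcutaneous tissue over a rigid bone proxy) is pressed against a
compliant hemispherical stimulus tip under force control, in either an
axisymmetric formulation (contact normal to the pad; used for all cue
simulations) or a plane-strain formulation (cross-section across the
finger width; used for deflection calibration).

Constitutive model
------------------
Each tissue layer and the stimulus use a compressible Neo-Hookean strain
energy

    Psi = C10 * (I1_bar - 3) + (1/D1) * (J - 1)^2

with ``I1_bar = J**(-2/3) * tr(F F^T)`` the modified first invariant and
``J = det F``.  The shear and bulk moduli follow as ``G = 2*C10`` and
``K = 2/D1``; a material is usually specified by G with
``K = bulk_ratio * G`` (default 1e5, near-incompressible).

Discretization and solver
-------------------------
Bilinear quadrilaterals with an F-bar (element-mean dilatation)
modification carry the near-incompressible response without volumetric
locking.  Equilibrium is solved by Newton iteration on a total-Lagrangian
residual; the material tangent dP/dF is evaluated by central differencing
of the analytic first Piola-Kirchhoff stress at every quadrature point
(vectorized over elements), which keeps the tangent in lock-step with the
stress definition.  Frictionless contact couples the stimulus surface
nodes (slave) to the fingertip surface segments (master) through a
penalty on the normal gap, with the penalty stiffness scaled to the
softer body's shear modulus.  Force control is an outer loop on the
rigid-driver travel: the travel is swept adaptively and refined by secant
iteration until each scheduled normal force is matched within 1%.

Units are mm / kPa / mN internally (1 kPa * mm^2 = 1 mN); public
interfaces take and report forces in N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

__all__ = [
    "ConfigError",
    "SolverError",
    "InvalidDeformationError",
    "NeoHookeanMaterial",
    "LayerSpec",
    "StimulusTip",
    "FingertipConfig",
    "FingertipModel",
    "StimulusModel",
    "ContactProblem",
    "SolverParams",
    "SolutionState",
    "ContactSolution",
    "CueProfile",
    "ForceDisplacement",
    "strain_energy",
    "cauchy_stress",
    "build_fingertip_model",
    "build_stimulus_model",
    "default_layers",
    "default_fingertip_config",
    "solve_contact",
    "solve_rigid_indentation",
    "interface_stress_profile",
    "interface_sed_profile",
    "surface_deflection_profile",
    "force_displacement_curve",
    "cue_distance",
    "export_vtk",
    "N_TO_MN",
]

N_TO_MN = 1000.0  # 1 N = 1000 mN = 1000 kPa*mm^2


class ConfigError(ValueError):
    """Invalid geometry, layer, or solver configuration."""


class InvalidDeformationError(ValueError):
    """Deformation gradient with non-positive Jacobian."""


class SolverError(RuntimeError):
    """Newton or force-control iteration failed to converge."""


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------

#: default bulk-to-shear ratio for tissue layers (near-incompressible)
DEFAULT_BULK_RATIO = 1e5


@dataclass(frozen=True)
class NeoHookeanMaterial:
    """Neo-Hookean constants; ``c10`` in kPa, ``d1`` in 1/kPa.

    ``G = 2*c10`` and ``K = 2/d1`` exactly.
    """

    c10: float
    d1: float

    def __post_init__(self):
        if self.c10 <= 0 or self.d1 <= 0:
            raise ConfigError("c10 and d1 must be positive")

    @property
    def shear_modulus(self) -> float:
        return 2.0 * self.c10

    @property
    def bulk_modulus(self) -> float:
        return 2.0 / self.d1

    @staticmethod
    def from_moduli(shear_modulus: float, bulk_modulus: float | None = None,
                    bulk_ratio: float = DEFAULT_BULK_RATIO) -> "NeoHookeanMaterial":
        if shear_modulus <= 0:
            raise ConfigError("shear modulus must be positive")
        K = bulk_modulus if bulk_modulus is not None else bulk_ratio * shear_modulus
        return NeoHookeanMaterial(c10=shear_modulus / 2.0, d1=2.0 / K)

    @staticmethod
    def from_poisson(shear_modulus: float, poisson: float) -> "NeoHookeanMaterial":
        if not 0 < poisson < 0.5:
            raise ConfigError("Poisson ratio must lie in (0, 0.5)")
        K = 2.0 * shear_modulus * (1.0 + poisson) / (3.0 * (1.0 - 2.0 * poisson))
        return NeoHookeanMaterial.from_moduli(shear_modulus, bulk_modulus=K)


def _embed_3x3(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.shape == (2, 2):
        out = np.eye(3)
        out[:2, :2] = F
        return out
    if F.shape == (3, 3):
        return F.copy()
    raise ValueError("deformation gradient must be 2x2 or 3x3")


def strain_energy(material: NeoHookeanMaterial, deformation_gradient: np.ndarray) -> float:
    """Strain energy density (kPa) of the Neo-Hookean law.

    ``Psi = C10*(I1_bar - 3) + (1/D1)*(J - 1)**2`` with the isochoric
    invariant ``I1_bar = J**(-2/3) * tr(F F^T)``.  A 2x2 gradient is
    embedded with unit out-of-plane stretch.

    Raises
    ------
    InvalidDeformationError
        If ``det F <= 0``.
    """
    F = _embed_3x3(deformation_gradient)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidDeformationError(f"non-positive Jacobian J={J}")
    i1 = float(np.trace(F @ F.T))
    i1_bar = J ** (-2.0 / 3.0) * i1
    return material.c10 * (i1_bar - 3.0) + (1.0 / material.d1) * (J - 1.0) ** 2


def cauchy_stress(material: NeoHookeanMaterial, deformation_gradient: np.ndarray) -> np.ndarray:
    """Cauchy stress tensor (kPa, 3x3) consistent with :func:`strain_energy`.

    ``sigma = (G/J) * J**(-2/3) * dev(B) + K*(J-1)*I`` with ``B = F F^T``.

    Raises
    ------
    InvalidDeformationError
        If ``det F <= 0``.
    """
    F = _embed_3x3(deformation_gradient)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise InvalidDeformationError(f"non-positive Jacobian J={J}")
    B = F @ F.T
    G = material.shear_modulus
    K = material.bulk_modulus
    dev_B = B - np.trace(B) / 3.0 * np.eye(3)
    return (G / J) * J ** (-2.0 / 3.0) * dev_B + K * (J - 1.0) * np.eye(3)


# -- vectorized constitutive evaluation ------------------------------------

def _pk1_vec(Fv: np.ndarray, c10: np.ndarray, d1: np.ndarray, axisym: bool) -> np.ndarray:
    """First Piola-Kirchhoff components for stacked deformation gradients.

    ``Fv[..., :]`` holds [F_rR, F_rZ, F_zR, F_zZ, F_tt] (axisymmetric) or
    [F_xX, F_xY, F_yX, F_yY] (plane strain, out-of-plane stretch 1).
    """
    f00, f01, f10, f11 = Fv[..., 0], Fv[..., 1], Fv[..., 2], Fv[..., 3]
    f22 = Fv[..., 4] if axisym else np.ones_like(f00)
    det2 = f00 * f11 - f01 * f10
    J = det2 * f22
    b00 = f00 * f00 + f01 * f01
    b01 = f00 * f10 + f01 * f11
    b11 = f10 * f10 + f11 * f11
    b22 = f22 * f22
    tr_b = b00 + b11 + b22
    G = 2.0 * c10
    K = 2.0 / d1
    coef = G * J ** (-5.0 / 3.0)
    p_vol = K * (J - 1.0)
    s00 = coef * (b00 - tr_b / 3.0) + p_vol
    s01 = coef * b01
    s11 = coef * (b11 - tr_b / 3.0) + p_vol
    s22 = coef * (b22 - tr_b / 3.0) + p_vol
    # F^{-T}: in-plane block transpose-inverse, hoop 1/f22
    g00, g01 = f11 / det2, -f10 / det2
    g10, g11 = -f01 / det2, f00 / det2
    p00 = J * (s00 * g00 + s01 * g10)
    p01 = J * (s00 * g01 + s01 * g11)
    p10 = J * (s01 * g00 + s11 * g10)
    p11 = J * (s01 * g01 + s11 * g11)
    if axisym:
        p22 = J * s22 / f22
        return np.stack([p00, p01, p10, p11, p22], axis=-1)
    return np.stack([p00, p01, p10, p11], axis=-1)


def _sigma_sed_vec(Fv: np.ndarray, c10: np.ndarray, d1: np.ndarray, axisym: bool):
    """(Cauchy components [s_rr, s_zz, s_tt, s_rz], Psi) for stacked gradients."""
    f00, f01, f10, f11 = Fv[..., 0], Fv[..., 1], Fv[..., 2], Fv[..., 3]
    f22 = Fv[..., 4] if axisym else np.ones_like(f00)
    det2 = f00 * f11 - f01 * f10
    J = det2 * f22
    b00 = f00 * f00 + f01 * f01
    b01 = f00 * f10 + f01 * f11
    b11 = f10 * f10 + f11 * f11
    b22 = f22 * f22
    tr_b = b00 + b11 + b22
    G = 2.0 * c10
    K = 2.0 / d1
    coef = G * J ** (-5.0 / 3.0)
    p_vol = K * (J - 1.0)
    s00 = coef * (b00 - tr_b / 3.0) + p_vol
    s01 = coef * b01
    s11 = coef * (b11 - tr_b / 3.0) + p_vol
    s22 = coef * (b22 - tr_b / 3.0) + p_vol
    psi = (G / 2.0) * (J ** (-2.0 / 3.0) * tr_b - 3.0) + (K / 2.0) * (J - 1.0) ** 2
    return np.stack([s00, s11, s22, s01], axis=-1), psi


# ---------------------------------------------------------------------------
# finite-element body
# ---------------------------------------------------------------------------

_GAUSS = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float) / np.sqrt(3.0)
_FD_STEP = 1e-6


@dataclass
class FEBody:
    """A meshed deformable body with per-element Neo-Hookean constants."""

    nodes: np.ndarray  # (n, 2) reference coordinates (r, z) or (x, y)
    elements: np.ndarray  # (m, 4) quad connectivity, counterclockwise
    c10: np.ndarray  # (m,)
    d1: np.ndarray  # (m,)
    formulation: str

    _B: np.ndarray | None = field(default=None, repr=False)
    _dV: np.ndarray | None = field(default=None, repr=False)
    _F0: np.ndarray | None = field(default=None, repr=False)
    _edofs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.c10 = np.broadcast_to(np.asarray(self.c10, dtype=float), (len(self.elements),)).copy()
        self.d1 = np.broadcast_to(np.asarray(self.d1, dtype=float), (len(self.elements),)).copy()
        if self.formulation not in ("axisymmetric", "plane-strain"):
            raise ConfigError(f"unknown formulation {self.formulation!r}")
        self._precompute()

    @property
    def axisym(self) -> bool:
        return self.formulation == "axisymmetric"

    @property
    def n_dof(self) -> int:
        return 2 * len(self.nodes)

    def _precompute(self) -> None:
        xe = self.nodes[self.elements]  # (m, 4, 2)
        ncomp = 5 if self.axisym else 4
        m = len(self.elements)
        B = np.zeros((m, 4, ncomp, 8))
        dV = np.zeros((m, 4))
        for g, (xi, eta) in enumerate(_GAUSS):
            dN = 0.25 * np.array([
                [-(1 - eta), -(1 - xi)],
                [+(1 - eta), -(1 + xi)],
                [+(1 + eta), +(1 + xi)],
                [-(1 + eta), +(1 - xi)],
            ])
            N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                                 (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
            jac = np.einsum("ai,maj->mij", dN, xe)
            det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
            if np.any(det <= 0):
                raise ConfigError("mesh contains inverted or degenerate elements")
            inv = np.empty_like(jac)
            inv[:, 0, 0] = jac[:, 1, 1] / det
            inv[:, 0, 1] = -jac[:, 0, 1] / det
            inv[:, 1, 0] = -jac[:, 1, 0] / det
            inv[:, 1, 1] = jac[:, 0, 0] / det
            dNdX = np.einsum("ai,mij->maj", dN, inv)  # (m, 4, 2)
            for a in range(4):
                B[:, g, 0, 2 * a] = dNdX[:, a, 0]
                B[:, g, 1, 2 * a] = dNdX[:, a, 1]
                B[:, g, 2, 2 * a + 1] = dNdX[:, a, 0]
                B[:, g, 3, 2 * a + 1] = dNdX[:, a, 1]
            w = det.copy()
            if self.axisym:
                R = xe[:, :, 0] @ N
                if np.any(R <= 0):
                    raise ConfigError("axisymmetric quadrature point at r <= 0")
                for a in range(4):
                    B[:, g, 4, 2 * a] = N[a] / R
                w = w * 2.0 * np.pi * R
            dV[:, g] = w
        self._B = B
        self._dV = dV
        self._F0 = (np.array([1.0, 0, 0, 1.0, 1.0]) if self.axisym
                    else np.array([1.0, 0, 0, 1.0]))
        dof = np.empty((m, 8), dtype=np.int64)
        dof[:, 0::2] = 2 * self.elements
        dof[:, 1::2] = 2 * self.elements + 1
        self._edofs = dof

    @property
    def volume(self) -> float:
        return float(self._dV.sum())

    # -- kinematics -------------------------------------------------------

    def _jacobians(self, Fv: np.ndarray) -> np.ndarray:
        J = Fv[..., 0] * Fv[..., 3] - Fv[..., 1] * Fv[..., 2]
        if self.axisym:
            J = J * Fv[..., 4]
        return J

    def _fbar_gradients(self, u: np.ndarray, full: bool = False):
        """F-bar-modified gradient components at quadrature points, or
        None when the trial state inverts an element.  With ``full`` the
        raw gradients and Jacobians are returned as well (for tangents)."""
        ue = u[self._edofs]
        Fv = np.einsum("mgci,mi->mgc", self._B, ue) + self._F0
        J = self._jacobians(Fv)
        if J.min() <= 1e-9:
            return None
        Jbar = (J * self._dV).sum(axis=1) / self._dV.sum(axis=1)
        expo = 1.0 / 3.0 if self.axisym else 0.5
        scale = (Jbar[:, None] / J) ** expo
        Fh = Fv * scale[..., None]
        if full:
            return Fh, Fv, J, Jbar, scale
        return Fh

    def _dJdF(self, Fv: np.ndarray) -> np.ndarray:
        """dJ/dF components at each quadrature point."""
        f00, f01, f10, f11 = Fv[..., 0], Fv[..., 1], Fv[..., 2], Fv[..., 3]
        if self.axisym:
            f22 = Fv[..., 4]
            det2 = f00 * f11 - f01 * f10
            return np.stack([f11 * f22, -f10 * f22, -f01 * f22,
                             f00 * f22, det2], axis=-1)
        return np.stack([f11, -f10, -f01, f00], axis=-1)

    def internal_force(self, u: np.ndarray) -> np.ndarray | None:
        Fh = self._fbar_gradients(u)
        if Fh is None:
            return None
        P = _pk1_vec(Fh, self.c10[:, None], self.d1[:, None], self.axisym)
        f_el = np.einsum("mgci,mgc,mg->mi", self._B, P, self._dV)
        f = np.zeros(self.n_dof)
        np.add.at(f, self._edofs, f_el)
        return f

    def force_and_stiffness(self, u: np.ndarray):
        """(internal force, COO triplets) or None on element inversion.

        The tangent is consistent with the F-bar internal force: the
        material stiffness dP/dF evaluated at the modified gradient is
        contracted against dF_hat/du, which carries the element-mean
        dilatation coupling (essential for Newton convergence in the
        near-incompressible limit).
        """
        out = self._fbar_gradients(u, full=True)
        if out is None:
            return None
        Fh, Fv, J, Jbar, scale = out
        c10 = self.c10[:, None]
        d1 = self.d1[:, None]
        P = _pk1_vec(Fh, c10, d1, self.axisym)
        f_el = np.einsum("mgci,mgc,mg->mi", self._B, P, self._dV)
        f = np.zeros(self.n_dof)
        np.add.at(f, self._edofs, f_el)

        ncomp = Fh.shape[-1]
        A = np.empty(Fh.shape[:-1] + (ncomp, ncomp))
        for c in range(ncomp):
            Fp = Fh.copy()
            Fp[..., c] += _FD_STEP
            Fm = Fh.copy()
            Fm[..., c] -= _FD_STEP
            A[..., c] = (_pk1_vec(Fp, c10, d1, self.axisym)
                         - _pk1_vec(Fm, c10, d1, self.axisym)) / (2.0 * _FD_STEP)
        # A[..., d, c] = dP_d/dF_c after the loop above fills column c
        A = np.swapaxes(A, -1, -2)

        # dF_hat/du = scale * (B + expo * F_hat (dJbar/Jbar - dJ/J))
        expo = 1.0 / 3.0 if self.axisym else 0.5
        q = self._dJdF(Fv) / J[..., None]  # (m, g, c): dJ/dF / J
        t = np.einsum("mgc,mgci->mgi", q, self._B)  # dJ/du / J per gp
        tbar = np.einsum("mg,mg,mgi->mi", self._dV, J, t) \
            / (self._dV.sum(axis=1) * Jbar)[:, None]  # dJbar/du / Jbar
        Bhat = scale[..., None, None] * self._B + expo * Fh[..., :, None] \
            * (tbar[:, None, None, :] - t[:, :, None, :])
        AB = np.einsum("mgcd,mgdj->mgcj", A, Bhat, optimize=True)
        Ke = np.einsum("mgci,mgcj,mg->mij", self._B, AB, self._dV, optimize=True)
        rows = np.repeat(self._edofs, 8, axis=1).ravel()
        cols = np.tile(self._edofs, (1, 8)).ravel()
        return f, (rows, cols, Ke.ravel())

    def element_fields(self, u: np.ndarray):
        """Element-mean (Cauchy components, von Mises, SED) at state ``u``."""
        Fh = self._fbar_gradients(u)
        if Fh is None:
            raise InvalidDeformationError("state contains inverted elements")
        sig, psi = _sigma_sed_vec(Fh, self.c10[:, None], self.d1[:, None], self.axisym)
        sig_m = sig.mean(axis=1)  # (m, 4): s_rr, s_zz, s_tt, s_rz
        psi_m = psi.mean(axis=1)
        tr = (sig_m[:, 0] + sig_m[:, 1] + sig_m[:, 2]) / 3.0
        vm = np.sqrt(1.5 * ((sig_m[:, 0] - tr) ** 2 + (sig_m[:, 1] - tr) ** 2
                            + (sig_m[:, 2] - tr) ** 2 + 2.0 * sig_m[:, 3] ** 2))
        return sig_m, vm, psi_m

    def total_strain_energy(self, u: np.ndarray) -> float:
        """Stored energy (mN*mm) of the body at state ``u``."""
        Fh = self._fbar_gradients(u)
        if Fh is None:
            raise InvalidDeformationError("state contains inverted elements")
        _, psi = _sigma_sed_vec(Fh, self.c10[:, None], self.d1[:, None], self.axisym)
        return float((psi * self._dV).sum())


# ---------------------------------------------------------------------------
# fingertip model
# ---------------------------------------------------------------------------

#: epidermis depth placing the mechanoreceptor interface 470 um below the
#: skin surface
EPIDERMIS_THICKNESS_MM = 0.470

#: literature-typical layer shear moduli (kPa), the calibrated defaults
DEFAULT_LAYER_MODULI = {"epidermis": 45.9, "dermis": 27.0, "subcutaneous": 11.5}


@dataclass(frozen=True)
class LayerSpec:
    """One soft-tissue layer: name, depth extent (mm), material."""

    name: str
    thickness: float
    material: NeoHookeanMaterial

    def __post_init__(self):
        if self.thickness <= 0:
            raise ConfigError(f"layer {self.name!r} must have positive thickness")


def default_layers(moduli: dict[str, float] | None = None,
                   bulk_ratio: float = DEFAULT_BULK_RATIO,
                   dermis_thickness: float = 1.2,
                   subcutaneous_thickness: float = 4.0) -> tuple[LayerSpec, ...]:
    """Default epidermis / dermis / subcutaneous stack (bone proxy is the
    rigid support below the stack)."""
    mod = dict(DEFAULT_LAYER_MODULI)
    if moduli:
        mod.update(moduli)

    def mk(g):
        return NeoHookeanMaterial.from_moduli(g, bulk_ratio=bulk_ratio)

    return (
        LayerSpec("epidermis", EPIDERMIS_THICKNESS_MM, mk(mod["epidermis"])),
        LayerSpec("dermis", dermis_thickness, mk(mod["dermis"])),
        LayerSpec("subcutaneous", subcutaneous_thickness, mk(mod["subcutaneous"])),
    )


@dataclass(frozen=True)
class FingertipConfig:
    """Parameterized layered finger-pad geometry.

    The pad is a layered axisymmetric (or plane-strain) domain with a flat
    contact surface; the cue-sampling extent of the surface and interface
    is ``interface_extent`` covered by ``n_interface_nodes`` equally
    spaced nodes, and the pad continues with geometric coarsening out to
    ``pad_radius``.  The mechanoreceptor interface lies at
    ``interface_depth`` (defaults to the epidermis thickness, 0.470 mm).
    """

    formulation: str = "axisymmetric"
    layers: tuple[LayerSpec, ...] = ()
    pad_radius: float = 18.0
    interface_extent: float = 15.2
    n_interface_nodes: int = 111
    layer_divisions: tuple[int, ...] = (2, 3, 4)
    interface_depth: float | None = None

    def __post_init__(self):
        if self.formulation not in ("axisymmetric", "plane-strain"):
            raise ConfigError(f"unknown formulation {self.formulation!r}")
        layers = tuple(self.layers) or default_layers()
        object.__setattr__(self, "layers", layers)
        if len(self.layer_divisions) != len(layers):
            raise ConfigError("layer_divisions must match the number of layers")
        if self.n_interface_nodes < 2:
            raise ConfigError("need at least 2 interface nodes")
        if self.pad_radius < self.interface_extent:
            raise ConfigError("pad_radius must cover the interface extent")
        depth = self.interface_depth if self.interface_depth is not None \
            else layers[0].thickness
        total = sum(l.thickness for l in layers)
        if not 0 < depth < total:
            raise ConfigError("interface depth must lie inside the soft-tissue stack")
        object.__setattr__(self, "interface_depth", float(depth))


def default_fingertip_config(coarse: bool = False, **overrides) -> FingertipConfig:
    """Default axisymmetric configuration (111 interface nodes over
    0-15.2 mm); ``coarse=True`` selects a reduced mesh for quick solves."""
    kw: dict = {}
    if coarse:
        kw.update(n_interface_nodes=56, layer_divisions=(2, 3, 3))
    kw.update(overrides)
    return FingertipConfig(**kw)


@dataclass
class FingertipModel:
    """Meshed fingertip: FE body plus the labeled node sets.

    ``interface_nodes`` are ordered by arc length along the
    epidermal-dermal interface (``interface_arc``, mm, spanning
    [0, interface_extent]); ``surface_nodes`` cover the epidermis surface.
    """

    config: FingertipConfig
    body: FEBody
    element_layer: np.ndarray  # (m,) layer index
    interface_nodes: np.ndarray
    interface_arc: np.ndarray
    surface_nodes: np.ndarray
    surface_arc: np.ndarray
    bottom_nodes: np.ndarray
    axis_nodes: np.ndarray
    interface_adjacency: list = field(default_factory=list, repr=False)

    @property
    def formulation(self) -> str:
        return self.config.formulation

    @property
    def nodes(self) -> np.ndarray:
        return self.body.nodes

    @property
    def elements(self) -> np.ndarray:
        return self.body.elements


def build_fingertip_model(config: FingertipConfig | None = None) -> FingertipModel:
    """Mesh the layered finger pad described by ``config``.

    The surface and every layer boundary are grid lines; the interface
    node set is taken on the grid line at the configured interface depth
    and restricted to arc length <= ``interface_extent`` (exactly
    ``n_interface_nodes`` nodes, 111 spanning 0-15.2 mm by default).
    """
    config = config or FingertipConfig()
    # radial grid: uniform over the cue extent, geometric coarsening beyond
    r_core = np.linspace(0.0, config.interface_extent, config.n_interface_nodes)
    dr = r_core[1] - r_core[0]
    ext = []
    r = config.interface_extent
    step = dr
    while r < config.pad_radius - 1e-9:
        step *= 1.7
        r = min(r + step, config.pad_radius)
        ext.append(r)
    r_grid = np.concatenate([r_core, np.asarray(ext)]) if ext else r_core
    nr = len(r_grid)

    # vertical grid: layer boundaries are exact grid lines
    z_levels = [0.0]
    layer_of_row: list[int] = []
    top = 0.0
    for li, (layer, ndiv) in enumerate(zip(config.layers, config.layer_divisions)):
        if ndiv < 1:
            raise ConfigError("each layer needs at least one element through thickness")
        for k in range(1, ndiv + 1):
            z_levels.append(top - layer.thickness * k / ndiv)
            layer_of_row.append(li)
        top -= layer.thickness
    z_levels = np.asarray(z_levels)
    nz = len(z_levels) - 1

    iz_if = int(np.argmin(np.abs(z_levels + config.interface_depth)))
    if abs(z_levels[iz_if] + config.interface_depth) > 1e-6:
        raise ConfigError("interface depth must coincide with a layer grid line")

    nodes = np.empty(((nz + 1) * nr, 2))
    for iz, z in enumerate(z_levels):
        nodes[iz * nr:(iz + 1) * nr, 0] = r_grid
        nodes[iz * nr:(iz + 1) * nr, 1] = z

    elems = []
    layer_idx = []
    for iz in range(nz):
        for ir in range(nr - 1):
            a = (iz + 1) * nr + ir
            b = (iz + 1) * nr + ir + 1
            c = iz * nr + ir + 1
            d = iz * nr + ir
            elems.append((a, b, c, d))
            layer_idx.append(layer_of_row[iz])
    elems = np.asarray(elems, dtype=np.int64)
    layer_idx = np.asarray(layer_idx, dtype=np.int64)

    c10 = np.array([config.layers[li].material.c10 for li in layer_idx])
    d1 = np.array([config.layers[li].material.d1 for li in layer_idx])
    body = FEBody(nodes=nodes, elements=elems, c10=c10, d1=d1,
                  formulation=config.formulation)

    n_if = config.n_interface_nodes
    interface_nodes = np.array([iz_if * nr + ir for ir in range(n_if)], dtype=np.int64)
    surface_nodes = np.arange(nr, dtype=np.int64)
    bottom_nodes = np.arange(nz * nr, (nz + 1) * nr, dtype=np.int64)
    axis_nodes = np.arange(0, (nz + 1) * nr, nr, dtype=np.int64)

    # adjacency: elements touching each interface node
    node_elems: dict[int, list[int]] = {}
    for ei, conn in enumerate(elems):
        for nid in conn:
            node_elems.setdefault(int(nid), []).append(ei)
    adjacency = [np.asarray(node_elems.get(int(nid), []), dtype=np.int64)
                 for nid in interface_nodes]
    if any(len(a) == 0 for a in adjacency):
        raise ConfigError("interface node without adjacent elements")

    return FingertipModel(
        config=config, body=body, element_layer=layer_idx,
        interface_nodes=interface_nodes, interface_arc=r_grid[:n_if].copy(),
        surface_nodes=surface_nodes, surface_arc=r_grid.copy(),
        bottom_nodes=bottom_nodes, axis_nodes=axis_nodes,
        interface_adjacency=adjacency,
    )


# ---------------------------------------------------------------------------
# stimulus model
# ---------------------------------------------------------------------------

#: plate Poisson ratio mimicking nearly incompressible rubber
DEFAULT_PLATE_POISSON = 0.475


@dataclass(frozen=True)
class StimulusTip:
    """A compliant hemispherical tip bonded to a rigid plate."""

    radius: float  # mm, default grid {4, 6, 8}
    shear_modulus: float  # kPa, default grid {10, 50, 90}
    plate_poisson: float = DEFAULT_PLATE_POISSON
    fine_edge: float = 0.25  # mm, max element edge in the contact region
    coarse_edge: float = 1.0  # mm, max edge elsewhere

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigError("tip radius must be positive")
        if not 0 < self.plate_poisson < 0.5:
            raise ConfigError("plate Poisson ratio must lie in (0, 0.5)")
        if self.fine_edge > self.coarse_edge:
            raise ConfigError("fine_edge must not exceed coarse_edge")
        if self.radius <= self.fine_edge:
            raise ConfigError("tip radius must exceed the fine element edge")

    @property
    def label(self) -> str:
        return f"{self.shear_modulus:g}kPa-{self.radius:g}mm"


@dataclass
class StimulusModel:
    """Meshed hemisphere; the flat face (``plate_nodes``) is tied to the
    rigid driver, ``arc_nodes`` run pole -> equator on the sphere surface."""

    tip: StimulusTip
    body: FEBody
    plate_nodes: np.ndarray
    axis_nodes: np.ndarray
    arc_nodes: np.ndarray

    @property
    def contact_region_mask(self) -> np.ndarray:
        """Nodes in the contact-candidate (lower) half of the sphere."""
        return self.body.nodes[:, 1] <= 0.5 * self.tip.radius


def _stimulus_mesh(radius: float, n: int):
    """Quarter-disk structured grid via the elliptical square-to-disk map."""
    u = np.linspace(0.0, 1.0, n + 1)
    v = np.linspace(-1.0, 0.0, n + 1)
    uu, vv = np.meshgrid(u, v, indexing="xy")  # row j -> v[j], col i -> u[i]
    x = radius * uu * np.sqrt(1.0 - vv**2 / 2.0)
    y = radius * vv * np.sqrt(1.0 - uu**2 / 2.0)
    nodes = np.column_stack([x.ravel(), (radius + y).ravel()])  # pole at z=0
    elems = []
    for j in range(n):
        for i in range(n):
            a = j * (n + 1) + i
            b = j * (n + 1) + i + 1
            c = (j + 1) * (n + 1) + i + 1
            d = (j + 1) * (n + 1) + i
            elems.append((a, b, c, d))
    return nodes, np.asarray(elems, dtype=np.int64)


def _max_edge(nodes: np.ndarray, elems: np.ndarray, mask: np.ndarray) -> float:
    """Longest element edge with both end nodes inside ``mask``."""
    best = 0.0
    for k in range(4):
        a = elems[:, k]
        b = elems[:, (k + 1) % 4]
        sel = mask[a] & mask[b]
        if sel.any():
            d = np.linalg.norm(nodes[a[sel]] - nodes[b[sel]], axis=1)
            best = max(best, float(d.max()))
    return best


def build_stimulus_model(tip: StimulusTip, formulation: str = "axisymmetric",
                         mesh_scale: float = 1.0) -> StimulusModel:
    """Mesh a hemispherical tip with its flat face tied to the rigid plate.

    The mesh is refined until every edge in the contact-candidate region
    (lower half of the sphere) is at most ``tip.fine_edge * mesh_scale``;
    ``mesh_scale > 1`` coarsens uniformly for quick solves.
    """
    fine = tip.fine_edge * mesh_scale
    coarse = tip.coarse_edge * mesh_scale
    n = max(4, int(np.ceil(1.2 * tip.radius / fine)))
    for _ in range(5):
        nodes, elems = _stimulus_mesh(tip.radius, n)
        contact_mask = nodes[:, 1] <= 0.5 * tip.radius
        if _max_edge(nodes, elems, contact_mask) <= fine and \
           _max_edge(nodes, elems, np.ones(len(nodes), bool)) <= coarse:
            break
        n = int(np.ceil(n * 1.3))
    mat = NeoHookeanMaterial.from_poisson(tip.shear_modulus, tip.plate_poisson)
    body = FEBody(nodes=nodes, elements=elems, c10=mat.c10, d1=mat.d1,
                  formulation=formulation)
    plate = np.arange(n * (n + 1), (n + 1) * (n + 1), dtype=np.int64)  # v=0 row
    axis = np.arange(0, (n + 1) * (n + 1), n + 1, dtype=np.int64)  # u=0 column
    arc = list(range(0, n + 1))  # v=-1 row, pole -> 45 degrees
    arc += [j * (n + 1) + n for j in range(1, n + 1)]  # u=1 column, -> equator
    arc = np.asarray([a for a in arc if a not in set(plate.tolist())], dtype=np.int64)
    return StimulusModel(tip=tip, body=body, plate_nodes=plate,
                         axis_nodes=axis, arc_nodes=arc)


# ---------------------------------------------------------------------------
# contact problem and solver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolverParams:
    """Penalty-contact Newton solver controls (units mm / kPa / mN)."""

    penalty_factor: float = 100.0  # x softer G / surface spacing
    force_rtol: float = 1e-3  # Newton: residual 2-norm vs contact force
    disp_tol: float = 1e-6  # Newton: step infinity-norm (mm)
    max_newton: int = 30
    force_match_rtol: float = 0.01  # force-control: |F - target| / target
    init_step: float = 0.02  # mm of driver travel
    max_step: float = 0.30
    min_step: float = 1e-5
    max_travel: float = 25.0
    record_path: bool = True


@dataclass
class ContactProblem:
    """A force-controlled fingertip-stimulus contact simulation.

    ``mode='passive'`` drives the stimulus plate into the fixed fingertip;
    ``mode='active'`` drives the fingertip base into the fixed stimulus.
    ``load_schedule`` lists the terminal normal forces (N) at which full
    solution states are reported.
    """

    fingertip: FingertipModel
    stimulus: StimulusTip | StimulusModel
    mode: str = "passive"
    load_schedule: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0)
    ramp_resolution: int = 8  # force sub-steps per N for ramp-phase output
    solver: SolverParams = field(default_factory=SolverParams)
    stimulus_mesh_scale: float = 1.0

    def __post_init__(self):
        if self.mode not in ("passive", "active"):
            raise ConfigError(f"mode must be 'passive' or 'active', got {self.mode!r}")
        sched = tuple(float(f) for f in self.load_schedule)
        if not sched:
            raise ConfigError("load_schedule must not be empty")
        if any(f < 0 for f in sched) or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigError("load_schedule must be strictly increasing and non-negative")
        object.__setattr__(self, "load_schedule", sched)
        if isinstance(self.stimulus, StimulusTip):
            model = build_stimulus_model(self.stimulus,
                                         formulation=self.fingertip.formulation,
                                         mesh_scale=self.stimulus_mesh_scale)
            object.__setattr__(self, "stimulus", model)


@dataclass
class SolutionState:
    """One converged equilibrium state of a contact problem."""

    mode: str
    load: float  # achieved normal force (N)
    rigid_body_travel: float  # driver travel (mm)
    finger_displacements: np.ndarray  # (n_f, 2) mm
    stimulus_displacements: np.ndarray | None  # (n_s, 2) mm
    finger_stress: np.ndarray  # (m, 4) element Cauchy [s_rr, s_zz, s_tt, s_rz]
    finger_vm: np.ndarray  # (m,) von Mises (kPa)
    finger_sed: np.ndarray  # (m,) strain energy density (kPa)
    stimulus_sed: np.ndarray | None
    strain_energy: float  # total stored energy, both bodies (mN*mm)
    contact_pressure: np.ndarray | None = None  # (n_active, 2): radius, kPa


class ContactSolution(Sequence):
    """Ordered solution states plus the recorded loading path."""

    def __init__(self, states: list[SolutionState], path: np.ndarray, mode: str):
        self.states = states
        self.path = path  # (k, 2): travel (mm), force (N)
        self.mode = mode

    def __len__(self):
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]


class _ContactSystem:
    """Assembled two-body (or body + rigid indenter) contact system."""

    def __init__(self, model: FingertipModel, stimulus: StimulusModel | None,
                 mode: str, params: SolverParams,
                 rigid_radius: float | None = None):
        self.model = model
        self.stim = stimulus
        self.mode = mode
        self.params = params
        self.rigid_radius = rigid_radius
        self.nf = model.body.n_dof
        self.ns = stimulus.body.n_dof if stimulus is not None else 0
        self.ndof = self.nf + self.ns
        self.axisym = model.body.axisym

        surf = model.surface_nodes
        h_surf = float(np.median(np.diff(model.body.nodes[surf, 0])))
        g_finger = 2.0 * model.body.c10.min()
        g_soft = g_finger if stimulus is None else min(g_finger,
                                                       stimulus.tip.shear_modulus)
        self.penalty = params.penalty_factor * g_soft / h_surf  # kPa/mm

        fixed = np.zeros(self.ndof, dtype=bool)
        fixed[2 * model.axis_nodes] = True  # u_r = 0 on the symmetry axis
        fixed[2 * model.bottom_nodes] = True
        fixed[2 * model.bottom_nodes + 1] = True
        self.finger_driver = (mode == "active")
        if stimulus is not None:
            off = self.nf
            fixed[off + 2 * stimulus.axis_nodes] = True
            # normal-direction tie to the rigid plate: radial slip along the
            # plate face avoids the corner singularity of a bonded face
            # while transmitting the full normal load
            fixed[off + 2 * stimulus.plate_nodes + 1] = True
        self.fixed = fixed
        self.free = ~fixed
        if self.finger_driver:
            self.driver_zdofs = 2 * model.bottom_nodes + 1
        elif stimulus is not None:
            self.driver_zdofs = self.nf + 2 * stimulus.plate_nodes + 1
        else:
            self.driver_zdofs = None  # rigid indenter: use contact sum

    def prescribed(self, travel: float) -> np.ndarray:
        vals = np.zeros(self.ndof)
        if self.finger_driver:
            vals[2 * self.model.bottom_nodes + 1] = travel
        elif self.stim is not None:
            vals[self.nf + 2 * self.stim.plate_nodes + 1] = -travel
        return vals

    # -- contact ----------------------------------------------------------

    def _slave_coords(self, u: np.ndarray, travel: float):
        if self.stim is not None:
            xs = self.stim.body.nodes[self.stim.arc_nodes] + \
                u[self.nf:].reshape(-1, 2)[self.stim.arc_nodes]
            return xs
        return None

    def contact(self, u: np.ndarray, travel: float):
        """Penalty contact forces, stiffness triplets and total normal force."""
        mdl = self.model
        uf = u[:self.nf].reshape(-1, 2)
        surf = mdl.surface_nodes
        xs_m = mdl.body.nodes[surf] + uf[surf]
        rs, zs = xs_m[:, 0], xs_m[:, 1]

        f = np.zeros(self.ndof)
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        data: list[np.ndarray] = []
        total = 0.0

        if self.stim is not None:
            # Vertical-gap penalty with the fingertip surface (the finer
            # discretization) as slave against the interpolated underside
            # of the stimulus (monotone-r prefix of its arc, up to the
            # widest bulge point).  The contact normal stays aligned with
            # the drive axis, which keeps the linearized system free of
            # normal-rotation chatter and matches the normal-contact
            # geometry.
            arc = self.stim.arc_nodes
            off = self.nf
            xsl = self.stim.body.nodes[arc] + u[off:].reshape(-1, 2)[arc]
            r_arc, z_arc = xsl[:, 0], xsl[:, 1]
            keep = np.nonzero(np.diff(r_arc) <= 0)[0]
            stop = (keep[0] + 1) if len(keep) else len(r_arc)
            if stop >= 2:
                total += self._vertical_pass(
                    f, rows, cols, data,
                    rs, zs, 2 * surf + 1, self._tributary(rs),
                    r_arc[:stop], z_arc[:stop], off + 2 * arc[:stop] + 1,
                    sign=-1.0)
        else:
            # rigid spherical indenter driven down the symmetry axis
            Ri = self.rigid_radius
            zc = Ri - travel
            xs_f = xs_m
            d = xs_f - np.array([0.0, zc])
            dist = np.linalg.norm(d, axis=1)
            gap = dist - Ri
            active = (gap < 0) & (xs_f[:, 0] < Ri)
            if active.any():
                ai = np.nonzero(active)[0]
                k = self.penalty
                areas = self._tributary(rs)
                A = areas[ai]
                n_a = d[ai] / dist[ai][:, None]
                fmag = -k * gap[ai] * A
                total += float((fmag * (-n_a[:, 1])).sum())
                dofs = 2 * surf[ai]
                np.add.at(f, dofs, fmag * n_a[:, 0])
                np.add.at(f, dofs + 1, fmag * n_a[:, 1])
                blk = (k * A)[:, None, None] * n_a[:, :, None] * n_a[:, None, :]
                D = np.column_stack([dofs, dofs + 1])
                rows.append(np.repeat(D, 2, axis=1).ravel())
                cols.append(np.tile(D, (1, 2)).ravel())
                data.append(blk.ravel())

        trips = (np.concatenate(rows) if rows else np.empty(0, np.int64),
                 np.concatenate(cols) if cols else np.empty(0, np.int64),
                 np.concatenate(data) if data else np.empty(0))
        return f, trips, total

    def _vertical_pass(self, f, rows, cols, data, r_sl, z_sl, sl_zdofs, areas,
                       r_m, z_m, m_zdofs, sign: float) -> float:
        """One penalty pass of slave nodes against an interpolated master
        height profile.  ``sign=+1`` keeps slaves above the master,
        ``sign=-1`` keeps them below.  Returns the transmitted force (mN).
        """
        j = np.clip(np.searchsorted(r_m, r_sl) - 1, 0, len(r_m) - 2)
        denom = r_m[j + 1] - r_m[j]
        tloc = np.clip((r_sl - r_m[j]) / np.where(denom == 0, 1.0, denom), 0.0, 1.0)
        z_surf = z_m[j] * (1 - tloc) + z_m[j + 1] * tloc
        gap = sign * (z_sl - z_surf)
        active = (gap < 0) & (r_sl >= r_m[0]) & (r_sl <= r_m[-1])
        if not active.any():
            return 0.0
        ai = np.nonzero(active)[0]
        k = self.penalty
        A = areas[ai]
        g = gap[ai]
        w1 = -(1.0 - tloc[ai])
        w2 = -tloc[ai]
        fmag = -k * g * A  # force magnitude transmitted at each slave node
        W = np.column_stack([np.ones_like(w1), w1, w2])
        D = np.column_stack([sl_zdofs[ai], m_zdofs[j[ai]], m_zdofs[j[ai] + 1]])
        for p in range(3):
            np.add.at(f, D[:, p], sign * fmag * W[:, p])
        blk = (k * A)[:, None, None] * W[:, :, None] * W[:, None, :]
        rows.append(np.repeat(D, 3, axis=1).ravel())
        cols.append(np.tile(D, (1, 3)).ravel())
        data.append(blk.ravel())
        return float(fmag.sum())

    def contact_pressures(self, u: np.ndarray, travel: float) -> np.ndarray:
        """(radius, normal traction kPa) at active contact nodes."""
        mdl = self.model
        uf = u[:self.nf].reshape(-1, 2)
        surf = mdl.surface_nodes
        xs_m = mdl.body.nodes[surf] + uf[surf]
        rs, zs = xs_m[:, 0], xs_m[:, 1]
        if self.stim is not None:
            arc = self.stim.arc_nodes
            xsl = self.stim.body.nodes[arc] + u[self.nf:].reshape(-1, 2)[arc]
            r_arc, z_arc = xsl[:, 0], xsl[:, 1]
            keep = np.nonzero(np.diff(r_arc) <= 0)[0]
            stop = (keep[0] + 1) if len(keep) else len(r_arc)
            r_m, z_m = r_arc[:stop], z_arc[:stop]
            j = np.clip(np.searchsorted(r_m, rs) - 1, 0, len(r_m) - 2)
            denom = r_m[j + 1] - r_m[j]
            tloc = np.clip((rs - r_m[j]) / np.where(denom == 0, 1.0, denom), 0, 1)
            gap = (z_m[j] * (1 - tloc) + z_m[j + 1] * tloc) - zs
            active = (gap < 0) & (rs >= r_m[0]) & (rs <= r_m[-1])
            return np.column_stack([rs[active], -self.penalty * gap[active]])
        zc = self.rigid_radius - travel
        d = xs_m - np.array([0.0, zc])
        dist = np.linalg.norm(d, axis=1)
        gap = dist - self.rigid_radius
        active = (gap < 0) & (rs < self.rigid_radius)
        return np.column_stack([rs[active], -self.penalty * gap[active]])

    def _tributary(self, r_sorted: np.ndarray) -> np.ndarray:
        """Per-node contact areas from radial tributary intervals."""
        r = np.asarray(r_sorted, dtype=float)
        mids = 0.5 * (r[:-1] + r[1:])
        lo = np.concatenate([[max(0.0, r[0] - (mids[0] - r[0]) if len(mids) else 0.0)], mids])
        hi = np.concatenate([mids, [r[-1]]])
        lo = np.minimum(lo, hi)
        if self.axisym:
            return np.pi * (hi**2 - lo**2)
        return hi - lo

    # -- Newton -----------------------------------------------------------

    def _residual(self, u: np.ndarray, travel: float):
        f_int = np.zeros(self.ndof)
        fb = self.model.body.internal_force(u[:self.nf])
        if fb is None:
            return None
        f_int[:self.nf] = fb
        if self.stim is not None:
            fs = self.stim.body.internal_force(u[self.nf:])
            if fs is None:
                return None
            f_int[self.nf:] = fs
        f_c, _, total = self.contact(u, travel)
        return f_int - f_c, total

    def _force(self, R: np.ndarray, contact_total: float) -> float:
        """Achieved normal force (mN): driver reaction, or the penalty sum
        for the rigid indenter."""
        if self.driver_zdofs is None:
            return contact_total
        return abs(float(R[self.driver_zdofs].sum()))

    def newton(self, u0: np.ndarray, travel: float):
        """Solve equilibrium at fixed driver travel; returns (u, force_mN)
        or None on failure."""
        p = self.params
        u = u0.copy()
        if self.driver_zdofs is not None:
            # rigid-translation warm start of the driven body
            target = travel if self.finger_driver else -travel
            delta = target - u[self.driver_zdofs[0]]
            if self.finger_driver:
                u[1:self.nf:2] += delta
            else:
                u[self.nf + 1::2] += delta
        u[self.fixed] = self.prescribed(travel)[self.fixed]
        res = self._residual(u, travel)
        if res is None:
            return None
        R, Fn = res
        norm = np.linalg.norm(R[self.free])
        norm0 = max(norm, 1.0)
        for _ in range(p.max_newton):
            scale = max(1.0, Fn)
            if norm <= p.force_rtol * scale:
                return u, self._force(R, Fn)
            fb = self.model.body.force_and_stiffness(u[:self.nf])
            if fb is None:
                return None
            f_int = np.zeros(self.ndof)
            f_int[:self.nf] = fb[0]
            rows = [fb[1][0]]
            cols = [fb[1][1]]
            data = [fb[1][2]]
            if self.stim is not None:
                fs = self.stim.body.force_and_stiffness(u[self.nf:])
                if fs is None:
                    return None
                f_int[self.nf:] = fs[0]
                rows.append(fs[1][0] + self.nf)
                cols.append(fs[1][1] + self.nf)
                data.append(fs[1][2])
            f_c, ctrips, Fn = self.contact(u, travel)
            rows.append(ctrips[0])
            cols.append(ctrips[1])
            data.append(ctrips[2])
            R = f_int - f_c
            norm = np.linalg.norm(R[self.free])
            scale = max(1.0, Fn)
            if norm <= p.force_rtol * scale:
                return u, self._force(R, Fn)
            K = coo_matrix((np.concatenate(data),
                            (np.concatenate(rows), np.concatenate(cols))),
                           shape=(self.ndof, self.ndof)).tocsr()
            Kff = K[self.free][:, self.free]
            du = spsolve(Kff, -R[self.free])
            if not np.all(np.isfinite(du)):
                return None
            if norm > 50.0 * max(norm0, p.force_rtol * scale):
                return None  # diverging: cut the travel step instead
            best = None
            for alpha in (1.0, 0.5, 0.25, 0.1, 0.05):
                u_try = u.copy()
                u_try[self.free] += alpha * du
                res = self._residual(u_try, travel)
                if res is None:
                    continue
                R_try, Fn_try = res
                n_try = np.linalg.norm(R_try[self.free])
                if best is None or n_try < best[0]:
                    best = (n_try, u_try, R_try, Fn_try, alpha)
                if n_try < (1.0 - 1e-4 * alpha) * norm:
                    break
            if best is None:
                return None
            norm, u, R, Fn, alpha = best
            if alpha * np.max(np.abs(du)) < p.disp_tol:
                scale = max(1.0, Fn)
                if norm <= 10.0 * p.force_rtol * scale:
                    return u, self._force(R, Fn)
                return None
        scale = max(1.0, Fn)
        if norm <= 10.0 * p.force_rtol * scale:
            # accept mildly unconverged states rather than failing the ramp
            return u, self._force(R, Fn)
        return None


def _make_state(system: _ContactSystem, u: np.ndarray, travel: float,
                force_mN: float) -> SolutionState:
    mdl = system.model
    sig, vm, sed = mdl.body.element_fields(u[:system.nf])
    energy = mdl.body.total_strain_energy(u[:system.nf])
    stim_disp = None
    stim_sed = None
    if system.stim is not None:
        us = u[system.nf:]
        stim_disp = us.reshape(-1, 2).copy()
        _, _, stim_sed = system.stim.body.element_fields(us)
        energy += system.stim.body.total_strain_energy(us)
    return SolutionState(
        mode=system.mode, load=force_mN / N_TO_MN, rigid_body_travel=travel,
        finger_displacements=u[:system.nf].reshape(-1, 2).copy(),
        stimulus_displacements=stim_disp,
        finger_stress=sig, finger_vm=vm, finger_sed=sed,
        stimulus_sed=stim_sed, strain_energy=energy,
        contact_pressure=system.contact_pressures(u, travel),
    )


def _sweep_to_targets(system: _ContactSystem, targets_N: Sequence[float]):
    """Advance driver travel until every target force is matched within
    tolerance; returns (states, path)."""
    p = system.params
    targets = [t * N_TO_MN for t in targets_N]
    states: dict[float, SolutionState] = {}
    u = np.zeros(system.ndof)
    travel, force = 0.0, 0.0
    path = [(0.0, 0.0)]
    cache: list[tuple[float, np.ndarray, float]] = [(0.0, u.copy(), 0.0)]
    pending = sorted(targets)
    for tgt in list(pending):
        if tgt <= 0.0:
            states[tgt] = _make_state(system, u, 0.0, 0.0)
            pending.remove(tgt)
    step = p.init_step
    while pending:
        if travel + step > p.max_travel:
            raise SolverError(f"driver travel exceeded {p.max_travel} mm before "
                              f"reaching {pending[0] / N_TO_MN:.3g} N")
        t_try = travel + step
        sol = system.newton(u, t_try)
        if sol is None:
            step *= 0.5
            if step < p.min_step:
                raise SolverError("Newton failed to converge at minimum travel step")
            continue
        u_new, F_new = sol
        path.append((t_try, F_new / N_TO_MN))
        cache.append((t_try, u_new.copy(), F_new))
        if len(cache) > 12:
            cache.pop(1)
        while pending and F_new >= pending[0] * (1.0 - p.force_match_rtol):
            tgt = pending[0]
            state = _refine_target(system, cache, (travel, force), (t_try, F_new), tgt)
            states[tgt] = state
            pending.pop(0)
        travel, force, u = t_try, F_new, u_new
        step = min(step * 1.4, p.max_step)
    ordered = [states[t * N_TO_MN] for t in targets_N]
    return ordered, np.asarray(path)


def _refine_target(system: _ContactSystem, cache, lo, hi, tgt_mN):
    """Refine the driver travel to hit a target force within tolerance.

    Damped Newton continuation on the monotone force-travel relation,
    always warm-started from the nearest converged state below the
    current guess.
    """
    p = system.params
    (t_lo, F_lo), (t_hi, F_hi) = lo, hi
    if abs(F_hi - tgt_mN) <= p.force_match_rtol * tgt_mN:
        t_c, u_c, F_c = min(cache, key=lambda c: abs(c[0] - t_hi))
        if abs(t_c - t_hi) < 1e-12:
            return _make_state(system, u_c, t_hi, F_hi)
    # start from the converged state just below the target
    below = [c for c in cache if c[2] <= tgt_mN * (1.0 + p.force_match_rtol)]
    t_a, u_a, F_a = max(below, key=lambda c: c[0]) if below else cache[0]
    slope = max((F_hi - F_lo) / max(t_hi - t_lo, 1e-12), 1e-6)
    damp = 1.0
    for _ in range(25):
        if abs(F_a - tgt_mN) <= p.force_match_rtol * tgt_mN:
            return _make_state(system, u_a, t_a, F_a)
        delta = damp * (tgt_mN - F_a) / slope
        if abs(delta) < 1e-9:
            break
        t_g = t_a + delta
        sol = system.newton(u_a, t_g)
        if sol is None:
            damp *= 0.4
            continue
        u_g, F_g = sol
        cache.append((t_g, u_g.copy(), F_g))
        if abs(t_g - t_a) > 1e-12 and F_g != F_a:
            slope = max((F_g - F_a) / (t_g - t_a), 1e-6) if t_g > t_a else slope
        if F_g <= tgt_mN * (1.0 + p.force_match_rtol):
            t_a, u_a, F_a = t_g, u_g, F_g
            damp = min(1.0, damp * 1.5)
        else:
            # overshot the band: shrink the next extrapolation
            damp *= 0.6
            if F_g < F_hi:
                t_hi, F_hi = t_g, F_g
    raise SolverError(f"could not match target force {tgt_mN / N_TO_MN:.3g} N "
                      f"within {100 * p.force_match_rtol:.1f}%")


def solve_contact(problem: ContactProblem, include_ramp: bool = False) -> ContactSolution:
    """Solve the force-controlled contact problem.

    Returns one :class:`SolutionState` per scheduled load (ordered), with
    the full recorded loading path on the result.  ``include_ramp`` adds
    intermediate states at ``ramp_resolution`` equal force sub-steps per
    newton up to the terminal load (the quasi-static ramp phase).
    """
    stim = problem.stimulus
    system = _ContactSystem(problem.fingertip, stim, problem.mode, problem.solver)
    targets = list(problem.load_schedule)
    if include_ramp and problem.ramp_resolution > 0:
        f_max = max(targets)
        n_sub = int(np.ceil(f_max * problem.ramp_resolution))
        sub = [f_max * (k + 1) / n_sub for k in range(n_sub)]
        targets = sorted(set(round(t, 9) for t in targets + sub))
    states, path = _sweep_to_targets(system, targets)
    by_force = {round(t, 9): s for t, s in zip(targets, states)}
    ordered = [by_force[round(t, 9)] for t in sorted(set(targets))]
    return ContactSolution(states=ordered, path=path, mode=problem.mode)


def solve_rigid_indentation(model: FingertipModel, indenter_radius: float,
                            travels: Sequence[float],
                            params: SolverParams | None = None) -> list[SolutionState]:
    """Displacement-controlled indentation by a rigid sphere/cylinder.

    Used for material calibration: the indenter apex starts at the skin
    surface and is driven to each travel (mm) in turn; returns one state
    per requested travel (achieved force recorded on the state).
    """
    params = params or SolverParams()
    if indenter_radius <= 0:
        raise ConfigError("indenter radius must be positive")
    system = _ContactSystem(model, None, "passive", params,
                            rigid_radius=indenter_radius)
    travels = sorted(float(t) for t in travels)
    if any(t < 0 for t in travels):
        raise ConfigError("indenter travels must be non-negative")
    states = []
    u = np.zeros(system.ndof)
    current = 0.0
    for t_target in travels:
        if t_target == 0.0:
            states.append(_make_state(system, u, 0.0, 0.0))
            continue
        step = max(params.init_step, (t_target - current) / 8.0)
        while current < t_target - 1e-12:
            t_try = min(current + step, t_target)
            sol = system.newton(u, t_try)
            if sol is None:
                step *= 0.5
                if step < params.min_step:
                    raise SolverError("rigid indentation failed to converge")
                continue
            u, Fn = sol
            current = t_try
            step = min(step * 1.4, params.max_step)
        states.append(_make_state(system, u, current, Fn))
    return states


# ---------------------------------------------------------------------------
# cue profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CueProfile:
    """A cutaneous cue sampled along an arc: stress / SED at the
    epidermal-dermal interface, or skin-surface deflection."""

    locations: np.ndarray  # arc length (mm)
    values: np.ndarray
    load: float  # N
    cue: str
    stimulus_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "locations", np.asarray(self.locations, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.locations.shape != self.values.shape:
            raise ValueError("locations and values must align")


def _node_average(model: FingertipModel, element_values: np.ndarray) -> np.ndarray:
    return np.array([element_values[adj].mean()
                     for adj in model.interface_adjacency])


def interface_stress_profile(state: SolutionState, model: FingertipModel,
                             measure: str = "von_mises",
                             stimulus_id: str = "") -> CueProfile:
    """Stress (kPa) at the epidermal-dermal interface vs arc length.

    Each interface node carries the arithmetic mean of the chosen scalar
    stress over its adjacent elements (von Mises by default; ``"normal"``
    selects the normal component sigma_zz).  111 samples spanning
    0-15.2 mm under the default configuration.
    """
    if measure == "von_mises":
        ev = state.finger_vm
    elif measure == "normal":
        ev = np.abs(state.finger_stress[:, 1])
    else:
        raise ValueError(f"unknown stress measure {measure!r}")
    return CueProfile(locations=model.interface_arc,
                      values=_node_average(model, ev),
                      load=state.load, cue=f"stress:{measure}",
                      stimulus_id=stimulus_id)


def interface_sed_profile(state: SolutionState, model: FingertipModel,
                          stimulus_id: str = "") -> CueProfile:
    """Strain energy density (kPa) at the interface, neighbor-averaged."""
    return CueProfile(locations=model.interface_arc,
                      values=_node_average(model, state.finger_sed),
                      load=state.load, cue="sed", stimulus_id=stimulus_id)


def surface_deflection_profile(state: SolutionState, model: FingertipModel,
                               stimulus_id: str = "") -> CueProfile:
    """Normal skin-surface deflection (mm, positive into the finger).

    In active mode the rigid-body travel of the driven base is subtracted
    so the deflection is measured relative to the bone.
    """
    uz = state.finger_displacements[model.surface_nodes, 1]
    base = state.rigid_body_travel if state.mode == "active" else 0.0
    return CueProfile(locations=model.surface_arc, values=-(uz - base),
                      load=state.load, cue="deflection", stimulus_id=stimulus_id)


def cue_distance(a: CueProfile, b: CueProfile) -> float:
    """Normalized RMS difference between two cue profiles.

    Profiles are linearly resampled onto their common arc-length range;
    the RMS of the pointwise difference is normalized by the RMS of the
    pooled profile values, so 0 means identical and values near or above
    1 mean entirely dissimilar.

    Raises
    ------
    ValueError
        If the profiles' location ranges do not overlap.
    """
    lo = max(a.locations.min(), b.locations.min())
    hi = min(a.locations.max(), b.locations.max())
    if hi <= lo:
        raise ValueError("cue profiles do not overlap in location")
    grid = a.locations[(a.locations >= lo) & (a.locations <= hi)]
    if grid.size < 2:
        grid = np.linspace(lo, hi, 16)
    av = np.interp(grid, a.locations, a.values)
    bv = np.interp(grid, b.locations, b.values)
    pooled = np.sqrt(np.mean(np.concatenate([av, bv]) ** 2))
    if pooled == 0.0:
        return 0.0
    return float(np.sqrt(np.mean((av - bv) ** 2)) / pooled)


# ---------------------------------------------------------------------------
# force-displacement (proprioceptive cue)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceDisplacement:
    """Fingertip force-displacement relation (proprioceptive cue)."""

    force: np.ndarray  # N, non-decreasing, starts at 0
    displacement: np.ndarray  # mm, non-decreasing, starts at 0

    def displacement_at(self, force: float | np.ndarray) -> np.ndarray:
        f = np.asarray(force, dtype=float)
        if np.any(f < self.force.min() - 1e-9) or np.any(f > self.force.max() + 1e-9):
            raise ValueError("force outside the solved range")
        return np.interp(f, self.force, self.displacement)

    def force_at(self, displacement: float | np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(displacement, dtype=float),
                         self.displacement, self.force)


def force_displacement_curve(states: Iterable[SolutionState] | ContactSolution) -> ForceDisplacement:
    """Force (N) vs fingertip travel (mm) from solved active-mode states.

    When given a full :class:`ContactSolution` the recorded loading path
    is used (dense); a bare list of states uses their terminal points.
    Includes the origin (0 N, 0 mm).

    Raises
    ------
    ValueError
        If fewer than 2 states are given or modes are mixed.
    """
    if isinstance(states, ContactSolution):
        modes = {states.mode}
        pts = [(f, t) for t, f in states.path]
    else:
        states = list(states)
        modes = {s.mode for s in states}
        pts = [(s.load, s.rigid_body_travel) for s in states]
    if len(modes) != 1:
        raise ValueError("states mix passive and active modes")
    if len(pts) < 2:
        raise ValueError("need at least 2 solved states")
    pts = sorted(set(pts))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    f = np.array([p[0] for p in pts])
    d = np.array([p[1] for p in pts])
    d = np.maximum.accumulate(d)
    return ForceDisplacement(force=f, displacement=d)


# ---------------------------------------------------------------------------
# inspection output
# ---------------------------------------------------------------------------

def export_vtk(path, body: FEBody, displacements: np.ndarray | None = None,
               point_data: dict[str, np.ndarray] | None = None,
               cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (optionally deformed) as ASCII legacy VTK."""
    nodes = body.nodes.copy()
    if displacements is not None:
        nodes = nodes + np.asarray(displacements).reshape(-1, 2)
    lines = ["# vtk DataFile Version 3.0", "tactillusion mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {len(nodes)} float"]
    lines += [f"{x:.6g} {y:.6g} 0" for x, y in nodes]
    m = len(body.elements)
    lines.append(f"CELLS {m} {5 * m}")
    lines += ["4 " + " ".join(map(str, conn)) for conn in body.elements]
    lines.append(f"CELL_TYPES {m}")
    lines += ["9"] * m
    if point_data:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, arr in point_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6g}" for v in np.asarray(arr).ravel()]
    if cell_data:
        lines.append(f"CELL_DATA {m}")
        for name, arr in cell_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.6g}" for v in np.asarray(arr).ravel()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
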