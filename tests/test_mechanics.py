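"""Constitutive law, meshing, contact solver, and cue extraction."""

import numpy as np
import pytest
import sympy

import tactillusion.mechanics as mech
from tactillusion.mechanics import (
    ConfigError,
    ContactProblem,
    CueProfile,
    FEBody,
    FingertipConfig,
    InvalidDeformationError,
    LayerSpec,
    NeoHookeanMaterial,
    StimulusTip,
    build_fingertip_model,
    build_stimulus_model,
    cauchy_stress,
    cue_distance,
    default_fingertip_config,
    force_displacement_curve,
    interface_sed_profile,
    interface_stress_profile,
    solve_rigid_indentation,
    strain_energy,
    surface_deflection_profile,
)

MAT = NeoHookeanMaterial.from_moduli(20.0, bulk_ratio=1e5)


class TestConstitutiveLaw:
    def test_undeformed_reference_state(self):
        assert strain_energy(MAT, np.eye(3)) == 0.0
        assert np.allclose(cauchy_stress(MAT, np.eye(3)), 0.0)

    def test_isochoric_simple_shear(self):
        gamma = 0.37
        F = np.eye(3)
        F[0, 1] = gamma
        assert strain_energy(MAT, F) == pytest.approx(MAT.c10 * gamma**2)

    def test_random_gradient_matches_symbolic_evaluation(self):
        """Independent oracle: exact rational evaluation of the energy."""
        Fq = sympy.Matrix([
            [sympy.Rational(11, 10), sympy.Rational(1, 5), sympy.Rational(-1, 10)],
            [sympy.Rational(1, 20), sympy.Rational(9, 10), sympy.Rational(3, 20)],
            [sympy.Rational(-1, 5), sympy.Rational(1, 10), sympy.Rational(21, 20)],
        ])
        c10, d1 = sympy.Rational(10), sympy.Rational(MAT.d1)
        J = Fq.det()
        i1 = sympy.trace(Fq * Fq.T)
        psi = c10 * (J ** sympy.Rational(-2, 3) * i1 - 3) + (1 / d1) * (J - 1) ** 2
        expected = float(psi.evalf(30))
        got = strain_energy(NeoHookeanMaterial(c10=10.0, d1=MAT.d1),
                            np.array(Fq.evalf(30), dtype=float))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_pure_dilation_is_hydrostatic(self):
        F = 1.02 * np.eye(3)
        sig = cauchy_stress(MAT, F)
        assert np.allclose(sig - sig[0, 0] * np.eye(3), 0.0, atol=1e-9)
        assert sig[0, 0] > 0  # expansion -> tension

    def test_stress_matches_energy_derivative(self):
        """P = J sigma F^-T must equal the gradient of the energy."""
        rng = np.random.default_rng(3)
        F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        assert np.linalg.det(F) > 0
        sig = cauchy_stress(MAT, F)
        P_an = np.linalg.det(F) * sig @ np.linalg.inv(F).T
        h = 1e-6
        P_fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                P_fd[i, j] = (strain_energy(MAT, Fp) - strain_energy(MAT, Fm)) / (2 * h)
        assert np.abs(P_an - P_fd).max() / np.abs(P_fd).max() < 1e-4

    def test_non_positive_jacobian_rejected(self):
        F = np.eye(3)
        F[0, 0] = -1.0
        with pytest.raises(InvalidDeformationError):
            strain_energy(MAT, F)
        with pytest.raises(InvalidDeformationError):
            cauchy_stress(MAT, F)

    def test_modulus_relations_exact(self):
        m = NeoHookeanMaterial(c10=7.5, d1=0.004)
        assert m.shear_modulus == 2 * 7.5
        assert m.bulk_modulus == 2 / 0.004
        with pytest.raises(ConfigError):
            NeoHookeanMaterial(c10=-1.0, d1=0.1)


class TestFingertipMesh:
    def test_default_interface_sampling(self):
        model = build_fingertip_model()
        assert len(model.interface_nodes) == 111
        assert model.interface_arc[0] == 0.0
        assert model.interface_arc[-1] == pytest.approx(15.2)
        # the interface sits at the epidermis depth
        z = model.nodes[model.interface_nodes, 1]
        assert np.allclose(z, -0.470)

    def test_zero_thickness_layer_rejected(self):
        with pytest.raises(ConfigError):
            LayerSpec("epidermis", 0.0, MAT)

    def test_interface_depth_must_lie_in_stack(self):
        with pytest.raises(ConfigError):
            FingertipConfig(interface_depth=50.0)

    def test_refinement_grows_elements_but_not_span(self):
        base = build_fingertip_model(default_fingertip_config())
        fine = build_fingertip_model(default_fingertip_config(
            n_interface_nodes=221, layer_divisions=(4, 6, 8)))
        assert len(fine.elements) > 2 * len(base.elements)
        assert fine.interface_arc[-1] == base.interface_arc[-1]


class TestStimulusMesh:
    def test_fine_edges_in_contact_region(self):
        model = build_stimulus_model(StimulusTip(radius=4.0, shear_modulus=10.0))
        nodes, elems = model.body.nodes, model.body.elements
        mask = model.contact_region_mask
        for k in range(4):
            a, b = elems[:, k], elems[:, (k + 1) % 4]
            sel = mask[a] & mask[b]
            d = np.linalg.norm(nodes[a[sel]] - nodes[b[sel]], axis=1)
            assert d.max() <= 0.25 + 1e-9

    def test_all_edges_below_coarse_bound(self):
        model = build_stimulus_model(StimulusTip(radius=8.0, shear_modulus=90.0))
        nodes, elems = model.body.nodes, model.body.elements
        for k in range(4):
            a, b = elems[:, k], elems[:, (k + 1) % 4]
            d = np.linalg.norm(nodes[a] - nodes[b], axis=1)
            assert d.max() <= 1.0 + 1e-9

    def test_degenerate_radius_rejected(self):
        with pytest.raises(ConfigError):
            StimulusTip(radius=0.1, shear_modulus=10.0, fine_edge=0.25)

    def test_plate_poisson_bounds(self):
        with pytest.raises(ConfigError):
            StimulusTip(radius=4.0, shear_modulus=10.0, plate_poisson=0.5)


class TestElementTangent:
    @pytest.mark.parametrize("formulation", ["axisymmetric", "plane-strain"])
    def test_assembled_stiffness_matches_fd_of_force(self, formulation):
        nodes = np.array([[r, z] for z in (0.0, -0.5, -1.0)
                          for r in (0.5, 1.0, 1.5)], float)
        elems = np.array([[3, 4, 1, 0], [4, 5, 2, 1], [6, 7, 4, 3], [7, 8, 5, 4]])
        body = FEBody(nodes=nodes, elements=elems,
                      c10=np.full(4, MAT.c10), d1=np.full(4, MAT.d1),
                      formulation=formulation)
        u = 0.02 * np.random.default_rng(0).standard_normal(body.n_dof)
        f, (rows, cols, data) = body.force_and_stiffness(u)
        K = np.zeros((body.n_dof,) * 2)
        np.add.at(K, (rows, cols), data)
        h = 1e-7
        Kfd = np.zeros_like(K)
        for j in range(body.n_dof):
            up, um = u.copy(), u.copy()
            up[j] += h
            um[j] -= h
            Kfd[:, j] = (body.internal_force(up) - body.internal_force(um)) / (2 * h)
        assert np.abs(K - Kfd).max() / np.abs(Kfd).max() < 1e-6


class TestProfiles:
    def test_neighbor_averaging_rule(self, coarse_fingertip):
        """Each interface node averages exactly its adjacent elements."""
        model = coarse_fingertip
        fake = np.arange(len(model.elements), dtype=float)
        state = _fake_state(model, element_scalar=fake)
        prof = interface_stress_profile(state, model)
        # independent recomputation of the adjacency from the connectivity
        for node_id, value in zip(model.interface_nodes, prof.values):
            adj = [e for e, conn in enumerate(model.elements) if node_id in conn]
            assert value == pytest.approx(np.mean(fake[adj]))

    def test_uniform_field_gives_constant_profile(self, coarse_fingertip):
        state = _fake_state(coarse_fingertip,
                            element_scalar=np.full(len(coarse_fingertip.elements), 3.5))
        prof = interface_stress_profile(state, coarse_fingertip)
        assert np.allclose(prof.values, 3.5)
        sed = interface_sed_profile(state, coarse_fingertip)
        assert np.allclose(sed.values, 3.5)

    def test_unloaded_state_has_zero_profiles(self, coarse_fingertip):
        state = _fake_state(coarse_fingertip,
                            element_scalar=np.zeros(len(coarse_fingertip.elements)))
        assert np.allclose(interface_stress_profile(state, coarse_fingertip).values, 0)
        assert np.allclose(surface_deflection_profile(state, coarse_fingertip).values, 0)

    def test_profile_has_111_samples_on_default_mesh(self, illusion_solutions):
        model = build_fingertip_model()
        # only the sampling structure needs the default mesh; values come
        # from the coarse solved state via the same extraction rule
        assert len(model.interface_nodes) == 111
        prof = interface_stress_profile(
            illusion_solutions["10kPa-4mm"][3],
            _model_of(illusion_solutions))
        assert prof.values.shape == prof.locations.shape


def _model_of(solutions):
    # the session fixture solves on the coarse default model
    return mech.build_fingertip_model(mech.default_fingertip_config(coarse=True))


def _fake_state(model, element_scalar):
    n = len(model.nodes)
    m = len(model.elements)
    return mech.SolutionState(
        mode="passive", load=0.0, rigid_body_travel=0.0,
        finger_displacements=np.zeros((n, 2)),
        stimulus_displacements=None,
        finger_stress=np.zeros((m, 4)),
        finger_vm=np.asarray(element_scalar, float),
        finger_sed=np.asarray(element_scalar, float),
        stimulus_sed=None, strain_energy=0.0)


class TestCueDistance:
    def test_zero_iff_identical_and_symmetric(self):
        x = np.linspace(0, 10, 50)
        a = CueProfile(x, np.sin(x) + 2, 1.0, "stress")
        b = CueProfile(x, np.cos(x) + 2, 1.0, "stress")
        assert cue_distance(a, a) == 0.0
        assert cue_distance(a, b) == pytest.approx(cue_distance(b, a))
        assert cue_distance(a, b) > 0

    def test_resampling_between_grids(self):
        a = CueProfile(np.linspace(0, 10, 40), np.linspace(1, 2, 40), 1.0, "sed")
        b = CueProfile(np.linspace(0, 10, 90), np.linspace(1, 2, 90), 1.0, "sed")
        assert cue_distance(a, b) < 1e-3

    def test_disjoint_ranges_rejected(self):
        a = CueProfile(np.linspace(0, 1, 5), np.ones(5), 1.0, "stress")
        b = CueProfile(np.linspace(5, 6, 5), np.ones(5), 1.0, "stress")
        with pytest.raises(ValueError):
            cue_distance(a, b)


class TestSolvedStates:
    def test_loads_match_schedule_within_1pct(self, illusion_solutions):
        for sol in illusion_solutions.values():
            for state, target in zip(sol, (0.25, 0.5, 1.0, 2.0)):
                assert state.load == pytest.approx(target, rel=0.0101)

    def test_sed_nonnegative_everywhere(self, illusion_solutions):
        for sol in illusion_solutions.values():
            for state in sol:
                assert state.finger_sed.min() >= -1e-12
                assert state.stimulus_sed.min() >= -1e-12

    def test_deflection_peaks_under_the_contact(self, illusion_solutions):
        model = _model_of(illusion_solutions)
        prof = surface_deflection_profile(illusion_solutions["90kPa-8mm"][3], model)
        assert prof.values[0] > prof.values[-1]
        assert prof.values.argmax() <= 2  # flat apex under the contact center
        assert prof.values[0] == pytest.approx(prof.values.max(), rel=0.01)

    def test_passive_active_equivalence(self, illusion_solutions, active_solutions):
        """Frame invariance: both drive modes give the same contact state."""
        model = _model_of(illusion_solutions)
        for sid in ("10kPa-4mm", "90kPa-8mm"):
            p = interface_stress_profile(illusion_solutions[sid][3], model)
            a = interface_stress_profile(active_solutions[sid][3], model)
            assert cue_distance(p, a) < 0.01
            assert active_solutions[sid][3].rigid_body_travel == pytest.approx(
                illusion_solutions[sid][3].rigid_body_travel, rel=0.02)

    def test_energy_consistency_moderate_strain(self, illusion_solutions):
        """External work along the path bounds the stored energy (~1%)
        outside the extreme-squash regime."""
        sol = illusion_solutions["90kPa-8mm"]
        for state in sol:
            m = sol.path[:, 0] <= state.rigid_body_travel + 1e-12
            tt = np.append(sol.path[m][:, 0], state.rigid_body_travel)
            ff = np.append(sol.path[m][:, 1], state.load) * 1000.0
            work = np.trapezoid(ff, tt)
            assert state.strain_energy == pytest.approx(work, rel=0.02)

    def test_force_displacement_curve_properties(self, active_solutions):
        fd = force_displacement_curve(active_solutions["10kPa-4mm"])
        assert fd.force[0] == 0.0 and fd.displacement[0] == 0.0
        assert np.all(np.diff(fd.displacement) >= 0)
        assert np.all(np.diff(fd.force) >= 0)

    def test_mixed_mode_states_rejected(self, illusion_solutions, active_solutions):
        mixed = [illusion_solutions["10kPa-4mm"][0], active_solutions["10kPa-4mm"][0]]
        with pytest.raises(ValueError):
            force_displacement_curve(mixed)

    def test_softer_sphere_needs_more_travel(self, active_solutions):
        """The proprioceptive cue separates the illusion pair."""
        fd_soft = force_displacement_curve(active_solutions["10kPa-4mm"])
        fd_stiff = force_displacement_curve(active_solutions["90kPa-8mm"])
        assert fd_soft.displacement_at(2.0) > 1.2 * fd_stiff.displacement_at(2.0)


class TestScalingInvariance:
    def test_modulus_load_homogeneity(self):
        """Scaling all moduli and loads by s leaves displacements unchanged."""
        s = 3.0
        travels = {}
        for scale in (1.0, s):
            layers = mech.default_layers(
                moduli={k: scale * v for k, v in mech.DEFAULT_LAYER_MODULI.items()})
            cfg = default_fingertip_config(coarse=True, layers=layers)
            model = build_fingertip_model(cfg)
            tip = StimulusTip(radius=6.0, shear_modulus=scale * 50.0)
            sol = mech.solve_contact(ContactProblem(
                fingertip=model, stimulus=tip, mode="passive",
                load_schedule=(0.25 * scale,), stimulus_mesh_scale=3.0))
            travels[scale] = sol[0].rigid_body_travel
        assert travels[s] == pytest.approx(travels[1.0], rel=0.02)


class TestRigidIndentation:
    def test_center_deflects_most_and_force_grows(self, coarse_fingertip):
        states = solve_rigid_indentation(coarse_fingertip, 5.0, (0.3, 0.6))
        assert states[1].load > states[0].load > 0
        prof = surface_deflection_profile(states[1], coarse_fingertip)
        assert prof.values[0] == pytest.approx(0.6, rel=0.05)
        assert prof.values[0] > prof.values[-1]

    def test_refinement_stability_of_cue_profiles(self, illusion_solutions):
        """A finer mesh changes the extracted profiles by <5% RMS."""
        tip = StimulusTip(radius=4.0, shear_modulus=10.0)
        fine_model = build_fingertip_model(default_fingertip_config())
        fine = mech.solve_contact(ContactProblem(
            fingertip=fine_model, stimulus=tip, mode="passive",
            load_schedule=(0.25,), stimulus_mesh_scale=1.0))
        coarse_model = _model_of(illusion_solutions)
        p_c = interface_stress_profile(illusion_solutions["10kPa-4mm"][0], coarse_model)
        p_f = interface_stress_profile(fine[0], fine_model)
        assert cue_distance(p_c, p_f) < 0.05
        d_c = surface_deflection_profile(illusion_solutions["10kPa-4mm"][0], coarse_model)
        d_f = surface_deflection_profile(fine[0], fine_model)
        assert cue_distance(d_c, d_f) < 0.05


class TestVtkExport:
    def test_legacy_vtk_structure(self, coarse_fingertip, tmp_path):
        path = tmp_path / "mesh.vtk"
        body = coarse_fingertip.body
        mech.export_vtk(path, body, cell_data={"layer": np.arange(len(body.elements))})
        text = path.read_text()
        assert f"POINTS {len(body.nodes)} float" in text
        assert f"CELLS {len(body.elements)}" in text
        assert "SCALARS layer float 1" in text
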