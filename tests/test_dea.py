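"""Bed-of-springs contact solver: material law, penetrations, equilibrium."""

import numpy as np
import pytest

import hipdea as h
import hipdea.mesh as hmesh
from hipdea.dea import MaterialParams, pose_rotation, spring_constant

from conftest import make_congruent_model, polar_instance


class TestSpringLaw:
    def test_confined_compression_modulus(self):
        mat = MaterialParams(youngs_modulus=12.0, poisson_ratio=0.43)
        assert mat.aggregate_modulus == pytest.approx(34.166, abs=1e-3)
        assert spring_constant(mat, 2.0) == pytest.approx(17.083, abs=1e-3)

    def test_zero_poisson_reduces_to_youngs(self):
        mat = MaterialParams(youngs_modulus=9.0, poisson_ratio=1e-12)
        assert mat.aggregate_modulus == pytest.approx(9.0, rel=1e-9)

    def test_doubling_thickness_halves_stiffness(self):
        mat = MaterialParams()
        assert spring_constant(mat, 4.0) == pytest.approx(
            spring_constant(mat, 2.0) / 2.0
        )

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams(poisson_ratio=0.5)

    def test_nonpositive_thickness_rejected(self):
        with pytest.raises(ValueError):
            spring_constant(MaterialParams(), 0.0)


class TestPose:
    def test_zero_pose_is_identity(self):
        surf = hmesh.icosphere(radius=5.0, subdivisions=2)
        posed = h.pose_femur(surf, np.zeros(3), [0, 0, 0], np.zeros(3))
        np.testing.assert_allclose(posed.vertices, surf.vertices, atol=1e-12)

    def test_translation_round_trip(self):
        surf = hmesh.icosphere(radius=5.0, subdivisions=2)
        t = np.array([0.3, -0.2, 0.9])
        posed = h.pose_femur(surf, np.zeros(3), [0, 0, 0], t)
        back = h.pose_femur(posed, np.zeros(3), [0, 0, 0], -t)
        np.testing.assert_allclose(back.vertices, surf.vertices, atol=1e-12)

    def test_flexion_maps_anterior_to_superior(self):
        # +X (anterior) rotates to +Y (superior) under 90 deg flexion about +Z
        rot = pose_rotation([90.0, 0.0, 0.0])
        np.testing.assert_allclose(rot @ [1, 0, 0], [0, 1, 0], atol=1e-9)


class TestPenetrations:
    def test_concentric_just_touching(self, hemisphere_model):
        model, _ = hemisphere_model
        delta = model.penetrations(np.zeros(3))
        assert delta.max() < 1e-9

    def test_polar_displacement_cosine_decay(self, hemisphere_model):
        model, frame = hemisphere_model
        u = 0.1
        delta = model.penetrations(u * frame.pole)
        gamma = np.arccos(np.clip(model.dirs @ frame.pole, -1, 1))
        inside = gamma < np.deg2rad(75.0)
        expected = u * np.cos(gamma[inside])
        assert delta.max() == pytest.approx(u, rel=0.02)
        np.testing.assert_allclose(delta[inside], expected, rtol=0.02)

    def test_withdrawn_head_no_contact(self, hemisphere_model):
        model, frame = hemisphere_model
        delta = model.penetrations(-0.5 * frame.pole)
        assert (delta == 0).all()

    def test_far_head_misses_all_rays(self, hemisphere_model):
        model, frame = hemisphere_model
        delta = model.penetrations(60.0 * frame.pole)
        assert np.isfinite(delta).all()


class TestResidual:
    def test_zero_load_zero_penetration(self, hemisphere_model):
        model, _ = hemisphere_model
        r = model.residual_force(np.zeros(3), np.zeros(3))
        np.testing.assert_allclose(r, 0.0, atol=1e-12)

    def test_analytic_displacement_balances_polar_load(self, hemisphere_model):
        model, frame = hemisphere_model
        F = 1000.0
        k = MaterialParams().aggregate_modulus / 2.0
        d0 = 3 * F / (2 * np.pi * 25.0**2 * k)
        r = model.residual_force(d0 * frame.pole, F * frame.pole)
        assert np.linalg.norm(r) < 0.01 * F

    def test_reaction_opposes_interior_displacements(self, hemisphere_model):
        model, frame = hemisphere_model
        rng = np.random.default_rng(8)
        for _ in range(5):
            u = frame.pole + 0.3 * rng.normal(size=3)
            u = 0.05 * u / np.linalg.norm(u)
            # with zero applied load the residual IS the spring reaction
            reaction = model.residual_force(u, np.zeros(3))
            assert reaction @ u < 0  # pushes back against the displacement


class TestSolve:
    def test_congruent_hemisphere_matches_closed_form(self, hemisphere_model):
        model, frame = hemisphere_model
        out = h.solve_instance(model, polar_instance(frame, 1000.0))
        assert isinstance(out, h.StressField)
        assert out.converged and out.residual < 1e-6
        p_max = 3 * 1000.0 / (2 * np.pi * 25.0**2)
        p_mean = p_max / 2.0
        assert out.element_stress.max() == pytest.approx(p_max, rel=0.03)
        active = out.element_stress > 0
        mean = float(
            (out.element_stress[active] * out.element_area[active]).sum()
            / out.element_area[active].sum()
        )
        assert mean == pytest.approx(p_mean, rel=0.03)

    def test_zero_load_trivially_converged(self, hemisphere_model):
        model, frame = hemisphere_model
        inst = h.LoadInstance(1, 0.1, np.zeros(3), np.zeros(3), 0.09)
        out = h.solve_instance(model, inst)
        assert isinstance(out, h.StressField)
        assert out.element_stress.max(initial=0.0) < 1e-9

    def test_no_tension_on_converged_fields(self, hemisphere_model):
        model, frame = hemisphere_model
        out = h.solve_instance(model, polar_instance(frame, 700.0))
        assert out.element_stress.min() >= 0.0

    def test_shallow_cup_lateral_load_diverges(self):
        model, frame = make_congruent_model(edge=1.0, coverage=25.0)
        lateral = np.array([0.0, -0.3, 1.0])
        lateral /= np.linalg.norm(lateral)
        inst = h.LoadInstance(2, 0.2, 1000.0 * lateral, np.zeros(3), 0.09)
        out = h.solve_instance(model, inst)
        assert isinstance(out, h.Divergence)
        assert out.reason in ("min_step", "max_iterations")

    def test_near_linearity_on_fixed_contact_set(self, hemisphere_model):
        # full-contact congruent cup: stress scales with load up to the
        # geometric nonlinearity of exact sphere-sphere overlap, O(u/R),
        # amplified toward the rim where the spring rays graze the head
        model, frame = hemisphere_model
        a = h.solve_instance(model, polar_instance(frame, 500.0))
        b = h.solve_instance(model, polar_instance(frame, 1000.0))
        # equilibrium displacement itself doubles to O(u/R)
        ua = np.linalg.norm(a.head_translation)
        ub = np.linalg.norm(b.head_translation)
        assert ub / ua == pytest.approx(2.0, abs=1e-3)
        core = a.element_stress > 0.2 * a.element_stress.max()
        ratio = b.element_stress[core] / a.element_stress[core]
        assert np.abs(ratio - 2.0).max() < 3e-3 * 2.0

    def test_frame_objectivity(self):
        model, frame = make_congruent_model(edge=2.0)
        inst = polar_instance(frame, 800.0)
        base = h.solve_instance(model, inst)

        rot = hmesh.rotation_matrix([1.0, 2.0, 0.5], 33.0)
        frame2 = frame.rotated(rot)
        cup2 = hmesh.spherical_cap_mesh(26.0, 90.0, frame2, 2.0).oriented(
            frame2.center, outward=False
        )
        layer2 = h.shivanna_offset(cup2, frame2, h.ShivannaParams(), side="acetabular")
        model2 = h.ContactModel(layer2, h.FemoralSurface.sphere(24.0, 1.0), frame2)
        inst2 = h.LoadInstance(2, 0.2, 800.0 * frame2.pole, np.zeros(3), 0.09)
        out2 = h.solve_instance(model2, inst2)
        # same mesh topology in the rotated frame: element-wise comparison
        np.testing.assert_allclose(
            out2.element_stress, base.element_stress, atol=1e-9
        )

    def test_aspherical_head_mesh_path(self):
        # the mesh-backed femoral surface agrees with the analytic sphere
        # when the 'noise' is zero, and perturbs stresses when it is not
        params = h.HipGeometryParams(
            head_radius=24.0, cup_radius=26.0, target_element_size=1.5,
            frame=h.cup_frame(inclination_deg=0.0, anteversion_deg=0.0),
        )
        head, frame = h.generate_femoral_head(params, seed=3, noise_amplitude=0.05)
        fem_layer = h.shivanna_offset(head, frame, h.ShivannaParams(), side="femoral")
        femur = h.FemoralSurface.from_layer(fem_layer, frame.center)
        assert not femur.is_sphere
        cup = hmesh.spherical_cap_mesh(26.0, 90.0, frame, 1.5).oriented(
            frame.center, outward=False
        )
        layer = h.shivanna_offset(cup, frame, h.ShivannaParams(), side="acetabular")
        model = h.ContactModel(layer, femur, frame)
        out = h.solve_instance(model, polar_instance(frame, 1000.0))
        assert isinstance(out, h.StressField)
        p_max = 3 * 1000.0 / (2 * np.pi * 25.0**2)
        # asphericity shifts the peak but stays in the same regime
        assert 0.5 * p_max < out.element_stress.max() < 3.0 * p_max


class TestSequence:
    def make_instances(self, frame, magnitudes):
        return [
            h.LoadInstance(k + 1, 0.1 * k + 0.05, m * frame.pole, np.zeros(3), 0.09)
            for k, m in enumerate(magnitudes)
        ]

    def test_all_converge_gives_seven_fields(self, hemisphere_model):
        model, frame = hemisphere_model
        seq = h.solve_sequence(
            model, self.make_instances(frame, [400, 900, 600, 500, 600, 850, 400])
        )
        assert isinstance(seq, h.GaitStressSequence)
        assert seq.t == 7
        assert seq.total_area == pytest.approx(model.total_area)

    def test_one_divergence_voids_sequence(self):
        model, frame = make_congruent_model(edge=1.2, coverage=25.0)
        lateral = np.array([0.0, -0.3, 1.0])
        lateral /= np.linalg.norm(lateral)
        instances = self.make_instances(frame, [200, 400, 300, 300, 300, 400, 200])
        instances[3] = h.LoadInstance(4, 0.35, 900.0 * lateral, np.zeros(3), 0.09)
        out = h.solve_sequence(model, instances)
        assert isinstance(out, h.SequenceDivergence)
        assert 4 in out.failed_instances

    def test_warm_start_path_independence(self, hemisphere_model):
        model, frame = hemisphere_model
        instances = self.make_instances(frame, [400, 900, 600, 500, 600, 850, 400])
        warm = h.solve_sequence(model, instances)
        cold = [h.solve_instance(model, inst) for inst in instances]
        for f_warm, f_cold in zip(warm.fields, cold):
            np.testing.assert_allclose(
                f_warm.element_stress, f_cold.element_stress, atol=1e-4
            )
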