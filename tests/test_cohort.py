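"""Synthetic cohort: parametric hips, radiographic measures, PAO reorientation."""

import numpy as np
import pytest

import hipdea as h
from hipdea.cohort import (
    CohortConfig,
    CohortValidationError,
    CoverageTable,
    HipGeometryParams,
    cup_frame,
    measures_from_mesh,
    measures_from_params,
    simulate_pao,
)


def neutral_params(**kw):
    defaults = dict(
        head_radius=24.0,
        cup_radius=26.0,
        frame=cup_frame(inclination_deg=0.0, anteversion_deg=0.0),
        coverage=CoverageTable(90.0, 90.0, 90.0, 90.0),
        target_element_size=1.0,
    )
    defaults.update(kw)
    return HipGeometryParams(**defaults)


class TestCoverageTable:
    def test_out_of_range_rejected(self):
        with pytest.raises(CohortValidationError):
            CoverageTable(125.0, 70.0, 80.0, 75.0)
        with pytest.raises(CohortValidationError):
            CoverageTable(60.0, 0.0, 80.0, 75.0)

    def test_monotone_between_knots(self):
        cov = CoverageTable(55.0, 70.0, 70.0, 55.0)
        az = np.linspace(0.0, 90.0, 50)
        vals = cov(az)
        assert (np.diff(vals) >= -1e-12).all()
        assert vals[0] == pytest.approx(55.0)
        assert vals[-1] == pytest.approx(70.0)

    def test_periodic(self):
        cov = CoverageTable(55.0, 70.0, 80.0, 60.0)
        assert cov(-90.0) == pytest.approx(cov(270.0))


class TestFemoralHead:
    def test_noise_free_head_is_exact_sphere(self):
        surf, frame = h.generate_femoral_head(neutral_params(), seed=1)
        r = np.linalg.norm(surf.vertices - frame.center, axis=1)
        assert np.abs(r - 24.0).max() < 1e-9

    def test_seeded_noise_reproducible(self):
        p = neutral_params()
        a, _ = h.generate_femoral_head(p, seed=5, noise_amplitude=0.1)
        b, _ = h.generate_femoral_head(p, seed=5, noise_amplitude=0.1)
        np.testing.assert_array_equal(a.vertices, b.vertices)
        c, _ = h.generate_femoral_head(p, seed=6, noise_amplitude=0.1)
        assert np.abs(a.vertices - c.vertices).max() > 0

    def test_element_size_honoured(self):
        p = neutral_params(head_radius=25.0, cup_radius=27.0, target_element_size=0.7,
                           head_extent=120.0)
        surf, _ = h.generate_femoral_head(p, seed=1)
        assert 0.56 <= surf.mean_edge_length() <= 0.84


class TestAcetabulum:
    def test_hemispherical_cup_area(self):
        p = neutral_params(target_element_size=0.9)
        cup, _ = h.generate_acetabulum(p, seed=1)
        assert cup.total_area == pytest.approx(2 * np.pi * 26.0**2, rel=0.02)

    def test_vanishing_coverage_limit(self):
        p = neutral_params(coverage=CoverageTable(2.0, 2.0, 2.0, 2.0),
                           target_element_size=0.3)
        cup, _ = h.generate_acetabulum(p, seed=1)
        assert cup.total_area < 0.02 * 2 * np.pi * 26.0**2

    def test_rim_depth_interpolates_between_sectors(self):
        from hipdea.mesh import radial_decomposition

        p = neutral_params(coverage=CoverageTable(55.0, 70.0, 70.0, 55.0))
        cup, frame = h.generate_acetabulum(p, seed=1)
        rim = cup.vertices[cup.boundary_vertices()]
        _, polar, az = radial_decomposition(rim, frame)
        sector = (az >= 0) & (az <= 90)
        order = np.argsort(az[sector])
        diffs = np.diff(polar[sector][order])
        assert (diffs >= -0.5).all()  # monotone up to rim discretisation
        assert polar.min() > 54.0 and polar.max() < 71.0

    def test_normals_point_toward_center(self):
        p = neutral_params()
        cup, frame = h.generate_acetabulum(p, seed=1)
        dots = np.einsum(
            "ij,ij->i", cup.element_normal, cup.element_centroid - frame.center
        )
        assert (dots < 0).all()


class TestRadiographicMeasures:
    def test_neutral_hemisphere_lcea_zero(self):
        m = measures_from_params(neutral_params())
        assert m.LCEA == pytest.approx(0.0, abs=0.5)
        assert m.AAA == pytest.approx(0.0, abs=0.5)
        assert m.FHEI == pytest.approx(50.0, abs=1.0)

    def test_deep_lateral_coverage_zero_extrusion(self):
        p = HipGeometryParams(
            head_radius=24.5, cup_radius=28.5,
            frame=cup_frame(inclination_deg=40.0, anteversion_deg=0.0),
            coverage=CoverageTable(119.0, 80.0, 80.0, 80.0),
        )
        assert measures_from_params(p).FHEI == pytest.approx(0.0, abs=1e-9)

    def test_lateral_coverage_sweep_monotone(self):
        lceas, ais, fheis = [], [], []
        for lat in (55.0, 65.0, 75.0, 85.0):
            p = HipGeometryParams(
                coverage=CoverageTable(lat, 60.0, 80.0, 75.0),
                frame=cup_frame(),
            )
            m = measures_from_params(p)
            lceas.append(m.LCEA)
            ais.append(m.AI)
            fheis.append(m.FHEI)
        assert all(b > a for a, b in zip(lceas, lceas[1:]))
        assert all(b < a for a, b in zip(ais, ais[1:]))
        assert all(b < a for a, b in zip(fheis, fheis[1:]))

    def test_anteversion_read_by_axial_angle(self):
        for av in (5.0, 15.0, 25.0):
            p = neutral_params(frame=cup_frame(inclination_deg=0.0,
                                               anteversion_deg=av))
            assert measures_from_params(p).AAA == pytest.approx(av, abs=2.0)

    def test_mesh_and_parametric_measures_agree(self):
        cfg = CohortConfig(target_element_size=0.8)
        rng = np.random.default_rng(17)
        record = h.cohort.generate_subject(rng, cfg, "T001")
        for geometry in (record.pre_geometry, record.post_geometry):
            cup, _ = h.generate_acetabulum(geometry)
            from_mesh = measures_from_mesh(cup, geometry)
            parametric = measures_from_params(geometry)
            for name in ("LCEA", "AI", "ACEA", "AAA", "FHEI"):
                assert getattr(from_mesh, name) == pytest.approx(
                    getattr(parametric, name), abs=2.0
                ), name


class TestPAO:
    def test_identity_rotation_preserves_measures(self):
        p = h.HipGeometryParams()
        post = simulate_pao(p, (0.0, 0.0, 0.0))
        a, b = measures_from_params(p), measures_from_params(post)
        assert a.as_dict() == pytest.approx(b.as_dict())

    def test_rotation_round_trip(self):
        p = h.HipGeometryParams()
        fwd = simulate_pao(p, (15.0, -8.0, 3.0))
        # inverse rotations in reverse order
        back = simulate_pao(
            simulate_pao(simulate_pao(fwd, (0.0, 0.0, -3.0)), (0.0, 8.0, 0.0)),
            (-15.0, 0.0, 0.0),
        )
        np.testing.assert_allclose(back.frame.axes, p.frame.axes, atol=1e-9)

    def test_lateral_rotation_increases_lcea(self):
        p = h.HipGeometryParams()
        post = simulate_pao(p, (15.0, 0.0, 0.0))
        assert measures_from_params(post).LCEA > measures_from_params(p).LCEA + 10.0

    def test_overlarge_rotation_rejected(self):
        with pytest.raises(CohortValidationError):
            simulate_pao(h.HipGeometryParams(), (50.0, 0.0, 0.0))


class TestCohortGeneration:
    def test_reproducible_records(self):
        a = h.generate_cohort(5, seed=33)
        b = h.generate_cohort(5, seed=33)
        assert len(a) == 5
        for ra, rb in zip(a, b):
            assert ra.pre_measures.as_dict() == pytest.approx(
                rb.pre_measures.as_dict()
            )
            assert ra.weight == rb.weight

    def test_zero_variance_config_identical_subjects(self):
        cfg = CohortConfig(
            age=(34.6, 0.0, 18, 60), weight=(72.5, 0.0, 40, 120),
            height=(1.69, 0.0, 1.45, 1.95), female_fraction=1.0,
            head_radius=(24.5, 0.0, 20, 29), inclination=(40.0, 0.0, 30, 50),
            anteversion=(20.0, 0.0, 8, 32), pre_lcea=(17.0, 0.0, 3, 26),
            pre_acea=(21.4, 0.0, 4, 36), medial_coverage=(80.0, 0.0, 65, 95),
            posterior_coverage=(75.0, 0.0, 60, 90),
            post_lcea_target=(28.6, 0.0, 20, 38),
            pao_anterior_rotation=(8.0, 0.0, 0, 18),
            pao_axial_rotation=(0.0, 0.0, -5, 5), correction_noise=0.0,
        )
        records = h.generate_cohort(3, seed=1, config=cfg)
        ref = records[0]
        for r in records[1:]:
            assert r.pre_measures.as_dict() == pytest.approx(
                ref.pre_measures.as_dict(), abs=1e-9
            )
            assert r.weight == ref.weight and r.sex == "F"

    def test_lcea_targeting_at_scale(self):
        # sample mean of pre-op LCEA within 3 SE of the configured target
        cfg = CohortConfig(target_element_size=1.5)
        records = h.generate_cohort(200, seed=10, config=cfg)
        lceas = np.array([r.pre_measures.LCEA for r in records])
        se = cfg.pre_lcea[1] / np.sqrt(len(records))
        assert abs(lceas.mean() - cfg.pre_lcea[0]) < 3 * se + 0.5

    def test_pao_effect_directions(self):
        records = h.generate_cohort(12, seed=2)
        diff = {
            k: np.mean(
                [r.post_measures.as_dict()[k] - r.pre_measures.as_dict()[k]
                 for r in records]
            )
            for k in ("LCEA", "ACEA", "AI", "FHEI")
        }
        assert diff["LCEA"] > 0 and diff["ACEA"] > 0
        assert diff["AI"] < 0 and diff["FHEI"] < 0

    def test_bilateral_flag_adds_23rd_hip(self):
        records = h.generate_cohort(22, seed=3, bilateral=True)
        assert len(records) == 23
        ids = [r.id for r in records]
        assert ids.count(records[0].id) == 2
        twin = records[1]
        assert twin.side == "L" and twin.weight == records[0].weight
        assert twin.pre_measures.as_dict() != pytest.approx(
            records[0].pre_measures.as_dict()
        )

    def test_manifest_layout(self):
        records = h.generate_cohort(3, seed=4)
        man = h.cohort_manifest(records)
        assert len(man) == 3
        for col in ("id", "sex", "weight_kg", "LCEA_pre", "LCEA_post", "FHEI_post"):
            assert col in man.columns

    def test_invalid_n_rejected(self):
        with pytest.raises(CohortValidationError):
            h.generate_cohort(0, seed=1)
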