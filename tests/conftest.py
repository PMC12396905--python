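"""Shared fixtures: small congruent-joint models and random stress sequences."""

from __future__ import annotations

import numpy as np
import pytest

import hipdea as h
import hipdea.mesh as hmesh
from hipdea.dea import GaitStressSequence, StressField


def make_congruent_model(edge: float = 1.4, coverage: float = 90.0):
    """Congruent sphere-in-cup: head 24 mm + 1 mm cartilage vs cup 26 mm
    - 1 mm cartilage, i.e. both contact surfaces at exactly 25 mm."""
    frame = h.cup_frame(inclination_deg=0.0, anteversion_deg=0.0)
    cup = hmesh.spherical_cap_mesh(26.0, coverage, frame, edge).oriented(
        frame.center, outward=False
    )
    layer = h.shivanna_offset(cup, frame, h.ShivannaParams(), side="acetabular")
    femur = h.FemoralSurface.sphere(24.0, 1.0)
    return h.ContactModel(layer, femur, frame), frame


@pytest.fixture(scope="session")
def hemisphere_model():
    return make_congruent_model(edge=1.4)


def polar_instance(frame, magnitude: float = 1000.0, dt: float = 0.09, index: int = 2):
    return h.LoadInstance(
        index, 0.2, magnitude * frame.pole, np.zeros(3), dt
    )


def random_sequence(rng: np.random.Generator) -> GaitStressSequence:
    """Small random gait stress sequence for metric oracles."""
    n = int(rng.integers(1, 51))
    t = int(rng.integers(1, 8))
    areas = rng.uniform(0.2, 2.0, n)
    stresses = rng.uniform(0.0, 14.0, (t, n))
    stresses[rng.random((t, n)) < 0.4] = 0.0  # separated elements
    dt = float(rng.uniform(0.02, 0.3))
    total_area = float(areas.sum() * rng.uniform(1.0, 2.0))  # cup larger than patch
    fields = [
        StressField(stresses[j], areas, np.zeros(3), True, 0.0) for j in range(t)
    ]
    return GaitStressSequence(fields, dt, total_area)


@pytest.fixture(scope="session")
def study_n22():
    """The end-to-end synthetic study: 22 hips, coarse 1.5 mm meshes."""
    cohort = h.generate_cohort(22, seed=1)
    result = h.run_study(cohort, h.StudySettings(element_size=1.5))
    return cohort, result
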