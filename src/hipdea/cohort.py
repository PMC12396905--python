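"""Synthetic dysplastic-hip cohort with simulated periacetabular osteotomy.

Stands in for CT-derived anatomy: near-spherical femoral heads, acetabular
cups parameterised by a rim-coverage table (polar rim depth vs azimuth about
the cup pole), subject covariates drawn from the published cohort
distributions, and PAO modelled as a rigid reorientation of the cup about
the head center. The five radiographic measures (LCEA, AI, ACEA, AAA, FHEI)
are computed from the 3D rim by orthographic projection in the pelvis frame
(+X anterior, +Y superior, +Z lateral; right-hip convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mesh import (
    SphericalFrame,
    TriSurface,
    rotation_matrix,
    spherical_cap_mesh,
    spherical_compose,
)

#: azimuth convention about the cup pole: 0 = superolateral, 90 = anterior,
#: 180 = inferomedial, 270 = posterior
COVERAGE_AZIMUTHS = ("lateral", "anterior", "medial", "posterior")


class CohortValidationError(ValueError):
    pass


@dataclass
class CoverageTable:
    """Rim polar depth (deg from the cup pole) at four cardinal azimuths.

    Values are interpolated between adjacent azimuths by a periodic cosine
    blend, which is C1 and monotone between knots. All depths must lie in
    the open interval (0, 120) degrees.
    """

    lateral: float
    anterior: float
    medial: float
    posterior: float

    def __post_init__(self) -> None:
        for name in COVERAGE_AZIMUTHS:
            v = getattr(self, name)
            if not 0.0 < v < 120.0:
                raise CohortValidationError(
                    f"rim coverage {name}={v} outside (0, 120) degrees"
                )

    def __call__(self, azimuth_deg) -> np.ndarray:
        az = np.mod(np.asarray(azimuth_deg, dtype=float), 360.0)
        knots = np.array([0.0, 90.0, 180.0, 270.0, 360.0])
        vals = np.array(
            [self.lateral, self.anterior, self.medial, self.posterior, self.lateral]
        )
        idx = np.clip(np.searchsorted(knots, az, side="right") - 1, 0, 3)
        s = (az - knots[idx]) / 90.0
        w = 0.5 * (1.0 - np.cos(np.pi * s))
        return vals[idx] * (1.0 - w) + vals[idx + 1] * w


def cup_frame(
    center=(0.0, 0.0, 0.0), inclination_deg: float = 40.0, anteversion_deg: float = 20.0
) -> SphericalFrame:
    """Cup-fixed frame: pole (e3) is the deepest-point direction.

    The acetabular opening axis is +Z (lateral) tilted inferiorly by the
    inclination and anteriorly by the anteversion; the pole is its opposite.
    Azimuth 0 (e1) points toward the superolateral rim sector.
    """
    axis = (
        rotation_matrix([0.0, 1.0, 0.0], anteversion_deg)
        @ rotation_matrix([1.0, 0.0, 0.0], inclination_deg)
        @ np.array([0.0, 0.0, 1.0])
    )
    pole = -axis
    up = np.array([0.0, 1.0, 0.0])
    e1 = up - (up @ pole) * pole
    n = np.linalg.norm(e1)
    if n < 1e-6:
        raise CohortValidationError("cup pole parallel to the vertical axis")
    e1 = e1 / n
    e2 = np.cross(pole, e1)
    return SphericalFrame(np.asarray(center, dtype=float), np.vstack([e1, e2, pole]))


@dataclass
class HipGeometryParams:
    """Parametric hip geometry (mm / degrees)."""

    head_radius: float = 24.5
    cup_radius: float = 28.5  # head_radius + nominal joint clearance
    frame: SphericalFrame = field(default_factory=cup_frame)
    coverage: CoverageTable = field(
        default_factory=lambda: CoverageTable(67.0, 62.0, 80.0, 75.0)
    )
    target_element_size: float = 0.7
    sourcil_span: float = 60.0  # polar arc of the weight-bearing roof proxy, deg
    head_extent: float = 150.0  # polar extent of the meshed head patch, deg

    def __post_init__(self) -> None:
        if self.cup_radius < self.head_radius:
            raise CohortValidationError("cup radius must be >= head radius")
        if self.target_element_size <= 0:
            raise CohortValidationError("target element size must be positive")

    @property
    def cup_axis(self) -> np.ndarray:
        """Acetabular opening direction (opposite the pole)."""
        return -self.frame.pole

    @property
    def clearance(self) -> float:
        return self.cup_radius - self.head_radius


@dataclass
class RadiographicMeasures:
    LCEA: float  # deg
    AI: float  # deg
    ACEA: float  # deg
    AAA: float  # deg
    FHEI: float  # % (0-100)

    def __post_init__(self) -> None:
        vals = [self.LCEA, self.AI, self.ACEA, self.AAA, self.FHEI]
        if not np.all(np.isfinite(vals)):
            raise CohortValidationError("non-finite radiographic measure")
        if not 0.0 <= self.FHEI <= 100.0:
            raise CohortValidationError("FHEI outside [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in MEASURE_NAMES}


MEASURE_NAMES = ["LCEA", "AI", "ACEA", "AAA", "FHEI"]


@dataclass
class SubjectRecord:
    id: str
    side: str
    sex: str  # "F" | "M"
    age: float  # years
    height: float  # m
    weight: float  # kg
    acetabular_radius: float  # mm
    pre_geometry: HipGeometryParams
    post_geometry: HipGeometryParams
    pre_measures: RadiographicMeasures
    post_measures: RadiographicMeasures
    pao_rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.height <= 0:
            raise CohortValidationError("weight and height must be positive")
        if self.sex not in ("F", "M"):
            raise CohortValidationError("sex must be F or M")


# --------------------------------------------------------------------------
# surface generation
# --------------------------------------------------------------------------


def _noise_field(amplitude: float, seed: int | None):
    """Smooth seeded radial perturbation (low-order angular harmonics)."""
    rng = np.random.default_rng(seed)
    coeffs = rng.normal(0.0, 1.0, 6)
    coeffs *= amplitude / np.sqrt((coeffs**2).sum() + 1e-300)

    def field_fn(polar_deg, azimuth_deg):
        th = np.deg2rad(np.asarray(polar_deg, dtype=float))
        ph = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
        return (
            coeffs[0] * np.sin(th) * np.cos(ph)
            + coeffs[1] * np.sin(th) * np.sin(ph)
            + coeffs[2] * np.cos(th)
            + coeffs[3] * np.sin(2 * th) * np.cos(ph)
            + coeffs[4] * np.sin(2 * th) * np.sin(2 * ph)
            + coeffs[5] * np.cos(2 * th)
        )

    return field_fn


def generate_femoral_head(
    params: HipGeometryParams, seed: int | None = None, noise_amplitude: float = 0.0
) -> tuple[TriSurface, SphericalFrame]:
    """Mesh a near-spherical femoral head patch about the cup pole.

    The patch covers the cup's solid angle plus margin; with zero noise the
    vertices lie exactly on the sphere of ``head_radius``.
    """
    offsets = _noise_field(noise_amplitude, seed) if noise_amplitude > 0 else None
    surf = spherical_cap_mesh(
        params.head_radius,
        params.head_extent,
        params.frame,
        params.target_element_size,
        radial_offsets=offsets,
    )
    return surf.oriented(params.frame.center, outward=True), params.frame


def generate_acetabulum(
    params: HipGeometryParams, seed: int | None = None
) -> tuple[TriSurface, SphericalFrame]:
    """Mesh the acetabular cup trimmed at the rim-coverage curve."""
    surf = spherical_cap_mesh(
        params.cup_radius,
        params.coverage,
        params.frame,
        params.target_element_size,
    )
    return surf.oriented(params.frame.center, outward=False), params.frame


# --------------------------------------------------------------------------
# radiographic measures
# --------------------------------------------------------------------------


def rim_points(params: HipGeometryParams, n: int = 720) -> np.ndarray:
    az = np.linspace(-180.0, 180.0, n, endpoint=False)
    theta = params.coverage(az)
    return spherical_compose(
        np.full(n, params.cup_radius), theta, az, params.frame
    )


def sourcil_medial_point(params: HipGeometryParams) -> np.ndarray:
    """Medial edge of the weight-bearing roof proxy.

    The roof is modelled as the rim band at the superolateral azimuth; its
    medial edge sits ``sourcil_span`` degrees of polar arc below the rim.
    """
    theta_rim = float(params.coverage(0.0))
    theta_m = max(theta_rim - params.sourcil_span, 5.0)
    return spherical_compose(
        np.array([params.cup_radius]), np.array([theta_m]), np.array([0.0]), params.frame
    )[0]


def compute_radiographic_measures(
    rim: np.ndarray,
    frame: SphericalFrame,
    head_radius: float,
    sourcil_medial: np.ndarray,
) -> RadiographicMeasures:
    """Five coverage angles from a 3D rim curve by orthographic projection.

    Landmarks are the rim points at the cup's cardinal azimuths (0 =
    superolateral, 90 = anterior, 270 = posterior), the geometric analogue
    of the radiographic sourcil edges. LCEA/ACEA: frontal/sagittal angle
    from vertical (+Y) to the head-center ray through the superolateral /
    anterior rim edge. AI: frontal inclination of the roof chord from the
    medial sourcil point to the superolateral rim edge (positive when the
    roof rises laterally). AAA: axial angle of the anterior-posterior rim
    chord against the sagittal (+X) axis, positive for anteversion. FHEI:
    % of head width uncovered lateral to the superolateral rim edge in
    frontal projection.
    """
    rim = np.asarray(rim, dtype=float)
    if len(rim) < 3:
        raise CohortValidationError("degenerate rim curve")
    from .mesh import radial_decomposition  # local import avoids cycle at init

    _, _, azimuth = radial_decomposition(rim, frame)
    rel = rim - frame.center

    def at_azimuth(target: float) -> np.ndarray:
        gap = np.abs((azimuth - target + 180.0) % 360.0 - 180.0)
        return rel[int(np.argmin(gap))]

    lat = at_azimuth(0.0)
    ant = at_azimuth(90.0)
    post = at_azimuth(270.0)
    if lat[1] <= 0:
        raise CohortValidationError("superolateral rim edge is not superior")

    lcea = float(np.rad2deg(np.arctan2(lat[2], lat[1])))
    acea = float(np.rad2deg(np.arctan2(ant[0], ant[1])))

    m = np.asarray(sourcil_medial, dtype=float) - frame.center
    ai = float(np.rad2deg(np.arctan2(lat[1] - m[1], lat[2] - m[2])))

    aaa = float(np.rad2deg(np.arctan2(post[2] - ant[2], ant[0] - post[0])))

    fhei = 100.0 * float(np.clip(head_radius - lat[2], 0.0, 2.0 * head_radius)) / (
        2.0 * head_radius
    )
    return RadiographicMeasures(lcea, ai, acea, aaa, fhei)


def measures_from_params(params: HipGeometryParams) -> RadiographicMeasures:
    return compute_radiographic_measures(
        rim_points(params),
        params.frame,
        params.head_radius,
        sourcil_medial_point(params),
    )


def measures_from_mesh(
    cup: TriSurface, params: HipGeometryParams
) -> RadiographicMeasures:
    """Measures recomputed from the meshed cup's open boundary."""
    rim = cup.vertices[cup.boundary_vertices()]
    return compute_radiographic_measures(
        rim, params.frame, params.head_radius, sourcil_medial_point(params)
    )


# --------------------------------------------------------------------------
# PAO
# --------------------------------------------------------------------------


def simulate_pao(pre: HipGeometryParams, rotation_deg) -> HipGeometryParams:
    """Rigid reorientation of the cup about the head center.

    ``rotation_deg`` = (about +X, about +Y, about +Z) in degrees, applied in
    that order; each angle limited to +/-45 degrees. For a right hip a
    positive X rotation increases lateral coverage (LCEA) and a negative Y
    rotation (version reduction) increases anterior coverage (ACEA). Radius
    and coverage table are unchanged.
    """
    rx, ry, rz = (float(a) for a in np.asarray(rotation_deg, dtype=float).reshape(3))
    for a in (rx, ry, rz):
        if abs(a) > 45.0:
            raise CohortValidationError("PAO rotation angles limited to +/-45 degrees")
    rot = (
        rotation_matrix([0, 0, 1], rz)
        @ rotation_matrix([0, 1, 0], ry)
        @ rotation_matrix([1, 0, 0], rx)
    )
    return replace(pre, frame=pre.frame.rotated(rot))


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Distributions for covariates and geometry (means, SDs, bounds)."""

    age: tuple = (34.6, 6.4, 18.0, 60.0)
    weight: tuple = (72.5, 14.2, 40.0, 120.0)
    height: tuple = (1.69, 0.08, 1.45, 1.95)
    female_fraction: float = 16.0 / 22.0
    head_radius: tuple = (24.5, 1.5, 20.0, 29.0)
    clearance: float = 4.0
    inclination: tuple = (40.0, 3.0, 30.0, 50.0)
    anteversion: tuple = (20.0, 4.0, 8.0, 32.0)
    pre_lcea: tuple = (17.0, 6.0, 3.0, 26.0)
    pre_acea: tuple = (21.4, 8.0, 4.0, 36.0)
    medial_coverage: tuple = (80.0, 4.0, 65.0, 95.0)
    posterior_coverage: tuple = (75.0, 4.0, 60.0, 90.0)
    post_lcea_target: tuple = (28.6, 3.0, 20.0, 38.0)
    pao_anterior_rotation: tuple = (8.0, 3.0, 0.0, 18.0)
    pao_axial_rotation: tuple = (0.0, 1.5, -5.0, 5.0)
    correction_noise: float = 2.0  # deg, under/overcorrection of lateral aim
    target_element_size: float = 0.7

    def draw(self, rng: np.random.Generator, which: str) -> float:
        mean, sd, lo, hi = getattr(self, which)
        if sd < 0:
            raise CohortValidationError(f"negative SD for {which}")
        for _ in range(200):
            v = rng.normal(mean, sd)
            if lo <= v <= hi:
                return float(v)
        return float(np.clip(mean, lo, hi))


def _solve_coverage(measure_fn, target: float, lo: float = 15.0, hi: float = 119.0) -> float:
    """Invert a monotone coverage->angle relation for one rim knot."""
    f_lo, f_hi = measure_fn(lo) - target, measure_fn(hi) - target
    if f_lo >= 0.0:
        return lo
    if f_hi <= 0.0:
        return hi
    return float(brentq(lambda th: measure_fn(th) - target, lo, hi, xtol=1e-3))


def _geometry_for_targets(
    rng: np.random.Generator, config: CohortConfig, lcea_t: float, acea_t: float,
    head_radius: float, inclination: float, anteversion: float,
    medial: float, posterior: float,
) -> HipGeometryParams:
    frame = cup_frame(inclination_deg=inclination, anteversion_deg=anteversion)
    base = HipGeometryParams(
        head_radius=head_radius,
        cup_radius=head_radius + config.clearance,
        frame=frame,
        coverage=CoverageTable(60.0, 60.0, medial, posterior),
        target_element_size=config.target_element_size,
    )

    def lcea_of(theta_lat: float) -> float:
        p = replace(
            base, coverage=CoverageTable(theta_lat, 60.0, medial, posterior)
        )
        return measures_from_params(p).LCEA

    lat = _solve_coverage(lcea_of, lcea_t)

    def acea_of(theta_ant: float) -> float:
        p = replace(base, coverage=CoverageTable(lat, theta_ant, medial, posterior))
        return measures_from_params(p).ACEA

    ant = _solve_coverage(acea_of, acea_t)
    return replace(base, coverage=CoverageTable(lat, ant, medial, posterior))


def generate_subject(
    rng: np.random.Generator, config: CohortConfig, subject_id: str, side: str = "R"
) -> SubjectRecord:
    sex = "F" if rng.random() < config.female_fraction else "M"
    age = config.draw(rng, "age")
    weight = config.draw(rng, "weight")
    height = config.draw(rng, "height")
    head_radius = config.draw(rng, "head_radius")

    pre = _geometry_for_targets(
        rng,
        config,
        lcea_t=config.draw(rng, "pre_lcea"),
        acea_t=config.draw(rng, "pre_acea"),
        head_radius=head_radius,
        inclination=config.draw(rng, "inclination"),
        anteversion=config.draw(rng, "anteversion"),
        medial=config.draw(rng, "medial_coverage"),
        posterior=config.draw(rng, "posterior_coverage"),
    )
    pre_measures = measures_from_params(pre)

    rx = float(
        np.clip(
            config.draw(rng, "post_lcea_target")
            - pre_measures.LCEA
            + rng.normal(0.0, config.correction_noise),
            0.0,
            40.0,
        )
    )
    # negative Y rotation (version reduction) deepens anterior coverage
    ry = -config.draw(rng, "pao_anterior_rotation")
    rz = config.draw(rng, "pao_axial_rotation")
    post = simulate_pao(pre, (rx, ry, rz))
    post_measures = measures_from_params(post)

    return SubjectRecord(
        id=subject_id,
        side=side,
        sex=sex,
        age=age,
        height=height,
        weight=weight,
        acetabular_radius=pre.cup_radius,
        pre_geometry=pre,
        post_geometry=post,
        pre_measures=pre_measures,
        post_measures=post_measures,
        pao_rotation=(rx, ry, rz),
    )


def generate_cohort(
    n: int,
    seed: int | None = None,
    config: CohortConfig | None = None,
    bilateral: bool = False,
) -> list[SubjectRecord]:
    """Generate ``n`` subjects (one hip each); ``bilateral`` adds a second,
    independently shaped hip for the first subject (the 23rd-hip bookkeeping
    case)."""
    if n < 1:
        raise CohortValidationError("need at least one subject")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    records = [generate_subject(rng, config, f"S{i + 1:03d}") for i in range(n)]
    if bilateral and records:
        first = records[0]
        twin = generate_subject(rng, config, first.id, side="L")
        twin.sex, twin.age, twin.height, twin.weight = (
            first.sex, first.age, first.height, first.weight,
        )
        records.insert(1, twin)
    return records


def cohort_manifest(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = dict(
            id=r.id, side=r.side, sex=r.sex, age=r.age, height_m=r.height,
            weight_kg=r.weight, acetabular_radius_mm=r.acetabular_radius,
        )
        for phase, m in (("pre", r.pre_measures), ("post", r.post_measures)):
            for k, v in m.as_dict().items():
                row[f"{k}_{phase}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
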