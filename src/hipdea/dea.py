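"""Discrete element (bed-of-springs) contact solver for the hip.

The subchondral bone is rigid; cartilage is a bed of independent linear
compressive springs normal to the acetabular contact surface. Spring axes
are radial rays from the cup center, fixed during the solve. The femoral
head has three translational degrees of freedom; at each quasistatic load
instance a damped Gauss-Newton (Levenberg-Marquardt) iteration drives the
residual between applied load and summed spring reactions below tolerance.

Material law: per-area stiffness k = E(1-nu) / ((1+nu)(1-2nu)) / h with h
the acetabular + femoral cartilage thickness in series along the spring axis
(confined-compression aggregate modulus, the standard elastic-foundation
choice). Units: mm, N, MPa.

Convergence: force residual < ``force_residual_tol`` (default 1e-6 N).
Divergence: more than ``max_iterations`` (default 400) iterations, or a
displacement step below ``min_step`` (default 1e-6 mm) while unconverged —
the subluxation signature on undercovered cups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cartilage import ACETABULAR, FEMORAL, CartilageLayer
from .gait import LoadInstance
from .mesh import SphericalFrame, TriSurface, radial_decomposition, rotation_matrix


class SolverError(RuntimeError):
    """Non-finite forces or an inconsistent model (distinct from divergence)."""


@dataclass
class MaterialParams:
    """Isotropic linear elastic cartilage constants."""

    youngs_modulus: float = 12.0  # MPa
    poisson_ratio: float = 0.43

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must lie in (0, 0.5)")

    @property
    def aggregate_modulus(self) -> float:
        """Confined-compression modulus E(1-nu)/((1+nu)(1-2nu)), MPa."""
        e, nu = self.youngs_modulus, self.poisson_ratio
        return e * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))


def spring_constant(mat: MaterialParams, combined_thickness) -> np.ndarray:
    """Per-area spring stiffness (MPa/mm) for a series cartilage stack."""
    h = np.asarray(combined_thickness, dtype=float)
    if np.any(h <= 0):
        raise ValueError("combined thickness must be positive")
    return mat.aggregate_modulus / h


@dataclass
class SolverSettings:
    force_residual_tol: float = 1e-6  # N
    max_iterations: int = 400
    min_step: float = 1e-6  # mm

    def __post_init__(self) -> None:
        if min(self.force_residual_tol, self.max_iterations, self.min_step) <= 0:
            raise ValueError("solver settings must be strictly positive")


@dataclass
class StressField:
    """Equilibrium contact state at one load instance."""

    element_stress: np.ndarray  # MPa, >= 0, 0 where separated
    element_area: np.ndarray  # mm^2
    head_translation: np.ndarray  # mm
    converged: bool
    residual: float  # N
    iterations: int = 0


@dataclass
class Divergence:
    reason: str  # "max_iterations" | "min_step"
    instance_index: int = 0
    residual: float = np.nan
    iterations: int = 0


@dataclass
class SequenceDivergence:
    failed_instances: list[int]
    reasons: list[str]


@dataclass
class GaitStressSequence:
    """Converged stress fields across the discretized stance phase."""

    fields: list[StressField]
    dt: float  # s
    total_area: float  # mm^2, sum of acetabular contact element areas

    def __post_init__(self) -> None:
        if len(self.fields) == 0:
            raise ValueError("empty stress sequence")
        if self.dt <= 0 or self.total_area <= 0:
            raise ValueError("dt and total_area must be positive")

    @property
    def t(self) -> int:
        return len(self.fields)

    @property
    def stresses(self) -> np.ndarray:
        """(t, n) element stress matrix."""
        return np.stack([f.element_stress for f in self.fields])

    @property
    def areas(self) -> np.ndarray:
        return self.fields[0].element_area


# --------------------------------------------------------------------------
# femoral contact surface model
# --------------------------------------------------------------------------


class FemoralSurface:
    """Star-shaped femoral cartilage outer surface about the head center.

    Carries the outer radius and local cartilage thickness as functions of
    body-frame direction. A perfect sphere (the default synthetic head) uses
    exact constant radii; a meshed head with asphericity falls back to
    nearest-direction lookup over its vertices.
    """

    def __init__(
        self,
        outer_radius: float,
        thickness: float,
        dirs_body: np.ndarray | None = None,
        radii: np.ndarray | None = None,
        thicknesses: np.ndarray | None = None,
    ):
        self.mean_outer_radius = float(outer_radius)
        self.mean_thickness = float(thickness)
        self._tree = None
        if dirs_body is not None:
            dirs_body = np.asarray(dirs_body, dtype=float)
            self._tree = cKDTree(dirs_body)
            self._radii = np.asarray(radii, dtype=float)
            self._thk = (
                np.asarray(thicknesses, dtype=float)
                if thicknesses is not None
                else np.full(len(dirs_body), thickness)
            )

    @property
    def is_sphere(self) -> bool:
        return self._tree is None

    @classmethod
    def sphere(cls, head_radius: float, thickness: float = 1.0) -> "FemoralSurface":
        return cls(head_radius + thickness, thickness)

    @classmethod
    def from_layer(cls, layer: CartilageLayer, center: np.ndarray) -> "FemoralSurface":
        if layer.side != FEMORAL:
            raise ValueError("expected a femoral cartilage layer")
        frame = SphericalFrame(center)
        r_out, _, _ = radial_decomposition(layer.contact, frame)
        dirs = (layer.contact.vertices - np.asarray(center)) / r_out[:, None]
        r_sub, _, _ = radial_decomposition(layer.subchondral, frame)
        thk_v = np.abs(r_out - r_sub)
        if float(r_out.std()) < 1e-9 and float(thk_v.std()) < 1e-9:
            return cls(float(r_out.mean()), float(thk_v.mean()))
        return cls(float(r_out.mean()), float(thk_v.mean()), dirs, r_out, thk_v)

    def radius_of(self, dirs_body: np.ndarray) -> np.ndarray:
        if self.is_sphere:
            return np.full(len(dirs_body), self.mean_outer_radius)
        _, idx = self._tree.query(dirs_body)
        return self._radii[idx]

    def thickness_of(self, dirs_body: np.ndarray) -> np.ndarray:
        if self.is_sphere:
            return np.full(len(dirs_body), self.mean_thickness)
        _, idx = self._tree.query(dirs_body)
        return self._thk[idx]


def pose_femur(surface: TriSurface, center: np.ndarray, angles_deg, translation) -> TriSurface:
    """Pose a femoral surface: flexion (about +Z), abduction (about +X),
    internal rotation (about +Y) about the head center, then translate."""
    rot = pose_rotation(angles_deg)
    posed = surface.transformed(rot, center)
    return TriSurface(posed.vertices + np.asarray(translation, dtype=float), posed.faces)


def pose_rotation(angles_deg) -> np.ndarray:
    flex, abd, rot = (float(a) for a in np.asarray(angles_deg, dtype=float).reshape(3))
    return (
        rotation_matrix([0.0, 1.0, 0.0], rot)
        @ rotation_matrix([1.0, 0.0, 0.0], abd)
        @ rotation_matrix([0.0, 0.0, 1.0], flex)
    )


# --------------------------------------------------------------------------
# assembled contact model
# --------------------------------------------------------------------------


class ContactModel:
    """Assembled spring-bed model of one hip.

    Per acetabular contact element: the unit spring ray from the cup center,
    the contact-surface radius along that ray, the element area, and the
    series stiffness from acetabular + femoral thickness sampled on the same
    ray (at the neutral pose).
    """

    def __init__(
        self,
        acet_layer: CartilageLayer,
        femur: FemoralSurface,
        frame: SphericalFrame,
        material: MaterialParams | None = None,
    ):
        if acet_layer.side != ACETABULAR:
            raise ValueError("expected an acetabular cartilage layer")
        material = material or MaterialParams()
        self.frame = frame
        self.femur = femur
        self.material = material

        center = frame.center
        contact = acet_layer.contact
        rel = contact.element_centroid - center
        self.dirs = rel / np.linalg.norm(rel, axis=1)[:, None]
        # surface radius along the ray: mean vertex radius is sagitta-free
        # (the chord centroid sits below the smooth surface by ~l^2/R)
        vert_r = np.linalg.norm(contact.vertices - center, axis=1)
        self.r_contact = vert_r[contact.faces].mean(axis=1)
        self.areas = acet_layer.contact.element_area
        h_fem = femur.thickness_of(self.dirs)
        self.h_combined = acet_layer.thickness + h_fem
        self.k = spring_constant(material, self.h_combined)
        self.total_area = float(self.areas.sum())

    @property
    def n_elements(self) -> int:
        return len(self.areas)

    def penetrations(self, translation, rotation: np.ndarray | None = None) -> np.ndarray:
        """Spring compressions (mm) for a head translation (and body rotation).

        For each element, the overlap along its ray between the femoral
        cartilage outer surface and the acetabular contact surface; rays that
        miss the femur, or separated springs, report zero.
        """
        o = np.asarray(translation, dtype=float).reshape(3)
        b = self.dirs @ o
        c2 = float(o @ o)
        if self.femur.is_sphere:
            r_o = self.femur.mean_outer_radius
            disc = b * b - c2 + r_o * r_o
            hit = disc > 0.0
            s_far = np.where(hit, b + np.sqrt(np.maximum(disc, 0.0)), -np.inf)
        else:
            # star-shaped head: fixed-point on the direction-dependent radius
            r_o = self.femur.mean_outer_radius
            disc = b * b - c2 + r_o * r_o
            hit = disc > 0.0
            s_far = np.where(hit, b + np.sqrt(np.maximum(disc, 0.0)), np.nan)
            rot = rotation if rotation is not None else np.eye(3)
            for _ in range(4):
                pts = s_far[:, None] * self.dirs - o[None, :]
                norm = np.linalg.norm(pts, axis=1)
                ok = hit & (norm > 1e-9)
                u_body = np.zeros_like(pts)
                u_body[ok] = (pts[ok] / norm[ok, None]) @ rot  # inverse rotation
                r_dir = np.where(ok, self.femur.radius_of(u_body), r_o)
                disc = b * b - c2 + r_dir * r_dir
                hit = disc > 0.0
                s_far = np.where(hit, b + np.sqrt(np.maximum(disc, 0.0)), np.nan)
            s_far = np.where(hit, s_far, -np.inf)
        return np.maximum(s_far - self.r_contact, 0.0)

    def residual_force(
        self, translation, applied_force, rotation: np.ndarray | None = None
    ) -> np.ndarray:
        """R = F_applied - sum_i p_i a_i d_i (N); zero at equilibrium."""
        delta = self.penetrations(translation, rotation)
        p = self.k * delta
        reaction = (p * self.areas) @ self.dirs
        r = np.asarray(applied_force, dtype=float) - reaction
        if not np.all(np.isfinite(r)):
            raise SolverError("non-finite residual force")
        return r

    def stresses(self, translation, rotation: np.ndarray | None = None) -> np.ndarray:
        return self.k * self.penetrations(translation, rotation)


# --------------------------------------------------------------------------
# solvers
# --------------------------------------------------------------------------


def _seek_contact(model: ContactModel, force: np.ndarray, max_travel: float = 10.0):
    """March the head along the load direction to the first spring contact.

    Returns a translation with a slight initial overlap, or None when the
    head never meets the cup within ``max_travel`` mm (subluxation path; the
    solver then diverges by its own step criterion).
    """
    f_norm = float(np.linalg.norm(force))
    if f_norm == 0.0:
        return np.zeros(3)
    d = np.asarray(force, dtype=float) / f_norm
    step = 0.05
    s = 0.0
    tol = 1e-6  # mm of overlap that counts as engaged contact
    while s <= max_travel:
        s += step
        if model.penetrations(s * d).max(initial=0.0) > tol:
            lo, hi = s - step, s
            for _ in range(30):
                mid = 0.5 * (lo + hi)
                if model.penetrations(mid * d).max(initial=0.0) > tol:
                    hi = mid
                else:
                    lo = mid
            return _axial_equilibrium(model, force, (hi + 1e-3), d, max_travel)
    return None


def _axial_equilibrium(
    model: ContactModel, force: np.ndarray, s_touch: float, d: np.ndarray,
    max_travel: float,
) -> np.ndarray:
    """1-D pre-equilibration along the load axis from the touch point.

    Marches the head deeper until the along-load spring reaction exceeds the
    applied load, then bisects. This gives the LM polish a start already in
    force balance along the dominant direction; without it, cold starts at
    light loads begin from a nearly empty contact set with a near-singular
    Jacobian.
    """
    def axial_excess(s: float) -> float:
        return float(d @ model.residual_force(s * d, force))

    lo = s_touch
    hi = lo
    step = 0.05
    while hi < s_touch + max_travel:
        hi = hi + step
        if axial_excess(hi) < 0.0:
            break
        step *= 1.5
    else:
        return s_touch * d  # reaction never reaches the load: likely subluxing
    if axial_excess(lo) < 0.0:
        return lo * d
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if axial_excess(mid) < 0.0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi) * d


def solve_instance(
    model: ContactModel,
    instance: LoadInstance,
    settings: SolverSettings | None = None,
    init: np.ndarray | None = None,
):
    """Quasistatic equilibrium for one load instance.

    Returns a :class:`StressField` on convergence or a :class:`Divergence`
    when the iteration budget is exhausted or the step collapses while the
    residual is still above tolerance.
    """
    settings = settings or SolverSettings()
    force = np.asarray(instance.force, dtype=float)
    rotation = pose_rotation(instance.angles)

    def resid(x):
        return model.residual_force(x, force, rotation)

    x = np.zeros(3) if init is None else np.asarray(init, dtype=float).copy()
    r = resid(x)
    if float(np.linalg.norm(r)) < settings.force_residual_tol:
        return StressField(
            model.stresses(x, rotation), model.areas.copy(), x, True,
            float(np.linalg.norm(r)), 0,
        )
    # grazing (round-off level) contact is no contact: without a meaningful
    # engaged spring set the Jacobian is singular along the load
    if init is None and model.penetrations(x, rotation).max(initial=0.0) < 1e-6:
        seeded = _seek_contact(model, force)
        if seeded is not None:
            x = seeded
            r = resid(x)

    lam = 1e-3
    fd_step = 1e-5  # mm, forward differences
    cost = float(r @ r)
    prev_rnorm = float(np.linalg.norm(r))
    for it in range(1, settings.max_iterations + 1):
        jac = np.empty((3, 3))
        for j in range(3):
            xp = x.copy()
            xp[j] += fd_step
            jac[:, j] = (resid(xp) - r) / fd_step
        jtj = jac.T @ jac
        jtr = jac.T @ r
        step_norm = 0.0
        accepted = False
        for _ in range(25):
            try:
                dx = -np.linalg.solve(
                    jtj + lam * np.diag(np.maximum(np.diag(jtj), 1e-12)), jtr
                )
            except np.linalg.LinAlgError:
                dx = np.zeros(3)
            step_norm = float(np.linalg.norm(dx))
            # always try the candidate step: a sub-min_step polish may still
            # drop the residual under tolerance, and the divergence rule only
            # applies to steps that fail to reach equilibrium
            r_new = resid(x + dx)
            cost_new = float(r_new @ r_new)
            if cost_new < cost:
                x = x + dx
                r = r_new
                cost = cost_new
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            if step_norm < settings.min_step:
                break
            lam *= 4.0
        rnorm = float(np.linalg.norm(r))
        if rnorm < settings.force_residual_tol:
            return StressField(
                model.stresses(x, rotation), model.areas.copy(), x, True, rnorm, it
            )
        # a collapsed step only signals divergence when the residual has also
        # stopped contracting; a quadratic Newton tail passes through the
        # min-step band one iteration before crossing the force tolerance
        stalled = rnorm > 0.5 * prev_rnorm
        if not accepted or (step_norm < settings.min_step and stalled):
            return Divergence("min_step", instance.index, rnorm, it)
        prev_rnorm = rnorm
    return Divergence("max_iterations", instance.index, float(np.linalg.norm(r)),
                      settings.max_iterations)


def solve_sequence(
    model: ContactModel,
    instances: list[LoadInstance],
    settings: SolverSettings | None = None,
):
    """Solve all stance instances with warm starting; all-or-nothing.

    Any diverging instance voids the whole sequence (the exclusion rule for
    subluxating hips): a :class:`SequenceDivergence` lists the failures.
    """
    settings = settings or SolverSettings()
    fields: list[StressField] = []
    failures: list[int] = []
    reasons: list[str] = []
    init = None
    for inst in instances:
        out = solve_instance(model, inst, settings, init=init)
        if isinstance(out, Divergence):
            failures.append(inst.index)
            reasons.append(out.reason)
            init = None
            continue
        fields.append(out)
        init = out.head_translation
    if failures:
        return SequenceDivergence(failures, reasons)
    return GaitStressSequence(fields, instances[0].dt, model.total_area)
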