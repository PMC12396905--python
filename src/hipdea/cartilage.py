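"""Cartilage layer generation from subchondral surfaces.

Two models are provided. The uniform-offset model ("Shivanna") recreates
healthy cartilage by offsetting each subchondral node 1 mm along its radial
axis into the joint space and smoothing the result toward sphericity with a
clamped neighbour-average rule. The mapped-thickness model ("Nishii")
recreates dysplastic acetabular cartilage — thicker toward the lateral rim —
by offsetting nodes according to a biharmonic-spline thickness map in
spherical coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator

from .mesh import MeshValidationError, SphericalFrame, TriSurface, radial_decomposition, spherical_compose

ACETABULAR = "acetabular"
FEMORAL = "femoral"


@dataclass
class ShivannaParams:
    """Uniform-offset cartilage parameters.

    offset: nominal cartilage thickness, mm.
    smoothing_iterations: sphericity-smoothing passes after the offset.
    max_step: per-vertex per-iteration clamp on the radial move, mm.
    """

    offset: float = 1.0
    smoothing_iterations: int = 5
    max_step: float = 0.05

    def __post_init__(self) -> None:
        if self.offset <= 0:
            raise ValueError("offset must be positive")
        if self.smoothing_iterations < 0:
            raise ValueError("smoothing_iterations must be >= 0")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


@dataclass
class CartilageLayer:
    """Paired subchondral/contact surfaces with per-element thickness (mm)."""

    subchondral: TriSurface
    contact: TriSurface
    thickness: np.ndarray
    side: str

    def __post_init__(self) -> None:
        if self.side not in (ACETABULAR, FEMORAL):
            raise ValueError(f"unknown side {self.side!r}")
        self.thickness = np.asarray(self.thickness, dtype=float)
        if len(self.thickness) != self.contact.n_faces:
            raise ValueError("thickness must be per contact element")
        if np.any(self.thickness <= 0):
            raise MeshValidationError("cartilage thickness must be positive everywhere")


def sphericity_smooth(
    surface: TriSurface,
    frame: SphericalFrame,
    iterations: int,
    max_step: float = 0.05,
) -> TriSurface:
    """Smooth vertex radii toward the neighbour average (Jacobi sweeps).

    Each iteration moves every vertex radius toward the mean radius of its
    mesh neighbours, clamped to ``max_step`` mm, using the previous iterate
    for all neighbour values (order independent). Angular coordinates are
    untouched. Isolated vertices are left in place with a warning.
    """
    r, polar, azimuth = radial_decomposition(surface, frame)
    adjacency = surface.vertex_adjacency
    isolated = [i for i, nb in enumerate(adjacency) if len(nb) == 0]
    if isolated:
        warnings.warn(f"{len(isolated)} isolated vertices left unsmoothed", stacklevel=2)
    for _ in range(iterations):
        r_new = r.copy()
        for i, nb in enumerate(adjacency):
            if len(nb) == 0:
                continue
            delta = r[nb].mean() - r[i]
            r_new[i] = r[i] + np.clip(delta, -max_step, max_step)
        r = r_new
    verts = spherical_compose(r, polar, azimuth, frame)
    return TriSurface(verts, surface.faces.copy())


def _element_thickness(sub: TriSurface, contact: TriSurface, frame: SphericalFrame) -> np.ndarray:
    """Per-element radial distance between the paired surfaces."""
    r_sub, _, _ = radial_decomposition(sub, frame)
    r_con, _, _ = radial_decomposition(contact, frame)
    per_vertex = np.abs(r_sub - r_con)
    return per_vertex[contact.faces].mean(axis=1)


def shivanna_offset(
    sub: TriSurface,
    frame: SphericalFrame,
    params: ShivannaParams | None = None,
    side: str = ACETABULAR,
) -> CartilageLayer:
    """Uniform radial offset into the joint space, then sphericity smoothing.

    Acetabular surfaces are offset toward the joint center, femoral surfaces
    away from it, so both layers carry ``params.offset`` of nominal cartilage
    between bone and joint space.
    """
    params = params or ShivannaParams()
    if side not in (ACETABULAR, FEMORAL):
        raise ValueError(f"unknown side {side!r}")
    r, polar, azimuth = radial_decomposition(sub, frame)
    sign = -1.0 if side == ACETABULAR else 1.0
    r_new = r + sign * params.offset
    if np.any(r_new <= 0):
        raise MeshValidationError("offset exceeds local radius")
    contact = TriSurface(spherical_compose(r_new, polar, azimuth, frame), sub.faces.copy())
    if params.smoothing_iterations > 0:
        contact = sphericity_smooth(
            contact, frame, params.smoothing_iterations, params.max_step
        )
    thickness = _element_thickness(sub, contact, frame)
    return CartilageLayer(sub, contact, thickness, side)


# --------------------------------------------------------------------------
# mapped thickness
# --------------------------------------------------------------------------


@dataclass
class ThicknessMap:
    """Biharmonic-spline thickness distribution over (polar, azimuth) degrees.

    The interpolant is exact at the samples and C1 in between; evaluation is
    clamped below at ``floor`` mm so derived layers keep positive thickness.
    """

    samples: np.ndarray  # (n, 3): polar_deg, azimuth_deg, thickness_mm
    floor: float = 0.2
    _rbf: RBFInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be (n, 3): polar, azimuth, thickness")
        if len(self.samples) < 3:
            raise ValueError("need at least 3 thickness samples")
        if np.any(self.samples[:, 2] <= 0):
            raise ValueError("sample thicknesses must be positive")
        sites = self.samples[:, :2]
        d = sites[:, None, :] - sites[None, :, :]
        dist = np.linalg.norm(d, axis=-1)
        np.fill_diagonal(dist, np.inf)
        if dist.min() < 1e-9:
            raise ValueError("duplicate thickness sample sites")
        if np.linalg.matrix_rank(sites - sites.mean(axis=0), tol=1e-9) < 2:
            raise ValueError("sample sites are collinear")
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        self._rbf = RBFInterpolator(sites, self.samples[:, 2], kernel="thin_plate_spline")

    def raw(self, polar_deg, azimuth_deg) -> np.ndarray:
        pts = np.stack(
            [np.atleast_1d(np.asarray(polar_deg, dtype=float)),
             np.atleast_1d(np.asarray(azimuth_deg, dtype=float))],
            axis=-1,
        )
        return self._rbf(pts)

    def __call__(self, polar_deg, azimuth_deg) -> np.ndarray:
        return np.maximum(self.raw(polar_deg, azimuth_deg), self.floor)


def fit_thickness_map(samples, floor: float = 0.2) -> ThicknessMap:
    """Fit an exact biharmonic-spline map from (polar, azimuth, thickness) rows."""
    return ThicknessMap(np.asarray(samples, dtype=float), floor=floor)


def default_dysplastic_map() -> ThicknessMap:
    """Packaged 12-site synthetic dysplastic acetabular map.

    Thickness rises from 1.4 mm centrally to 2.6 mm in the rim band toward
    the superolateral azimuth, emulating the reported rim-thickened pattern
    of dysplastic acetabula. The values are synthetic placeholders, not a
    digitised cadaveric dataset; study users can supply their own CSV.
    """
    rows = []
    for az in (-135.0, -45.0, 45.0, 135.0):
        rows.append((15.0, az, 1.4))
    for az in (-90.0, 0.0, 90.0, 180.0):
        rows.append((45.0, az, 1.8))
    # rim band: thickest toward azimuth 0 (superolateral)
    for az, th in ((0.0, 2.6), (90.0, 2.2), (180.0, 1.9), (-90.0, 2.2)):
        rows.append((75.0, az, th))
    return ThicknessMap(np.asarray(rows))


def nishii_offset(
    sub: TriSurface, frame: SphericalFrame, thickness_map: ThicknessMap
) -> CartilageLayer:
    """Offset an acetabular subchondral surface by a mapped thickness.

    Each vertex moves toward the joint center by the map value at its
    spherical coordinates; element thickness is the map at the element
    centroid. Topology is preserved (element correspondence is kept for
    thickness bookkeeping).
    """
    r, polar, azimuth = radial_decomposition(sub, frame)
    t_vertex = thickness_map(polar, azimuth)
    if np.any(t_vertex <= 0):
        raise MeshValidationError("thickness map non-positive on the surface")
    r_new = r - t_vertex
    if np.any(r_new <= 0):
        raise MeshValidationError("mapped offset exceeds local radius")
    contact = TriSurface(spherical_compose(r_new, polar, azimuth, frame), sub.faces.copy())
    _, cpol, caz = radial_decomposition(contact.element_centroid, frame)
    thickness = thickness_map(cpol, caz)
    return CartilageLayer(sub, contact, thickness, ACETABULAR)
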