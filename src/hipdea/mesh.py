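"""Triangulated open-surface geometry for joint contact modelling.

The carriers here are deliberately minimal: a :class:`TriSurface` is an open
triangulated patch (subchondral bone or cartilage contact surface, units mm)
with per-element area/centroid/normal, and a :class:`SphericalFrame` is the
joint-centred frame used for radial (spherical-coordinate) decompositions.
Everything downstream — cartilage generation, contact springs, radiographic
angles — is expressed through these two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import Delaunay


class MeshValidationError(ValueError):
    """Raised when a mesh violates a structural invariant."""


# --------------------------------------------------------------------------
# frames
# --------------------------------------------------------------------------


@dataclass
class SphericalFrame:
    """A joint-centred right-handed frame.

    ``axes`` rows are (e1, e2, e3): e3 is the pole of the spherical
    decomposition (polar angle measured from e3, azimuth from e1 toward e2).
    Coordinates are mm throughout.
    """

    center: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise MeshValidationError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise MeshValidationError("frame axes are left-handed")

    @property
    def pole(self) -> np.ndarray:
        return self.axes[2]

    def rotated(self, rotation: np.ndarray) -> "SphericalFrame":
        """Rigidly rotate the frame axes about its own center."""
        return SphericalFrame(self.center.copy(), self.axes @ np.asarray(rotation).T)


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation about ``axis`` by ``angle_deg`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array(
        [[0.0, -axis[2], axis[1]], [axis[2], 0.0, -axis[0]], [-axis[1], axis[0], 0.0]]
    )
    return np.eye(3) + np.sin(a) * k + (1.0 - np.cos(a)) * (k @ k)


# --------------------------------------------------------------------------
# surfaces
# --------------------------------------------------------------------------


class TriSurface:
    """An open triangulated surface with per-element properties.

    Degenerate (zero-area) faces are dropped at construction; faces must
    reference valid vertices. Normals are unit length but their orientation
    is only meaningful after :meth:`oriented` fixes them relative to a joint
    center.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (V, 3)")
        if faces.ndim != 2 or faces.shape[1] != 3 or len(faces) == 0:
            raise MeshValidationError("faces must be a non-empty (F, 3) array")
        if faces.min() < 0 or faces.max() >= len(vertices):
            raise MeshValidationError("face references an invalid vertex")

        v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
        cross = np.cross(v1 - v0, v2 - v0)
        area2 = np.linalg.norm(cross, axis=1)
        scale = max(float(np.ptp(vertices)), 1.0)
        keep = area2 > 1e-12 * scale**2
        if not keep.any():
            raise MeshValidationError("mesh has only degenerate faces")
        faces = faces[keep]
        cross = cross[keep]
        area2 = area2[keep]

        self.vertices = vertices
        self.faces = faces
        self.element_area = 0.5 * area2
        self.element_centroid = vertices[faces].mean(axis=1)
        self.element_normal = cross / area2[:, None]

    # -- basic properties ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def total_area(self) -> float:
        return float(self.element_area.sum())

    @property
    def vertex_adjacency(self) -> list[np.ndarray]:
        """Neighbor vertex index sets (cached)."""
        if not hasattr(self, "_adjacency"):
            neighbors: list[set] = [set() for _ in range(self.n_vertices)]
            for a, b, c in self.faces:
                neighbors[a].update((b, c))
                neighbors[b].update((a, c))
                neighbors[c].update((a, b))
            self._adjacency = [np.fromiter(s, dtype=np.int64) for s in neighbors]
        return self._adjacency

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def mean_edge_length(self) -> float:
        e = self.edges()
        return float(
            np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean()
        )

    def boundary_vertices(self) -> np.ndarray:
        """Vertices on the open boundary (edges used by exactly one face)."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        border = uniq[counts == 1]
        if len(border) == 0:
            raise MeshValidationError("surface has no boundary (closed mesh?)")
        return np.unique(border)

    # -- transforms ---------------------------------------------------------

    def oriented(self, center: np.ndarray, outward: bool) -> "TriSurface":
        """Return a copy with all face windings consistent about ``center``.

        ``outward=True`` makes normals point away from ``center`` (femoral
        convention); ``outward=False`` points them toward it (acetabular
        convention: toward the head center / joint space).
        """
        center = np.asarray(center, dtype=float)
        dots = np.einsum("ij,ij->i", self.element_normal, self.element_centroid - center)
        want = 1.0 if outward else -1.0
        flip = dots * want < 0
        faces = self.faces.copy()
        faces[flip] = faces[flip][:, [0, 2, 1]]
        out = TriSurface(self.vertices.copy(), faces)
        dots = np.einsum(
            "ij,ij->i", out.element_normal, out.element_centroid - center
        )
        if not ((dots * want) > 0).all():
            raise MeshValidationError(
                "winding could not be made consistent by reorientation"
            )
        return out

    def transformed(self, rotation: np.ndarray, about: np.ndarray) -> "TriSurface":
        """Rigidly rotate the surface about a point."""
        about = np.asarray(about, dtype=float)
        rotation = np.asarray(rotation, dtype=float)
        verts = (self.vertices - about) @ rotation.T + about
        return TriSurface(verts, self.faces.copy())

    def subdivided(self) -> "TriSurface":
        """Midpoint 1→4 subdivision (area preserving)."""
        verts = [tuple(v) for v in self.vertices]
        index: dict = {}
        new_vertices = list(self.vertices)

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in index:
                index[key] = len(new_vertices)
                new_vertices.append(0.5 * (self.vertices[i] + self.vertices[j]))
            return index[key]

        del verts
        new_faces = []
        for a, b, c in self.faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        return TriSurface(np.asarray(new_vertices), np.asarray(new_faces))

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_FORMATS = {"ply", "stl", "obj"}


def read_surface(path, fmt: str | None = None) -> TriSurface:
    """Read a triangulated surface (PLY/STL/OBJ, coordinates in mm)."""
    if fmt is not None and fmt.lower() not in _FORMATS:
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        mesh = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise loader failures
        raise MeshValidationError(f"could not read mesh from {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshValidationError(f"{path} contains no triangulated surface")
    return TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def write_surface(surface: TriSurface, path) -> None:
    surface.to_trimesh().export(str(path))


# --------------------------------------------------------------------------
# spherical decomposition
# --------------------------------------------------------------------------


def radial_decomposition(
    points_or_surface, frame: SphericalFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose vertices into (radius mm, polar deg in [0,180], azimuth deg in [-180,180)).

    Polar angle is measured from the frame pole (e3), azimuth from e1 toward
    e2. Raises if any point coincides with the frame center.
    """
    pts = (
        points_or_surface.vertices
        if isinstance(points_or_surface, TriSurface)
        else np.asarray(points_or_surface, dtype=float)
    )
    rel = (pts - frame.center) @ frame.axes.T  # local coordinates
    r = np.linalg.norm(rel, axis=-1)
    if np.any(r < 1e-12):
        raise MeshValidationError("point coincides with frame center")
    polar = np.rad2deg(np.arccos(np.clip(rel[..., 2] / r, -1.0, 1.0)))
    azimuth = np.rad2deg(np.arctan2(rel[..., 1], rel[..., 0]))
    azimuth = np.where(azimuth >= 180.0, azimuth - 360.0, azimuth)
    return r, polar, azimuth


def spherical_compose(
    r: np.ndarray, polar_deg: np.ndarray, azimuth_deg: np.ndarray, frame: SphericalFrame
) -> np.ndarray:
    """Inverse of :func:`radial_decomposition`."""
    th = np.deg2rad(np.asarray(polar_deg, dtype=float))
    ph = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    r = np.asarray(r, dtype=float)
    local = np.stack(
        [r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph), r * np.cos(th)],
        axis=-1,
    )
    return local @ frame.axes + frame.center


# --------------------------------------------------------------------------
# parametric spherical-cap mesher
# --------------------------------------------------------------------------


def spherical_cap_mesh(
    radius: float,
    coverage_deg,
    frame: SphericalFrame,
    target_edge: float,
    radial_offsets=None,
) -> TriSurface:
    """Mesh a spherical cap of ``radius`` about the frame pole.

    ``coverage_deg`` is either a scalar polar extent or a callable mapping
    azimuth (deg) to the rim polar angle (deg). Points are laid out on
    concentric rings with spacing close to ``target_edge`` and triangulated
    by a planar Delaunay in normalised cap coordinates, so the rim lies
    exactly on the coverage curve. ``radial_offsets``, if given, is a
    callable(polar_deg, azimuth_deg) -> additive radius perturbation (mm).
    """
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    if callable(coverage_deg):
        cov = coverage_deg
    else:
        value = float(coverage_deg)
        cov = lambda az: np.full_like(np.asarray(az, dtype=float), value)  # noqa: E731

    az_probe = np.linspace(-180.0, 180.0, 181)
    theta_probe = np.asarray(cov(az_probe), dtype=float)
    if np.any(theta_probe <= 0.0):
        raise MeshValidationError("coverage must be positive for all azimuths")
    theta_bar = np.deg2rad(theta_probe.mean())

    n_rings = max(3, int(round(theta_bar * radius / target_edge)))
    pts = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        t = k / n_rings
        ring_theta = t * theta_bar
        n_k = max(6, int(round(2.0 * np.pi * radius * np.sin(ring_theta) / target_edge)))
        phase = (k % 2) * np.pi / n_k
        phi = phase + np.arange(n_k) * 2.0 * np.pi / n_k
        pts.extend(zip(t * np.cos(phi), t * np.sin(phi)))
    pts2d = np.asarray(pts)

    faces = Delaunay(pts2d).simplices
    t = np.hypot(pts2d[:, 0], pts2d[:, 1])
    phi = np.arctan2(pts2d[:, 1], pts2d[:, 0])
    az_deg = np.rad2deg(phi)
    theta_deg = t * np.asarray(cov(az_deg), dtype=float)

    r = np.full(len(pts2d), float(radius))
    if radial_offsets is not None:
        r = r + np.asarray(radial_offsets(theta_deg, az_deg), dtype=float)
    verts = spherical_compose(r, theta_deg, az_deg, frame)
    return TriSurface(verts, faces)


def icosphere(radius: float = 1.0, subdivisions: int = 3) -> TriSurface:
    """Closed icosphere fixture (delegates to trimesh)."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface(np.asarray(m.vertices), np.asarray(m.faces))
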