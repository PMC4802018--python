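"""Biplane projective geometry and the three renderers.

A biplane C-arm acquires two simultaneous X-ray projections, each described
by a 3x4 projection matrix ``P`` mapping homogeneous world coordinates (mm)
to homogeneous pixel coordinates.  This module holds the geometry container,
the rigid transform (translation-only, see :class:`RigidTransform`), the 3D
chamber model container, and the three forward renderers the similarity
measures consume:

* :func:`render_shadow` — binary footprint ``S_T`` of the transformed model,
* :func:`render_apparent_edges` — apparent-edge image ``E_T`` rendered from
  the surface mesh with per-triangle opacity ``o = 1 - |d.n|``,
* :func:`compute_cade` — contrast-agent distribution estimate ``C_T^3D``
  (binary reconstruction of contrasted chamber voxels from two thresholded
  projections) with its forward projections ``C_T^A``, ``C_T^B``.

Conventions: 0-based pixel indices with pixel centers at integers; pixel
coordinates are ``(u, v) = (column, row)``; world units are mm; matrices are
row-major.  Projection matrices are normalized on construction so that the
third row of their left 3x3 block is a unit vector with positive depth in
front of the camera.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import trimesh
from numba import njit
from scipy import ndimage

from ._util import warn_once

__all__ = [
    "AtriumModel",
    "CADEResult",
    "ProjectionGeometry",
    "RigidTransform",
    "camera_center",
    "compute_cade",
    "make_biplane_geometry",
    "normalize_projection_matrix",
    "project_point",
    "project_points",
    "render_apparent_edges",
    "render_shadow",
    "triangle_opacities",
]


# ---------------------------------------------------------------------------
# transforms and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Rigid transform of the chamber model.

    Only the 3-DOF translation ``t`` (mm) is parameterized: the evaluation
    protocol this tool follows registers translation only, since patient
    positioning rules out large rotations and small ones are below what can
    be corrected reliably from faint contrast.  The type is the extension
    point should rotation ever be added.
    """

    t: np.ndarray

    def __init__(self, t=(0.0, 0.0, 0.0)):
        t = np.asarray(t, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "t", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls((0.0, 0.0, 0.0))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of world points."""
        return np.asarray(points, dtype=float) + self.t

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RigidTransform(t=[{self.t[0]:.3f}, {self.t[1]:.3f}, {self.t[2]:.3f}])"


@dataclass
class AtriumModel:
    """3D chamber model: binary voxel indicator plus surface mesh.

    ``volume[i, j, k]`` is the indicator chi(v) of the chamber interior on a
    voxel grid with isotropic ``spacing`` (mm); voxel ``(i, j, k)`` has its
    center at ``origin + spacing * (i, j, k)`` in world mm, axes (x, y, z).
    ``mesh`` is the corresponding watertight triangle surface in world mm.
    """

    volume: np.ndarray
    spacing: float
    origin: np.ndarray
    mesh: trimesh.Trimesh

    def __post_init__(self):
        self.volume = np.ascontiguousarray(self.volume.astype(bool))
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @cached_property
    def voxel_centers(self) -> np.ndarray:
        """(N, 3) world coordinates of all interior (chi=1) voxel centers."""
        idx = np.argwhere(self.volume)
        return self.origin + self.spacing * idx.astype(float)

    @cached_property
    def voxel_indices(self) -> np.ndarray:
        """(N, 3) integer grid indices of the interior voxels."""
        return np.argwhere(self.volume)

    @property
    def n_voxels(self) -> int:
        return int(self.volume.sum())


@dataclass
class CADEResult:
    """Contrast-agent distribution estimate for one transform.

    ``C3D`` is a binary grid on the model grid (chamber voxels estimated as
    contrasted); ``C_A``/``C_B`` are its forward projections (splatted) into
    the two planes.
    """

    C3D: np.ndarray
    C_A: np.ndarray
    C_B: np.ndarray


# ---------------------------------------------------------------------------
# projection matrices
# ---------------------------------------------------------------------------


def normalize_projection_matrix(P: np.ndarray) -> np.ndarray:
    """Scale a 3x4 projection matrix to a canonical form.

    After normalization the third row of the left 3x3 block is a unit vector
    and the homogeneous scale ``w`` of a projected point equals its signed
    depth (mm) in front of the camera.
    """
    P = np.asarray(P, dtype=float).reshape(3, 4).copy()
    M = P[:, :3]
    if np.linalg.matrix_rank(M) != 3:
        raise ValueError("projection matrix left 3x3 block must have rank 3")
    P /= np.linalg.norm(M[2])
    if np.linalg.det(P[:, :3]) < 0:
        P = -P
    return P


def camera_center(P: np.ndarray) -> np.ndarray:
    """World position of the X-ray source (the camera center) for ``P``."""
    P = np.asarray(P, dtype=float)
    return -np.linalg.solve(P[:, :3], P[:, 3])


def principal_direction(P: np.ndarray) -> np.ndarray:
    """Unit viewing direction of the camera (toward the detector)."""
    P = normalize_projection_matrix(P)
    return P[2, :3]


def focal_lengths_px(P: np.ndarray) -> tuple[float, float]:
    """Focal lengths (pixels) of a zero-skew pinhole matrix."""
    P = normalize_projection_matrix(P)
    m0, m1, m2 = P[0, :3], P[1, :3], P[2, :3]
    u0 = float(m0 @ m2)
    v0 = float(m1 @ m2)
    fu = float(np.linalg.norm(m0 - u0 * m2))
    fv = float(np.linalg.norm(m1 - v0 * m2))
    return fu, fv


def project_points(P: np.ndarray, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project (N, 3) world points; returns (uv (N, 2), depth w (N,)).

    ``uv`` columns are (u=column, v=row) after perspective division.  Points
    with ``w == 0`` (on the camera plane) yield non-finite uv; callers that
    need strictness use :func:`project_point`.
    """
    pts = np.asarray(points, dtype=float)
    P = np.asarray(P, dtype=float)
    h = pts @ P[:, :3].T + P[:, 3]
    w = h[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        uv = h[:, :2] / w[:, None]
    return uv, w


def project_point(P: np.ndarray, x) -> tuple[float, float]:
    """Project a single world point (mm) to pixel coordinates ``(u, v)``.

    Raises ``ValueError`` for points on the camera plane (homogeneous w=0),
    which project to infinity.
    """
    uv, w = project_points(P, np.asarray(x, dtype=float).reshape(1, 3))
    if w[0] == 0.0:
        raise ValueError("point lies on the camera plane (w = 0): projects to infinity")
    return float(uv[0, 0]), float(uv[0, 1])


def back_project_ray(P: np.ndarray, pixel) -> tuple[np.ndarray, np.ndarray]:
    """Ray (origin at source, unit direction into the scene) through a pixel."""
    P = normalize_projection_matrix(P)
    c = camera_center(P)
    u, v = float(pixel[0]), float(pixel[1])
    d = np.linalg.solve(P[:, :3], np.array([u, v, 1.0]))
    d /= np.linalg.norm(d)
    # orient the ray into the half-space in front of the camera
    if d @ P[2, :3] < 0:
        d = -d
    return c, d


# ---------------------------------------------------------------------------
# geometry container
# ---------------------------------------------------------------------------


@dataclass
class ProjectionGeometry:
    """Calibrated biplane geometry: matrices P_A, P_B plus detector layout.

    ``image_shape`` is (rows, cols); ``pixel_spacing`` is the detector pixel
    pitch in mm.  Both matrices are normalized on construction.  The two
    principal rays must not be parallel, otherwise the biplane system
    degenerates to a single view and image-center triangulation is undefined.
    """

    P_A: np.ndarray
    P_B: np.ndarray
    image_shape: tuple[int, int]
    pixel_spacing: float = 1.0

    def __post_init__(self):
        self.P_A = normalize_projection_matrix(self.P_A)
        self.P_B = normalize_projection_matrix(self.P_B)
        self.image_shape = (int(self.image_shape[0]), int(self.image_shape[1]))
        d_a = self.P_A[2, :3]
        d_b = self.P_B[2, :3]
        if np.linalg.norm(np.cross(d_a, d_b)) < 1e-8:
            raise ValueError("principal rays of planes A and B are parallel")

    @property
    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        return self.P_A, self.P_B

    def to_dict(self) -> dict:
        return {
            "P_A": self.P_A.tolist(),
            "P_B": self.P_B.tolist(),
            "image_shape": list(self.image_shape),
            "pixel_spacing": self.pixel_spacing,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        return cls(
            P_A=np.asarray(d["P_A"], dtype=float),
            P_B=np.asarray(d["P_B"], dtype=float),
            image_shape=tuple(d["image_shape"]),
            pixel_spacing=float(d["pixel_spacing"]),
        )


def _pinhole_matrix(
    source: np.ndarray,
    R: np.ndarray,
    focal_mm: float,
    pixel_spacing: float,
    principal_point: tuple[float, float],
) -> np.ndarray:
    f_px = focal_mm / pixel_spacing
    K = np.array(
        [[f_px, 0.0, principal_point[0]], [0.0, f_px, principal_point[1]], [0.0, 0.0, 1.0]]
    )
    t = -R @ np.asarray(source, dtype=float)
    return K @ np.hstack([R, t[:, None]])


def make_biplane_geometry(
    image_shape: tuple[int, int] = (256, 256),
    pixel_spacing: float = 1.6,
    source_iso_mm: float = 750.0,
    source_detector_mm: float = 1050.0,
    principal_offset_a_px: tuple[float, float] = (0.0, 0.0),
    principal_offset_b_px: tuple[float, float] = (0.0, 0.0),
) -> ProjectionGeometry:
    """Construct an idealized orthogonal biplane C-arm geometry.

    Plane A views along world +z (an AP-like view, source at ``-z``), plane B
    along world +x (a lateral view, source at ``-x``); the world origin is
    the iso-center.  World axes: x left-right, y cranio-caudal, z
    anterior-posterior.  ``principal_offset_*_px`` shifts the detector
    principal point away from the image center, so the back-projected image
    centers triangulate to a point away from the iso-center (a deliberately
    poor initialization for capture-range experiments).
    """
    rows, cols = image_shape
    cu, cv = (cols - 1) / 2.0, (rows - 1) / 2.0
    pp_a = (cu + principal_offset_a_px[0], cv + principal_offset_a_px[1])
    pp_b = (cu + principal_offset_b_px[0], cv + principal_offset_b_px[1])

    R_a = np.eye(3)  # camera z = world z
    # camera z = world x, camera up = world y
    R_b = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    src_a = np.array([0.0, 0.0, -source_iso_mm])
    src_b = np.array([-source_iso_mm, 0.0, 0.0])
    P_A = _pinhole_matrix(src_a, R_a, source_detector_mm, pixel_spacing, pp_a)
    P_B = _pinhole_matrix(src_b, R_b, source_detector_mm, pixel_spacing, pp_b)
    return ProjectionGeometry(P_A=P_A, P_B=P_B, image_shape=image_shape, pixel_spacing=pixel_spacing)


# ---------------------------------------------------------------------------
# voxel splatting
# ---------------------------------------------------------------------------


def splat_footprint_px(P: np.ndarray, points: np.ndarray, spacing: float) -> int:
    """Conservative square splat width (px) covering a voxel's projection.

    Uses the largest magnification over the point cloud (closest depth) so a
    voxel never falls between pixels; minimum 1 px.
    """
    _, w = project_points(P, points)
    w = w[w > 0]
    if w.size == 0:
        return 1
    fu, fv = focal_lengths_px(P)
    ext = spacing * max(fu, fv) / float(w.min())
    return max(1, int(np.ceil(ext)))


def splat_accumulate(
    points: np.ndarray,
    P: np.ndarray,
    image_shape: tuple[int, int],
    spacing: float,
    footprint: int | None = None,
) -> np.ndarray:
    """Additively splat world points into an image (line-integral style).

    Each point deposits 1 over a ``footprint`` x ``footprint`` pixel block
    centered on its rounded projection; the result is the count image
    convolved with that block (zero padding outside the detector).  Points
    behind the source or projecting outside the detector are dropped.
    """
    rows, cols = image_shape
    acc = np.zeros((rows, cols), dtype=np.float64)
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return acc
    if footprint is None:
        footprint = splat_footprint_px(P, pts, spacing)
    uv, w = project_points(P, pts)
    ok = w > 0
    u = np.rint(uv[ok, 0]).astype(np.int64)
    v = np.rint(uv[ok, 1]).astype(np.int64)
    inb = (u >= -footprint) & (u < cols + footprint) & (v >= -footprint) & (v < rows + footprint)
    u, v = u[inb], v[inb]
    # clip to the grid after the in-range test so near-border footprints
    # still contribute their in-image part
    if footprint == 1:
        keep = (u >= 0) & (u < cols) & (v >= 0) & (v < rows)
        np.add.at(acc, (v[keep], u[keep]), 1.0)
        return acc
    pad = footprint
    big = np.zeros((rows + 2 * pad, cols + 2 * pad), dtype=np.float64)
    np.add.at(big, (v + pad, u + pad), 1.0)
    big = ndimage.uniform_filter(big, size=footprint, mode="constant", cval=0.0)
    big *= footprint**2
    # uniform_filter centers even windows half a pixel up-left; acceptable
    # for the conservative square footprint
    return big[pad : pad + rows, pad : pad + cols]


def render_shadow(
    model: AtriumModel,
    P: np.ndarray,
    T: RigidTransform,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Binary projected shadow ``S_T`` of the transformed model.

    A pixel is 1 iff at least one interior voxel of the model, transformed
    by ``T``, splats onto it.
    """
    pts = model.voxel_centers
    if pts.shape[0] == 0:
        return np.zeros(image_shape, dtype=bool)
    acc = splat_accumulate(T.apply(pts), P, image_shape, model.spacing)
    return acc > 0


# ---------------------------------------------------------------------------
# apparent-edge rendering
# ---------------------------------------------------------------------------


@njit(cache=True)
def _raster_opacity(tri_uv, opacity, rows, cols):  # pragma: no cover - numba
    """Composite triangles order-independently: out = 1 - prod(1 - o_k)."""
    trans = np.ones((rows, cols), dtype=np.float64)
    n_tri = tri_uv.shape[0]
    for k in range(n_tri):
        o = opacity[k]
        if o <= 0.0:
            continue
        x0, y0 = tri_uv[k, 0, 0], tri_uv[k, 0, 1]
        x1, y1 = tri_uv[k, 1, 0], tri_uv[k, 1, 1]
        x2, y2 = tri_uv[k, 2, 0], tri_uv[k, 2, 1]
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if area == 0.0:
            continue
        umin = int(np.floor(min(x0, min(x1, x2))))
        umax = int(np.ceil(max(x0, max(x1, x2))))
        vmin = int(np.floor(min(y0, min(y1, y2))))
        vmax = int(np.ceil(max(y0, max(y1, y2))))
        if umin < 0:
            umin = 0
        if vmin < 0:
            vmin = 0
        if umax > cols - 1:
            umax = cols - 1
        if vmax > rows - 1:
            vmax = rows - 1
        inv = 1.0 / area
        om = 1.0 - o
        for v in range(vmin, vmax + 1):
            for u in range(umin, umax + 1):
                w0 = ((x1 - u) * (y2 - v) - (x2 - u) * (y1 - v)) * inv
                w1 = ((x2 - u) * (y0 - v) - (x0 - u) * (y2 - v)) * inv
                w2 = 1.0 - w0 - w1
                if w0 >= 0.0 and w1 >= 0.0 and w2 >= 0.0:
                    trans[v, u] *= om
    return 1.0 - trans


def triangle_opacities(
    mesh: trimesh.Trimesh, P: np.ndarray, T: RigidTransform
) -> np.ndarray:
    """Per-triangle rendering opacity ``o = 1 - |d . n|``.

    ``d`` is the unit viewing direction from the X-ray source to the
    (transformed) triangle centroid, ``n`` the outward unit face normal:
    0 for faces parallel to the detector, 1 for faces seen edge-on.
    Degenerate (zero-area) faces get opacity 0.
    """
    P = normalize_projection_matrix(P)
    src = camera_center(P)
    verts = T.apply(mesh.vertices)
    centroids = verts[mesh.faces].mean(axis=1)
    d = centroids - src
    d /= np.linalg.norm(d, axis=1)[:, None]
    o = 1.0 - np.abs(np.einsum("ij,ij->i", d, mesh.face_normals))
    o[mesh.area_faces <= 1e-12] = 0.0
    return o


def render_apparent_edges(
    mesh: trimesh.Trimesh,
    P: np.ndarray,
    T: RigidTransform,
    image_shape: tuple[int, int],
    smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Apparent-edge image ``E_T`` of the transformed surface mesh.

    Every triangle is rasterized with opacity ``o = 1 - |d . n|`` where ``d``
    is the unit viewing direction from the X-ray source to the triangle
    centroid and ``n`` the outward unit normal: faces seen edge-on (n
    perpendicular to d) are opaque, faces parallel to the detector are
    transparent, so the image responds exactly where apparent contours —
    silhouette and internal folds — project.  Covering triangles composite
    order-independently as ``1 - prod(1 - o_k)``.  The result is smoothed
    with ``smooth_sigma`` (px) to match the scale of the fluoroscopic edge
    image it is correlated with.
    """
    P = normalize_projection_matrix(P)
    rows, cols = image_shape
    if mesh is None or len(mesh.faces) == 0:
        return np.zeros(image_shape, dtype=np.float64)
    verts = T.apply(mesh.vertices)

    good = mesh.area_faces > 1e-12
    n_degenerate = int((~good).sum())
    if n_degenerate:
        warn_once(
            "degenerate-triangles",
            f"skipped {n_degenerate} degenerate (zero-area) triangles during edge rendering",
        )
    faces = mesh.faces[good]
    opacity = triangle_opacities(mesh, P, T)[good]

    uv, w = project_points(P, verts)
    tri_uv = uv[faces]
    front = np.all(w[faces] > 0, axis=1) & np.all(np.isfinite(tri_uv.reshape(len(faces), -1)), axis=1)
    tri_uv = np.ascontiguousarray(tri_uv[front])
    opacity = np.ascontiguousarray(opacity[front])

    E = _raster_opacity(tri_uv, opacity, rows, cols)
    if smooth_sigma > 0:
        E = ndimage.gaussian_filter(E, smooth_sigma, mode="reflect")
    return E


# ---------------------------------------------------------------------------
# contrast-agent distribution estimate (CADE)
# ---------------------------------------------------------------------------


def compute_cade(
    model: AtriumModel,
    I_thr_A: np.ndarray,
    I_thr_B: np.ndarray,
    geometry: ProjectionGeometry,
    T: RigidTransform,
) -> CADEResult:
    """Binary reconstruction of contrasted chamber voxels and its projections.

    A voxel ``v`` is estimated as contrasted iff (a) the transformed voxel
    projects on a contrasted pixel in plane A, (b) likewise in plane B, and
    (c) ``v`` lies inside the chamber:

        C3D(v) = I_thr_A(P_A(T(v))) * I_thr_B(P_B(T(v))) * chi(v)

    with nearest-pixel lookup; voxels projecting outside either detector (or
    behind a source) count as uncontrasted.  ``C_A``/``C_B`` splat all
    C3D=1 voxels back into the planes, for consistency scoring against the
    thresholded fluoroscopic contrast.
    """
    I_thr_A = np.asarray(I_thr_A)
    I_thr_B = np.asarray(I_thr_B)
    if I_thr_A.shape != geometry.image_shape or I_thr_B.shape != geometry.image_shape:
        raise ValueError("threshold images must match the geometry's image shape")
    rows, cols = geometry.image_shape

    pts = T.apply(model.voxel_centers)
    inside = np.ones(pts.shape[0], dtype=bool)
    for P, I_thr in ((geometry.P_A, I_thr_A), (geometry.P_B, I_thr_B)):
        uv, w = project_points(P, pts)
        u = np.rint(uv[:, 0]).astype(np.int64)
        v = np.rint(uv[:, 1]).astype(np.int64)
        ok = (w > 0) & (u >= 0) & (u < cols) & (v >= 0) & (v < rows)
        hit = np.zeros(pts.shape[0], dtype=bool)
        hit[ok] = I_thr[v[ok], u[ok]] > 0
        inside &= hit

    C3D = np.zeros(model.volume.shape, dtype=bool)
    idx = model.voxel_indices[inside]
    C3D[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    contrasted = pts[inside]
    C_A = splat_accumulate(contrasted, geometry.P_A, geometry.image_shape, model.spacing) > 0
    C_B = splat_accumulate(contrasted, geometry.P_B, geometry.image_shape, model.spacing) > 0
    return CADEResult(C3D=C3D, C_A=C_A, C_B=C_B)
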