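"""Acquisition geometry and the elementary forward operations.

A light-field tomographic acquisition records, for each sub-aperture
("view") of the objective pupil, a handful of 1-D en-face projections of
that view's perspective image, taken at programmed orientations.  The
measurement is therefore a *sinogram partitioned over views*: every
projection angle appears at exactly one view, and the union of angles over
views spans the full half-turn.

Conventions used throughout the package
---------------------------------------
* Image arrays are indexed ``[row, col]``; ``x`` is the column (detector)
  axis, ``y`` the row axis.  The grid center sits at ``((N-1)/2, (N-1)/2)``.
* ``rotate_image(P, theta)`` rotates counter-clockwise in the
  (x right, y = row index increasing downward) frame: a point offset
  ``(+5, 0)`` from center maps to ``(0, +5)`` at ``theta = 90``.
* The en-face projection sums along ``y`` (column sums), so the detector
  coordinate of a point is the x-coordinate of its rotated position.
* With these conventions the projection-axis disparity of a sub-aperture
  shear ``(s*u, s*v)`` at rotation angle ``theta`` is
  ``s*u*cos(theta) - s*v*sin(theta)``; the field's usual shearing formula
  ``s*u*sin(theta) - s*v*cos(theta)`` (see :func:`shear_shift`) measures
  the same quantity with the orientation taken from the y axis, i.e. at
  the complementary angle ``90 - theta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class InvalidPlanError(ValueError):
    """Raised when an angle plan cannot be constructed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SystemGeometry:
    """Geometry of a view-partitioned tomographic acquisition.

    Parameters
    ----------
    image_size_N : int
        Pixels per image side (and detector length).
    view_apertures : (K, 2) array
        Normalized aperture coordinates ``(u_k, v_k)`` in [-1, 1]^2.
    angle_assignment : tuple of (view, angle) pairs
        Ordered plan rows; every angle in [0, 180) appears exactly once.
    pixel_pitch : float, optional
        Physical sampling at the object plane, micrometers per pixel.
    """

    image_size_N: int
    view_apertures: np.ndarray
    angle_assignment: tuple  # ((k, theta_deg), ...) in sinogram row order
    pixel_pitch: float = 0.9
    subaperture_diameter_D: float | None = None
    full_aperture_D0: float | None = None
    pupil_demag_r: float | None = None

    def __post_init__(self):
        ap = np.atleast_2d(np.asarray(self.view_apertures, dtype=float))
        object.__setattr__(self, "view_apertures", ap)
        if self.image_size_N < 2:
            raise InvalidPlanError("image size N must be >= 2")
        if self.num_views_K < 1:
            raise InvalidPlanError("need at least one view")
        ks = [k for k, _ in self.angle_assignment]
        if ks and (min(ks) < 0 or max(ks) >= self.num_views_K):
            raise InvalidPlanError("plan references an undefined view")
        thetas = [th for _, th in self.angle_assignment]
        if any(not (0.0 <= th < 180.0) for th in thetas):
            raise InvalidPlanError("angles must lie in [0, 180) degrees")
        if len(set(thetas)) != len(thetas):
            raise InvalidPlanError("each angle must be assigned to exactly one view")

    @property
    def num_views_K(self) -> int:
        return self.view_apertures.shape[0]

    @property
    def total_angles_Ntheta(self) -> int:
        return len(self.angle_assignment)

    @property
    def angles_per_view(self) -> list[int]:
        counts = [0] * self.num_views_K
        for k, _ in self.angle_assignment:
            counts[k] += 1
        return counts

    def rows(self):
        """Iterate plan rows as (row index, view k, angle deg)."""
        for i, (k, th) in enumerate(self.angle_assignment):
            yield i, k, th


@dataclass
class FeatureKernel:
    """Depth-indexed image feature kernel h(d): what all views share.

    ``values`` is the N x N nonnegative intensity grid (expected photons);
    ``depth_d`` its signed depth (um) relative to nominal focus.
    """

    values: np.ndarray
    depth_d: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature kernel must be a 2-D grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature kernel must be finite")
        if np.any(self.values < 0):
            raise ValueError("feature kernel must be nonnegative")


@dataclass
class PerspectiveImage:
    """Sub-aperture (single-view) image P_k."""

    values: np.ndarray
    view_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class Sinogram:
    """Stack of labeled 1-D en-face projections.

    ``rows`` has shape (n_rows, N); ``views`` and ``angles_deg`` label each
    row.  Row order follows the view-partitioned stacking of the plan.
    """

    rows: np.ndarray
    views: np.ndarray
    angles_deg: np.ndarray
    noise_sigma_meta: str | None = None

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=float)
        self.views = np.asarray(self.views, dtype=int)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.rows.ndim != 2:
            raise ValueError("sinogram rows must be 2-D (n_rows x N)")
        if len(self.views) != len(self.rows) or len(self.angles_deg) != len(self.rows):
            raise ValueError("row labels must match row count")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def detector_size(self) -> int:
        return self.rows.shape[1]

    def copy(self) -> "Sinogram":
        return Sinogram(self.rows.copy(), self.views.copy(), self.angles_deg.copy(),
                        self.noise_sigma_meta)


@dataclass
class TimeResolvedScene:
    """Voxel grid of expected photon counts with per-voxel time decay.

    ``voxels`` has axes (z, t, y, x) — or (z, t, lam, y, x) when a
    wavelength axis is present.  ``z_planes`` are depths in um,
    ``time_axis`` bin centers in ns with uniform spacing.
    """

    voxels: np.ndarray
    z_planes: np.ndarray
    time_axis: np.ndarray
    wavelength_axis: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.z_planes = np.asarray(self.z_planes, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        expected_ndim = 4 if self.wavelength_axis is None else 5
        if self.voxels.ndim != expected_ndim:
            raise ValueError(f"scene voxels must be {expected_ndim}-D")
        if np.any(self.voxels < 0):
            raise ValueError("scene must be nonnegative")
        for ax in (self.z_planes, self.time_axis):
            if len(ax) > 1 and np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")
        dt = np.diff(self.time_axis)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9):
            raise ValueError("time bins must be uniform")

    @property
    def bin_width_ns(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0])


# ---------------------------------------------------------------------------
# view plans and aperture lattices
# ---------------------------------------------------------------------------


def square_lattice_apertures(K: int, extent: float = 0.8) -> np.ndarray:
    """K aperture coordinates on a centered square lattice in the unit pupil.

    The smallest g x g grid with g^2 >= K is laid over
    [-extent, extent]^2 and the K points closest to the pupil center are
    kept (deterministic; ties broken by lattice order).
    """
    if K < 1:
        raise InvalidPlanError("K must be >= 1")
    if K == 1:
        return np.zeros((1, 2))
    g = int(np.ceil(np.sqrt(K)))
    coords = np.linspace(-extent, extent, g)
    uu, vv = np.meshgrid(coords, coords, indexing="xy")
    pts = np.column_stack([uu.ravel(), vv.ravel()])
    order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
    return pts[order[:K]]


def build_view_plan(
    K: int,
    Ntheta: int,
    scheme: str = "balanced",
    *,
    image_size_N: int | None = None,
    apertures: np.ndarray | None = None,
    permutation: np.ndarray | None = None,
    pixel_pitch: float = 0.9,
) -> SystemGeometry:
    """Partition ``Ntheta`` evenly spaced projection angles over ``K`` views.

    Angles are ``i * 180 / Ntheta`` for i = 0..Ntheta-1 (the prism spans a
    quarter turn; image rotation doubles it to the half-turn needed for
    tomography).  The ``balanced`` scheme deals contiguous blocks of the
    angle sequence to successive views with sizes differing by at most one
    (larger blocks first).  The ``custom`` scheme first reorders the angle
    sequence by a caller-supplied permutation — the hook for shaping the
    off-focus point response by shuffling orientations across views.
    """
    if K < 1:
        raise InvalidPlanError("K must be >= 1")
    if K > Ntheta:
        raise InvalidPlanError(f"cannot spread {Ntheta} angles over {K} views")
    angles = np.arange(Ntheta) * (180.0 / Ntheta)
    if scheme == "custom":
        if permutation is None:
            raise InvalidPlanError("custom scheme needs a permutation")
        perm = np.asarray(permutation, dtype=int)
        if sorted(perm.tolist()) != list(range(Ntheta)):
            raise InvalidPlanError("permutation must reorder range(Ntheta)")
        angles = angles[perm]
    elif scheme != "balanced":
        raise InvalidPlanError(f"unknown scheme {scheme!r}")

    base, extra = divmod(Ntheta, K)
    sizes = [base + (1 if k < extra else 0) for k in range(K)]
    assignment = []
    pos = 0
    for k, nk in enumerate(sizes):
        for th in angles[pos:pos + nk]:
            assignment.append((k, float(th)))
        pos += nk

    if apertures is None:
        apertures = square_lattice_apertures(K)
    N = image_size_N if image_size_N is not None else Ntheta  # non-compressive default
    return SystemGeometry(
        image_size_N=N,
        view_apertures=np.asarray(apertures, dtype=float),
        angle_assignment=tuple(assignment),
        pixel_pitch=pixel_pitch,
    )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def rotate_image(P: np.ndarray, theta_deg: float) -> np.ndarray:
    """Rotate an image by ``theta_deg`` about the grid center.

    Bilinear interpolation, zero padding outside the grid.  Rotation sense:
    counter-clockwise with the row index increasing downward, i.e. a point
    at offset (+5, 0) from center lands at (0, +5) for theta = 90.
    """
    P = np.asarray(P, dtype=float)
    th = np.deg2rad(theta_deg % 360.0)
    c, s = np.cos(th), np.sin(th)
    n_y, n_x = P.shape
    center = np.array([(n_y - 1) / 2.0, (n_x - 1) / 2.0])
    # output (y', x') pulls from input at the inverse rotation
    # forward map on (x, y): x' = x c - y s ; y' = x s + y c
    # inverse map: x = x' c + y' s ; y = -x' s + y' c  (row-major matrix below)
    mat = np.array([[c, -s], [s, c]])  # acts on (y, x) offsets: inverse mapping
    offset = center - mat @ center
    return ndimage.affine_transform(P, mat, offset=offset, order=1,
                                    mode="grid-constant", cval=0.0, prefilter=False)


def project_enface(P: np.ndarray) -> np.ndarray:
    """En-face projection along the y axis: column sums, length N."""
    P = np.asarray(P, dtype=float)
    return P.sum(axis=0)


def shear_shift(s: float, u_k: float, v_k: float, theta_deg: float) -> float:
    """Projection-axis shift of a sheared sub-aperture view.

    Returns ``s*u_k*sin(theta) - s*v_k*cos(theta)`` exactly — the standard
    form with the projection orientation measured from the y axis.  With
    this package's image-rotation convention the disparity of plan row
    ``(k, theta)`` is ``shear_shift(s, u_k, v_k, 90 - theta)``
    (see :func:`row_disparity`).
    """
    th = np.deg2rad(theta_deg)
    return s * u_k * np.sin(th) - s * v_k * np.cos(th)


def row_disparity(s: float, u_k: float, v_k: float, theta_deg: float) -> float:
    """Detector-axis disparity of shear (s*u, s*v) at rotation angle theta.

    Equal to ``shear_shift(s, u_k, v_k, 90 - theta_deg)``; this is the form
    consistent with :func:`rotate_image` / :func:`project_enface`.
    """
    th = np.deg2rad(theta_deg)
    return s * u_k * np.cos(th) - s * v_k * np.sin(th)


def shift_image(P: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Translate an image by (dx, dy) pixels, bilinear, zero-filled."""
    P = np.asarray(P, dtype=float)
    return ndimage.shift(P, (dy, dx), order=1, mode="constant", cval=0.0,
                         prefilter=False)


def render_perspective(h: FeatureKernel | np.ndarray, view: tuple[float, float],
                       s: float, view_index: int = 0) -> PerspectiveImage:
    """Render the sub-aperture view p_k(x, y) = h(x - s*u_k, y - s*v_k).

    The kernel is translated by (+s*u_k, +s*v_k); borders are zero-filled.
    """
    values = h.values if isinstance(h, FeatureKernel) else np.asarray(h, float)
    u_k, v_k = view
    return PerspectiveImage(shift_image(values, s * u_k, s * v_k), view_index)


def forward_project_row(img: np.ndarray, theta_deg: float) -> np.ndarray:
    """One sinogram row: rotate by theta then project en face."""
    return project_enface(rotate_image(img, theta_deg))


def forward_sinogram(scene, geom: SystemGeometry, shears=None,
                     operator=None) -> np.ndarray | Sinogram:
    """Apply the depth-dependent forward model F(d) to a scene.

    ``scene`` may be a single 2-D image (one plane), a list of
    :class:`FeatureKernel` / (image, s) planes superposed incoherently, or
    a :class:`TimeResolvedScene` (the operator is applied independently
    per time bin and wavelength, returning an array of shape
    (..., n_rows, N)).

    ``shears`` gives the shear parameter s per plane; for a
    :class:`TimeResolvedScene` it must match ``z_planes``.  The heavy
    lifting is done by a cached sparse operator (see
    :mod:`lifttomo.operators`); pass ``operator`` to reuse one.
    """
    from .operators import ForwardOperator  # local import to avoid cycle

    if isinstance(scene, TimeResolvedScene):
        if shears is None:
            raise ValueError("time-resolved scenes need per-plane shears")
        op = operator or ForwardOperator(geom, shears=shears)
        nz = scene.voxels.shape[0]
        lead = scene.voxels.shape[1:-2]  # (t,) or (t, lam)
        out = np.zeros(lead + (geom.total_angles_Ntheta, geom.image_size_N))
        flat = scene.voxels.reshape(nz, -1, *scene.voxels.shape[-2:])
        out_flat = out.reshape(-1, *out.shape[-2:])
        for j in range(flat.shape[1]):
            out_flat[j] = op.apply_planes(flat[:, j])
        return out

    if isinstance(scene, FeatureKernel):
        planes = [scene.values]
        svals = [0.0] if shears is None else list(np.atleast_1d(shears))
    elif isinstance(scene, np.ndarray) and scene.ndim == 2:
        planes = [scene]
        svals = [0.0] if shears is None else list(np.atleast_1d(shears))
    else:
        planes, svals = [], []
        for item in scene:
            if isinstance(item, FeatureKernel):
                planes.append(item.values)
            else:
                planes.append(np.asarray(item[0], float))
                svals.append(float(item[1]))
        if shears is not None:
            svals = list(np.atleast_1d(shears))
        if len(svals) != len(planes):
            raise ValueError("one shear per plane required")

    op = operator or ForwardOperator(geom, shears=svals)
    rows = op.apply_planes(np.stack(planes))
    return Sinogram(rows,
                    views=np.array([k for k, _ in geom.angle_assignment]),
                    angles_deg=np.array([th for _, th in geom.angle_assignment]))
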