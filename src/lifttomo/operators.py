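"""Sparse-matrix realization of the view-partitioned forward model.

Each sinogram row is the composition (en-face projection) @ (rotation) @
(sub-aperture shear) applied to a depth plane.  All three factors are
assembled as sparse matrices over the flattened N x N grid with bilinear
interpolation and zero padding, matching :func:`lifttomo.geometry.rotate_image`
and :func:`lifttomo.geometry.shift_image` to machine precision.  Assembling
the operator explicitly buys an *exact* adjoint (the transpose), which the
iterative solvers rely on.

The per-plane operator F_s (n_rows x N^2) is cached per shear value, so
time-resolved scenes reuse one factorization across all time bins.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .geometry import SystemGeometry


def _bilinear_matrix(N: int, src_y: np.ndarray, src_x: np.ndarray) -> sparse.csr_matrix:
    """Sparse (N^2 x N^2) gather matrix: out[p] = bilinear(in, src[p]).

    ``src_y``/``src_x`` give, for each output pixel (flattened row-major),
    the input coordinate it pulls from.  Out-of-grid samples contribute
    zero (zero padding).
    """
    y0 = np.floor(src_y).astype(np.int64)
    x0 = np.floor(src_x).astype(np.int64)
    fy = src_y - y0
    fx = src_x - x0
    rows_out = np.arange(N * N, dtype=np.int64)

    data, rows, cols = [], [], []
    for dy, dx, w in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        yy = y0 + dy
        xx = x0 + dx
        ok = (yy >= 0) & (yy < N) & (xx >= 0) & (xx < N) & (w > 0)
        data.append(w[ok])
        rows.append(rows_out[ok])
        cols.append(yy[ok] * N + xx[ok])
    mat = sparse.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N * N, N * N),
    )
    return mat.tocsr()


def rotation_matrix(N: int, theta_deg: float) -> sparse.csr_matrix:
    """Sparse bilinear rotation about the grid center ((N-1)/2, (N-1)/2)."""
    th = np.deg2rad(theta_deg % 360.0)
    c, s = np.cos(th), np.sin(th)
    ctr = (N - 1) / 2.0
    yo, xo = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    dy = yo.ravel() - ctr
    dx = xo.ravel() - ctr
    # inverse map (pull): rotate output offsets by -theta
    src_x = c * dx + s * dy + ctr
    src_y = -s * dx + c * dy + ctr
    return _bilinear_matrix(N, src_y, src_x)


def shift_matrix(N: int, dx: float, dy: float) -> sparse.csr_matrix:
    """Sparse bilinear translation by (dx, dy) pixels, zero-filled."""
    yo, xo = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    src_y = yo.ravel() - dy
    src_x = xo.ravel() - dx
    return _bilinear_matrix(N, src_y, src_x)


def projection_matrix(N: int) -> sparse.csr_matrix:
    """Sparse (N x N^2) column-sum (en-face projection along y)."""
    cols = np.arange(N * N, dtype=np.int64)
    rows = cols % N  # detector index = x = column index
    data = np.ones(N * N)
    return sparse.coo_matrix((data, (rows, cols)), shape=(N, N * N)).tocsr()


class ForwardOperator:
    """Cached sparse forward model F(d) for one geometry.

    Parameters
    ----------
    geom : SystemGeometry
    shears : float or sequence of float
        Shear parameter s for each scene plane (s = 0 is the nominal
        focal plane).  ``matrix(s)`` returns the (n_rows x N^2) sparse
        operator for one plane; ``apply_planes`` superposes planes
        incoherently.
    """

    def __init__(self, geom: SystemGeometry, shears=0.0):
        self.geom = geom
        self.N = geom.image_size_N
        self.shears = [float(s) for s in np.atleast_1d(shears)]
        self._proj = projection_matrix(self.N)
        # per-angle projection-of-rotation blocks, shared across shears
        self._angle_block: dict[float, sparse.csr_matrix] = {}
        for _, _, th in geom.rows():
            if th not in self._angle_block:
                self._angle_block[th] = self._proj @ rotation_matrix(self.N, th)
        self._mats: dict[float, sparse.csr_matrix] = {}
        for s in self.shears:
            self._mats[s] = self._assemble(s)

    def _assemble(self, s: float) -> sparse.csr_matrix:
        blocks = []
        for _, k, th in self.geom.rows():
            A = self._angle_block[th]
            if s != 0.0:
                u, v = self.geom.view_apertures[k]
                A = A @ shift_matrix(self.N, s * u, s * v)
            blocks.append(A)
        return sparse.vstack(blocks, format="csr")

    def matrix(self, s: float = 0.0) -> sparse.csr_matrix:
        s = float(s)
        if s not in self._mats:
            self._mats[s] = self._assemble(s)
        return self._mats[s]

    @property
    def n_rows(self) -> int:
        return self.geom.total_angles_Ntheta

    # -- linear-operator interface on a single plane -----------------------
    def apply(self, img: np.ndarray, s: float = 0.0) -> np.ndarray:
        """F_s @ img -> sinogram rows (n_rows, N)."""
        out = self.matrix(s) @ np.asarray(img, float).ravel()
        return out.reshape(self.n_rows, self.N)

    def adjoint(self, rows: np.ndarray, s: float = 0.0) -> np.ndarray:
        """Exact transpose: F_s^T @ rows -> image (N, N)."""
        out = self.matrix(s).T @ np.asarray(rows, float).ravel()
        return out.reshape(self.N, self.N)

    def apply_planes(self, planes: np.ndarray) -> np.ndarray:
        """Superpose F_{s_j} @ plane_j over all planes (incoherent sum)."""
        planes = np.asarray(planes, float)
        if planes.ndim == 2:
            planes = planes[None]
        if planes.shape[0] != len(self.shears):
            raise ValueError("number of planes must match configured shears")
        out = np.zeros((self.n_rows, self.N))
        for plane, s in zip(planes, self.shears):
            if plane.shape != (self.N, self.N):
                raise ValueError("plane size does not match geometry")
            out += self.apply(plane, s)
        return out

    def lipschitz(self, s: float = 0.0, n_iter: int = 20, safety: float = 1.05,
                  seed: int = 0) -> float:
        """Largest eigenvalue of F^T F by power iteration, with safety margin."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(self.N * self.N)
        x /= np.linalg.norm(x)
        A = self.matrix(s)
        lam = 1.0
        for _ in range(n_iter):
            y = A.T @ (A @ x)
            lam = float(np.linalg.norm(y))
            if lam == 0:
                return safety
            x = y / lam
        return safety * lam
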