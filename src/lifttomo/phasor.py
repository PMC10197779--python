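"""Temporal and spectral phasor transforms, clustering, and unmixing.

The phasor of a decay I(t) is its normalized first Fourier harmonic,

    G = sum I(t) cos(w t) / sum I(t),    S = sum I(t) sin(w t) / sum I(t),

with w = 2 pi / T and T the histogram span (one laser repetition period).
Mono-exponential decays fall on the universal semicircle
(G - 1/2)^2 + S^2 = 1/4; intensity-weighted mixtures land on the chord
between their pure components, which is what makes phasor-space unmixing
linear.  Spectral phasors use the same construction with the phase
spanning one full turn over the wavelength range.

Clustering is a full-covariance Gaussian mixture on (G, S); the
responsibilities are the per-pixel cluster probabilities.  The
cluster-to-component assignment is user-declared (the panel composition is
known a priori when samples are labeled), never inferred.

For a four-component panel resolved by two lifetime clusters (a, b) and
three spectral clusters (a, b, c) with the assignment
  lifetime a -> component 3;  lifetime b -> components 1, 2, 4;
  spectral a -> component 1;  spectral b -> components 2, 3;  spectral c -> component 4,
the amplitude fractions satisfy the linear system

    pL_a = f3,  pL_b = f1 + f2 + f4,  pT_a = f1,  pT_b = f2 + f3,  pT_c = f4,

with sum(f) = 1, inverted exactly by
    f1 = pT_a,  f3 = pL_a,  f2 = pT_b - pL_a,  f4 = pT_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture


class UndefinedPhasorError(ValueError):
    pass


class ClusteringError(ValueError):
    pass


@dataclass
class PhasorCloud:
    """Per-pixel phasor coordinates in one domain."""

    G: np.ndarray
    S: np.ndarray
    domain: str = "temporal"  # or "spectral"
    harmonic_omega: float | None = None  # rad/ns, temporal domain

    def __post_init__(self):
        self.G = np.atleast_1d(np.asarray(self.G, dtype=float))
        self.S = np.atleast_1d(np.asarray(self.S, dtype=float))
        if self.G.shape != self.S.shape:
            raise ValueError("G and S must have equal shape")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.G, self.S])


@dataclass
class FractionMaps:
    """Per-pixel cluster probabilities and unmixed amplitude fractions."""

    p_lifetime: np.ndarray  # (pixels, 2)
    p_spectral: np.ndarray  # (pixels, 3)
    fractions: np.ndarray   # (pixels, 4), rows on the simplex
    residual: np.ndarray    # consistency residual of the overdetermined system


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def phasor_transform(signal: np.ndarray, axis: np.ndarray,
                     domain: str = "temporal",
                     omega: float | None = None) -> tuple[float, float]:
    """First-harmonic phasor (G, S) of a nonnegative 1-D profile.

    Temporal domain: ``axis`` is the time axis (ns, bin centers) and
    ``omega`` the angular frequency in rad/ns; by default
    ``2 pi / span`` where the span is one full histogram period
    (n_bins * bin width).  Spectral domain: ``axis`` is the wavelength
    axis and the phase spans 2 pi over its range.
    """
    signal = np.asarray(signal, dtype=float)
    axis = np.asarray(axis, dtype=float)
    total = signal.sum()
    if total <= 0:
        raise UndefinedPhasorError("zero total intensity: phasor undefined")
    if domain == "temporal":
        if omega is None:
            dt = axis[1] - axis[0]
            omega = 2.0 * np.pi / (len(axis) * dt)
        phase = omega * (axis - axis[0])
    elif domain == "spectral":
        lam0, lam1 = axis[0], axis[-1]
        phase = 2.0 * np.pi * (axis - lam0) / (lam1 - lam0)
    else:
        raise ValueError(f"unknown phasor domain {domain!r}")
    G = float(np.sum(signal * np.cos(phase)) / total)
    S = float(np.sum(signal * np.sin(phase)) / total)
    return G, S


def phasor_cloud(signals: np.ndarray, axis: np.ndarray,
                 domain: str = "temporal",
                 omega: float | None = None) -> PhasorCloud:
    """Phasor transform of every row of a (pixels, bins) array.

    Zero-intensity pixels get NaN coordinates rather than raising.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    G = np.full(signals.shape[0], np.nan)
    S = np.full(signals.shape[0], np.nan)
    for p in range(signals.shape[0]):
        try:
            G[p], S[p] = phasor_transform(signals[p], axis, domain, omega)
        except UndefinedPhasorError:
            pass
    if domain == "temporal" and omega is None:
        dt = axis[1] - axis[0]
        omega = 2.0 * np.pi / (len(axis) * dt)
    return PhasorCloud(G, S, domain=domain,
                       harmonic_omega=omega if domain == "temporal" else None)


def monoexp_phasor(tau_ns: float, omega: float) -> tuple[float, float]:
    """Closed-form phasor of a mono-exponential decay at frequency omega."""
    wt = omega * tau_ns
    return 1.0 / (1.0 + wt * wt), wt / (1.0 + wt * wt)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_probabilities(cloud: PhasorCloud, n_clusters: int,
                          seed: int = 0, n_init: int = 10) -> np.ndarray:
    """Gaussian-mixture responsibilities of each pixel over (G, S).

    Full-covariance mixture, ``n_init`` restarts, deterministic given
    ``seed``.  Rows sum to one.  NaN pixels (undefined phasors) get NaN
    probability rows.
    """
    if n_clusters < 1:
        raise ClusteringError("n_clusters must be >= 1")
    pts = cloud.points
    valid = np.all(np.isfinite(pts), axis=1)
    X = pts[valid]
    if n_clusters == 1:
        out = np.full((pts.shape[0], 1), np.nan)
        out[valid] = 1.0
        return out
    if np.unique(X, axis=0).shape[0] < n_clusters:
        raise ClusteringError("fewer distinct phasor points than clusters")
    gmm = GaussianMixture(n_components=n_clusters, covariance_type="full",
                          n_init=n_init, random_state=seed)
    gmm.fit(X)
    probs = gmm.predict_proba(X)
    out = np.full((pts.shape[0], n_clusters), np.nan)
    out[valid] = probs
    return out


# ---------------------------------------------------------------------------
# amplitude-fraction unmixing
# ---------------------------------------------------------------------------


def forward_fractions(f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map amplitude fractions (f1..f4) to cluster probabilities.

    Returns ``(p_lifetime (.., 2), p_spectral (.., 3))`` under the standard
    four-component assignment documented in the module docstring.
    """
    f = np.asarray(f, dtype=float)
    f1, f2, f3, f4 = np.moveaxis(f, -1, 0)
    pL = np.stack([f3, f1 + f2 + f4], axis=-1)
    pT = np.stack([f1, f2 + f3, f4], axis=-1)
    return pL, pT


def unmix_fractions(p_lifetime: np.ndarray, p_spectral: np.ndarray,
                    tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Invert the cluster-probability system for amplitude fractions f1..f4.

    ``p_lifetime`` has 2 columns (a, b); ``p_spectral`` 3 columns (a, b, c);
    each family must sum to 1 per pixel within ``tol``.  The exact solution
    is f1 = pT_a, f3 = pL_a, f2 = pT_b - pL_a, f4 = pT_c; results are
    clipped to [0, 1] and renormalized.  For normalized families the fifth
    constraint pL_b = f1 + f2 + f4 is linearly dependent and always
    satisfied, so the reported residual is instead the per-pixel mass
    removed by clipping (zero exactly when the probabilities are consistent
    with a point on the simplex).
    """
    pL = np.atleast_2d(np.asarray(p_lifetime, dtype=float))
    pT = np.atleast_2d(np.asarray(p_spectral, dtype=float))
    if pL.shape[-1] != 2 or pT.shape[-1] != 3:
        raise ValueError("expected 2 lifetime and 3 spectral probabilities")
    if pL.shape[0] != pT.shape[0]:
        raise ValueError("pixel counts differ between probability families")
    for fam, name in ((pL, "lifetime"), (pT, "spectral")):
        sums = fam.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > max(tol, 1e-12)):
            raise ValueError(f"{name} probabilities must sum to 1 per pixel")
    f1 = pT[:, 0]
    f3 = pL[:, 0]
    f2 = pT[:, 1] - pL[:, 0]
    f4 = pT[:, 2]
    f = np.stack([f1, f2, f3, f4], axis=-1)
    clipped = np.clip(f, 0.0, 1.0)
    residual = np.abs(f - clipped).sum(axis=-1)
    norm = clipped.sum(axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    return clipped / norm, residual
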