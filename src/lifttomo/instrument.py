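"""Closed-form system calculators and 1-D instrument calibrations.

Everything here is desk arithmetic about the acquisition system itself:
how many scanning steps the view-partitioned scheme saves over point- and
line-scanning, the light throughput of the direct and spectral detection
arms, FWHM deconvolution of convolved widths, sub-pixel localization of
projection centers from a pinhole acquisition, and the linear
wavelength-to-pixel fit of the spectral axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .geometry import Sinogram


class InfeasibleWidthError(ValueError):
    pass


class MissingSignalError(ValueError):
    pass


@dataclass
class ThroughputParams:
    """Optical/detector parameters entering the throughput formulas.

    Lengths may be in any single consistent unit (they only enter as
    ratios).  ``pixel_pitch_p`` and ``full_aperture_D0`` must share a unit.
    """

    pixel_pitch_p: float | None = None
    fill_factor_kappa: float | None = None
    full_aperture_D0: float | None = None
    pupil_demag_r: float | None = None
    grating_efficiency_chi: float | None = None
    quantum_efficiency_eta: float | None = None
    num_views_K: int | None = None

    def __post_init__(self):
        for name in ("fill_factor_kappa", "grating_efficiency_chi",
                     "quantum_efficiency_eta"):
            val = getattr(self, name)
            if val is not None and not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("pixel_pitch_p", "full_aperture_D0", "pupil_demag_r"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CenterCalibration:
    """Sub-pixel projection-center positions yp0 indexed by plan row."""

    views: np.ndarray
    angles_deg: np.ndarray
    centers_px: np.ndarray

    def __post_init__(self):
        self.centers_px = np.asarray(self.centers_px, dtype=float)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def compression_and_reduction(N: int, Ntheta: int, K: int):
    """(compression ratio, point-scan factor, line-scan factor).

    CR = N / Ntheta (exact rational, returned as Fraction); the scanning
    reduction over a point scanner is N * K and over a line scanner K
    (depth sampling equals the number of views in light-field imaging).
    """
    if N <= 0 or Ntheta <= 0 or K <= 0:
        raise ValueError("N, Ntheta and K must be positive integers")
    cr = Fraction(int(N), int(Ntheta))
    return cr, int(N) * int(K), int(K)


def throughput(params: ThroughputParams, mode: str) -> float:
    """Light throughput zeta of the direct (``flim``) or spectral
    (``sflim``) detection arm.

    flim:  p * kappa / (D0 * r) — the sub-aperture/pupil-demagnification
    factors cancel, leaving the pixel aperture over the demagnified pupil.
    sflim: chi * eta / K — one view out of K through the grating and
    gated camera; the pupil demagnification r plays no role here.
    """
    if mode == "flim":
        needed = (params.pixel_pitch_p, params.fill_factor_kappa,
                  params.full_aperture_D0, params.pupil_demag_r)
        if any(v is None for v in needed):
            raise ValueError("flim throughput needs p, kappa, D0, r")
        p, kappa, D0, r = needed
        return p * kappa / (D0 * r)
    if mode == "sflim":
        needed = (params.grating_efficiency_chi,
                  params.quantum_efficiency_eta, params.num_views_K)
        if any(v is None for v in needed):
            raise ValueError("sflim throughput needs chi, eta, K")
        chi, eta, K = needed
        return chi * eta / K
    raise ValueError(f"unknown throughput mode {mode!r}")


def deconvolved_width(total_w: float, known_ws) -> tuple[float, int]:
    """Deconvolve a measured width into its unknown component.

    For discrete functions the width of an m-fold convolution obeys
    w(f1 * ... * fm) = sum w(fi) - (m - 1); given the total and m-1 known
    component widths the unknown is total - sum(known) + (m - 1).  Returns
    the exact real value and its nearest-integer pixel count (measured
    widths are conventionally rounded to whole pixels).
    """
    known_ws = list(known_ws)
    m = len(known_ws) + 1
    exact = float(total_w) - float(sum(known_ws)) + (m - 1)
    if exact < 0:
        raise InfeasibleWidthError(
            f"deconvolved width {exact} is negative: components wider than total")
    return exact, int(round(exact))


# ---------------------------------------------------------------------------
# calibrations
# ---------------------------------------------------------------------------


def calibrate_projection_center(pinhole_sinogram: Sinogram,
                                window_px: int = 5,
                                threshold_frac: float = 0.05) -> CenterCalibration:
    """Sub-pixel projection center of each row of a pinhole acquisition.

    Each row must carry a single detectable peak; the center is the
    intensity-weighted centroid over a +-``window_px`` window around the
    maximum.  A row whose peak falls below ``threshold_frac`` of the
    sinogram's global maximum raises :class:`MissingSignalError` naming it.
    """
    rows = pinhole_sinogram.rows
    global_max = rows.max()
    if global_max <= 0:
        raise MissingSignalError("sinogram carries no signal at all")
    centers = np.empty(rows.shape[0])
    for i, row in enumerate(rows):
        if row.max() < threshold_frac * global_max:
            raise MissingSignalError(
                f"row {i} (view {pinhole_sinogram.views[i]}, "
                f"angle {pinhole_sinogram.angles_deg[i]:.1f} deg) has no peak")
        pk = int(np.argmax(row))
        lo = max(0, pk - window_px)
        hi = min(len(row), pk + window_px + 1)
        seg = row[lo:hi]
        centers[i] = float(np.sum(np.arange(lo, hi) * seg) / seg.sum())
    return CenterCalibration(views=pinhole_sinogram.views.copy(),
                             angles_deg=pinhole_sinogram.angles_deg.copy(),
                             centers_px=centers)


def fit_spectral_axis(pairs) -> tuple[float, float, float]:
    """Least-squares line wavelength = slope * pixel + intercept.

    ``pairs`` is a list of (wavelength nm, pixel).  Returns
    (slope nm/pixel, intercept nm, residual RMS nm); needs at least two
    distinct wavelengths.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least 2 (wavelength, pixel) pairs")
    lam, px = pairs[:, 0], pairs[:, 1]
    if np.unique(lam).size < 2:
        raise ValueError("need at least 2 distinct wavelengths")
    coef = np.polyfit(px, lam, 1)
    resid = lam - np.polyval(coef, px)
    return float(coef[0]), float(coef[1]), float(np.sqrt(np.mean(resid ** 2)))
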