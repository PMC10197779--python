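"""TCSPC histogram post-processing and mono-exponential lifetime fitting.

A time-correlated single-photon-counting (TCSPC) detector array delivers a
per-pixel histogram of photon arrival times at a fixed bin width (50 ps by
default here).  Raw histograms carry three instrument artifacts that are
corrected before fitting:

1. *background* — dark counts and stray light, measured separately and
   subtracted (clipped at zero, counts cannot go negative);
2. *delay skew* — each pixel's zero-reference bin differs because the
   on-chip delay lines are not matched; histograms are circularly shifted
   so the reference bin maps to index 0 (the histogram is periodic in the
   laser repetition period, so a circular shift is the faithful correction);
3. *bin-width nonlinearity* — the delay chains make some bins effectively
   wider than others; a per-pixel multiplicative correction is derived from
   non-time-correlated uniform illumination by histogram equalization, and
   normalized to preserve each pixel's total count.

Lifetimes are then estimated per pixel by weighted log-linear least squares
on the post-peak tail of the decay (optionally refined by a nonlinear fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal


class EmptyMaskError(ValueError):
    pass


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class TCSPCHistogramSet:
    """Per-pixel photon-count histograms, shape (pixels, bins)."""

    counts: np.ndarray
    bin_width_ns: float = 0.05
    time_zero: int = 0

    def __post_init__(self):
        self.counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if self.bin_width_ns <= 0:
            raise ValueError("bin width must be positive")

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def time_axis_ns(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns


@dataclass
class CorrectionTables:
    """Per-pixel background, delay, and nonlinearity corrections."""

    background: np.ndarray | None = None
    zero_ref_bins: np.ndarray | None = None
    nonlin_matrix: np.ndarray | None = None


@dataclass
class LifetimeMap:
    """Per-pixel mono-exponential fit results."""

    tau_ns: np.ndarray
    amplitude: np.ndarray
    fit_quality: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if np.any(self.tau_ns[self.mask] <= 0):
            raise ValueError("fitted lifetimes must be positive where valid")


# ---------------------------------------------------------------------------
# corrections
# ---------------------------------------------------------------------------


def preprocess_histograms(h: TCSPCHistogramSet,
                          c: CorrectionTables) -> TCSPCHistogramSet:
    """Background subtraction, delay alignment, nonlinearity correction."""
    counts = h.counts.copy()
    if c.background is not None:
        bg = np.atleast_2d(np.asarray(c.background, dtype=float))
        if bg.shape[1] != h.n_bins:
            raise ValueError("background bin count mismatch")
        counts = np.clip(counts - bg, 0.0, None)
    if c.zero_ref_bins is not None:
        zref = np.atleast_1d(np.asarray(c.zero_ref_bins, dtype=int))
        for p in range(counts.shape[0]):
            z = zref[p] if zref.size > 1 else zref[0]
            counts[p] = np.roll(counts[p], -int(z))
    if c.nonlin_matrix is not None:
        w = np.atleast_2d(np.asarray(c.nonlin_matrix, dtype=float))
        if w.shape[-1] != h.n_bins:
            raise ValueError("nonlinearity matrix bin count mismatch")
        counts = counts * w
    return TCSPCHistogramSet(counts, h.bin_width_ns, time_zero=0)


def build_nonlinearity_correction(uniform_runs) -> np.ndarray:
    """Per-pixel bin weights flattening uniform-illumination histograms.

    ``uniform_runs`` is a list of :class:`TCSPCHistogramSet` acquired under
    non-time-correlated uniform illumination (the instrument protocol
    averages ~100 runs).  The averaged histogram of an ideal detector is
    flat; the returned weights rescale each bin so it becomes flat, while
    preserving each pixel's total count.  Pixels with an all-zero average
    are flagged with identity weights.
    """
    if len(uniform_runs) < 1:
        raise ValueError("need at least one uniform-illumination run")
    avg = np.mean([np.atleast_2d(r.counts) for r in uniform_runs], axis=0)
    n_pix, n_bins = avg.shape
    weights = np.ones_like(avg)
    for p in range(n_pix):
        total = avg[p].sum()
        if total <= 0:
            continue  # dead pixel: identity weights
        target = total / n_bins
        nz = avg[p] > 0
        weights[p, nz] = target / avg[p, nz]
        # renormalize so the correction preserves this pixel's total
        corrected_total = float(np.sum(weights[p] * avg[p]))
        weights[p] *= total / corrected_total
    return weights


# ---------------------------------------------------------------------------
# mono-exponential fitting
# ---------------------------------------------------------------------------


def fit_monoexponential(decay: np.ndarray, time_axis_ns: np.ndarray,
                        min_counts: float = 5.0,
                        refine: bool = False) -> tuple[float, float, float, bool]:
    """Fit A * exp(-t / tau) to the post-peak tail of a decay.

    The fit window runs from the histogram peak bin to the last bin with at
    least ``min_counts`` counts.  The default estimator is weighted linear
    least squares on log counts (weights = counts); it carries a small
    positive bias on Poisson data (about +1.5% at 1e4 photons), so
    ``refine=True`` follows it with a Poisson maximum-likelihood
    refinement, which is unbiased to sampling precision.  Returns
    ``(tau_ns, amplitude, quality, valid)`` where quality is the RMS
    residual of the fit relative to the peak and ``valid`` is False when
    the data cannot support a fit.
    """
    decay = np.asarray(decay, dtype=float)
    t = np.asarray(time_axis_ns, dtype=float)
    invalid = (np.nan, np.nan, np.nan, False)
    if decay.size != t.size or decay.size < 5 or not np.any(decay > 0):
        return invalid
    peak = int(np.argmax(decay))
    above = np.nonzero(decay >= min_counts)[0]
    if above.size == 0:
        return invalid
    last = int(above[-1])
    sel = slice(peak, last + 1)
    y = decay[sel]
    tt = t[sel]
    pos = y > 0
    if pos.sum() < 5:
        return invalid
    y, tt = y[pos], tt[pos]
    # weighted LSQ on log(y): weight w_i = y_i
    w = y
    X = np.column_stack([np.ones_like(tt), tt])
    ly = np.log(y)
    WX = X * w[:, None]
    try:
        beta = np.linalg.solve(X.T @ WX, WX.T @ ly)
    except np.linalg.LinAlgError:
        return invalid
    if beta[1] >= 0:  # non-decaying
        return invalid
    tau = -1.0 / beta[1]
    amp = float(np.exp(beta[0]))
    if refine:
        # Poisson ML over the full post-peak tail; zero-count bins stay in
        # (they carry information -- dropping them biases tau upward)
        t_all = t[peak:]
        y_all = decay[peak:]

        def nll(p):
            a, ta = p
            if a <= 0 or ta <= 0:
                return 1e300
            lam = a * np.exp(-t_all / ta)
            return float(np.sum(lam - y_all * np.log(lam + 1e-300)))

        res = optimize.minimize(nll, [amp, tau], method="Nelder-Mead",
                                options=dict(xatol=1e-6, fatol=1e-9))
        if res.x[1] > 0:
            amp, tau = float(res.x[0]), float(res.x[1])
    model = amp * np.exp(-tt / tau)
    quality = float(np.sqrt(np.mean((y - model) ** 2)) / max(y.max(), 1e-30))
    return float(tau), amp, quality, True


def fit_lifetime_map(histograms: np.ndarray, time_axis_ns: np.ndarray,
                     mask: np.ndarray | None = None,
                     min_counts: float = 5.0,
                     min_counts_frac: float | None = None,
                     refine: bool = False) -> LifetimeMap:
    """Mono-exponential fit per pixel of a (pixels, bins) histogram array.

    ``min_counts_frac``, when given, overrides ``min_counts`` with a
    per-pixel threshold at that fraction of the pixel's own peak — the
    right windowing for reconstructed (non-count) decays whose noise floor
    scales with the signal.
    """
    histograms = np.atleast_2d(np.asarray(histograms, dtype=float))
    n = histograms.shape[0]
    tau = np.full(n, np.nan)
    amp = np.full(n, np.nan)
    qual = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    candidates = np.arange(n) if mask is None else np.nonzero(mask)[0]
    for p in candidates:
        mc = (min_counts if min_counts_frac is None
              else min_counts_frac * histograms[p].max())
        tau[p], amp[p], qual[p], ok[p] = fit_monoexponential(
            histograms[p], time_axis_ns, min_counts=mc, refine=refine)
    return LifetimeMap(tau_ns=tau, amplitude=amp, fit_quality=qual, mask=ok)


# ---------------------------------------------------------------------------
# lifetime histograms and peak detection
# ---------------------------------------------------------------------------


def lifetime_histogram(lmap: LifetimeMap, bins=50,
                       range_ns: tuple[float, float] | None = None):
    """Histogram the valid per-pixel lifetimes.

    Returns ``(counts, bin_centers)``.  Raises :class:`EmptyMaskError` when
    no pixel has a valid fit.
    """
    vals = lmap.tau_ns[lmap.mask]
    if vals.size == 0:
        raise EmptyMaskError("no valid lifetime fits to histogram")
    counts, edges = np.histogram(vals, bins=bins, range=range_ns)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def histogram_peaks(counts: np.ndarray, centers: np.ndarray,
                    min_prominence_frac: float = 0.05) -> np.ndarray:
    """Mode locations of a lifetime histogram (ns), sorted ascending."""
    counts = np.asarray(counts, dtype=float)
    if counts.max() <= 0:
        return np.array([])
    idx, _ = signal.find_peaks(counts,
                               prominence=min_prominence_frac * counts.max())
    return np.sort(centers[idx])
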