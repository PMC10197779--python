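# Methods

## Forward model and conventions

The measurement model is ray-optical: a scene plane at depth `d` appears
in pupil view `k = (u_k, v_k)` translated by the disparity `(s·u_k,
s·v_k)`, where the shear parameter `s` depends linearly on depth; the
rotated view is then collapsed to a 1-D en-face projection.  No
diffraction, aberration, or PSF blur is modeled — depth enters only
through the shear, and fluorescence from different planes adds
incoherently (intensities sum).

Conventions (fixed once, used everywhere):

- arrays are `[row, col] = [y, x]`; the grid center is `((N−1)/2, (N−1)/2)`;
- `rotate_image(P, θ)` is counter-clockwise in the x-right/row-down frame
  (an impulse at offset `(+5, 0)` goes to `(0, +5)` at 90°), bilinear,
  zero-padded;
- the en-face projection sums along y, so the detector coordinate of a
  point is the x-coordinate of its rotated position;
- projection orientations are `θ_i = i·180°/N_θ`, each assigned to exactly
  one view (contiguous blocks in the balanced plan; a caller-supplied
  permutation reorders the sequence for point-response shaping).

With these conventions the detector-axis disparity of plan row `(k, θ)` at
shear `s` is `s·u_k·cosθ − s·v_k·sinθ` (`row_disparity`).  The classical
shearing formula `s·u_k·sinθ − s·v_k·cosθ` (`shear_shift`) measures the
same quantity with the orientation taken from the y axis; the two coincide
at the complementary angle.  Both are exposed; the refocusing path uses
the rotation-angle form so that refocusing exactly undoes the forward
disparity.

The forward operator is assembled as an explicit sparse matrix
(shear, rotation and projection factors composed per plan row).  This
costs memory (~4·N²·N_θ nonzeros) but makes the adjoint the exact matrix
transpose, which the iterative solvers and their convergence checks
depend on; a matrix-free composition of library resampling routines would
only have an approximate adjoint.  Bilinear resampling on a rotated
lattice conserves intensity to interpolation accuracy (~1e-3 relative;
exact at lattice-aligned angles) — the operative accuracy limit of the
forward model.

## Reconstruction

**FBP.** Rows are ramp-filtered (discrete Ramachandran–Lakshminarayanan
kernel, Hann apodization by default for noise control) and back-projected
through the exact adjoint, scaled by `π/(2N_θ)`.  The pooled rows across
all views are treated as one parallel-beam dataset, which is exactly what
the view-partitioned model implies once refocused to a common shear.

**FISTA.** Monotone FISTA (an accepted iterate never raises the
objective) on `‖f − F(d)h‖² + μ·φ(h)`, step `1/L` with `L` from 20 power
iterations and a 5% safety factor, nonnegativity projection each iterate
(photon counts), and the proximal step delegated to a denoiser:
Chambolle-type total variation with 10 inner iterations by default, or
any callable `(image, strength) → image` (e.g. a BM3D plugin).  The
reported objective uses the isotropic TV seminorm.  Non-convergence
within `max_iters` returns the best iterate with a warning flag.

μ defaults: 0.02 for noiseless compressive data; for shot-noise-limited
data the weight is matched to the noise level as `μ = 50·√(128/M)` (the
scaled measurement noise is ∝ 1/√M; the anchor was fixed with the
photon-budget protocol itself, whose quality/limit numbers these defaults
produce).  At `N_θ = N` the operator is numerically rank-deficient, so the
unregularized problem has a null-space ambiguity; the μ=0 equivalence
check against least squares is therefore run on an overdetermined
geometry (`N_θ = 2N`, smallest singular value ≈ 0.02).

**Depth.** Refocusing shifts each row by minus its disparity with
sub-pixel linear interpolation (a round trip is therefore a mild
smoothing, not an exact identity — tested to 2% on smooth rows).  Focus is
scored by the sum of the modified Laplacian in a 5×5 window; the
all-in-focus composite takes each pixel's best depth, ties going to the
smallest depth index.  The shear↔depth map is fitted as a straight line by
least squares and carries residual diagnostics and a validity range.

## Lifetime and phasor analysis

TCSPC histograms (50 ps bins by default) are corrected in the instrument's
order: background subtraction clipped at zero; delay alignment by circular
shift (the histogram is periodic in the laser period); bin-nonlinearity
correction by per-pixel weights that flatten averaged uniform-illumination
histograms, renormalized to preserve totals (idempotent on corrected
data; dead pixels get identity weights).

Lifetimes are fitted per pixel on the window from the histogram peak to
the last bin above a threshold (absolute counts for raw histograms; a
fraction of the pixel's own peak for reconstructed decays, whose noise
floor scales with signal — fitting into that floor biases τ upward).  The
default estimator is weighted log-linear least squares; it carries a small
positive bias on Poisson data (≈ +1.5% at 10⁴ photons), so an optional
Poisson maximum-likelihood refinement over the full post-peak tail
(zero-count bins included — they are informative) is provided and is the
right choice when unbiasedness matters.

Phasors are first-harmonic Fourier coordinates normalized by total
intensity, with ω = 2π/(histogram span) in the temporal domain — the span
standing in for the laser repetition period — and the phase spanning 2π
over the wavelength range in the spectral domain.  Mono-exponential
decays then lie on the universal semicircle `(G−½)² + S² = ¼` and
mixtures at intensity-weighted convex combinations, which is what makes
the downstream unmixing linear.  Cluster probabilities come from a
full-covariance Gaussian mixture (10 restarts, seeded); the mapping of
clusters to fluorophores is declared by the user, never inferred.  For
the four-component panel (2 lifetime × 3 spectral clusters) the fraction
system inverts exactly as `f1 = pT_a, f3 = pL_a, f2 = pT_b − pL_a,
f4 = pT_c`; since the remaining equation is linearly dependent for
normalized families, the reported consistency residual is the mass
removed when clipping negative fractions.

## Synthetic data

The generators emulate the bench studies at desk scale: bead scenes
(disks placed by rejection sampling with one-diameter minimum separation,
lifetimes cycling through 1.5/3.4/4.0 ns, intensities normalized to peak
1), the standard Shepp-Logan phantom as the complex object, and a
programmatic three-bar target as the sparse one (sparsity is the operative
property, not the chart artwork).  Shot noise scales the clean signal so
its brightest element has expected count `M` and draws independent
Poisson counts, seeded.  They do not emulate detector afterpulsing or
crosstalk, optical blur, autofluorescence background, or sample motion —
so passing tests certify the reconstruction/analysis chain under the
stated noise model, not instrument performance on tissue.

Study problem sizes were chosen to exercise the protocols on a single
CPU: photon-budget sweep at N = 128 with 5 seeds per photon level,
compression sweep at N = 180 (the reference image dimension, giving
integer N_θ at CR 9), and the mixed-bead pipeline at N = 64 with 200 time
bins and peak count M = 100 per sinogram element (≈ 2·10³ photons per
bright pixel after integration).  The per-bin reconstruction uses FBP —
200 regularized solves would add nothing at this photon budget — and the
lifetime histogram uses 50 ps-wide bins over 0.75–6 ns.

## Known limitations

- The forward model is 2-D-per-plane; there is no joint multi-depth
  deconvolution, only plane-by-plane refocusing.
- FBP amplitude calibration is exact only in the same discretization
  family as the forward model; absolute intensities of reconstructions
  are meaningful up to that scale.
- The GMM clustering assumes roughly Gaussian phasor clusters; heavily
  overlapping panels need the user-declared assignment to stay valid.
- The learned-enhancement stage of the original instrument pipeline is
  out of scope by design; reconstructions here are classical.
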