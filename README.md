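# lifttomo

Desk-scale simulation and analysis toolkit for **light-field tomographic
fluorescence lifetime imaging**: a computational-imaging scheme in which a
microscope records only 1-D en-face projections of pupil sub-aperture
("view") images instead of full 2-D frames, and volumetric lifetime maps
are recovered tomographically.

It is aimed at computational-imaging and FLIM researchers who want to
prototype acquisition geometries, reconstruction settings, and
lifetime/spectral unmixing chains without the instrument.

## The model

A perspective image `P_k` at view `k` yields, at projection orientation
`θ`, the measurement

```
f_kθ = T R_θ P_k
```

where `R_θ` rotates the image (the dove prism's action) and `T` sums it
along the y axis (the cylindrical lens).  Only a subset `n_k` of the `N_θ`
orientations is acquired at each view; stacking all rows gives the
view-partitioned sinogram `f`.  Because all views see the same scene up to
a depth-dependent disparity, each `P_k = B_k(d) h(d)` is a sheared copy of
a common feature kernel, so

```
f = F(d) h(d) + σ,       F(d) = [A_1 B_1(d); … ; A_K B_K(d)]
```

and although each view is angularly sparse, `h(d)` is observed on the
*union* of all orientations.  The package implements:

- the forward operator `F(d)` as an exact sparse matrix (bilinear shear →
  rotation → column sum), with its adjoint;
- numerical refocusing (per-row shear `s·u_k sinθ − s·v_k cosθ`), filtered
  back-projection, and FISTA solving
  `argmin ‖f − F(d)h‖² + μ‖φ(h)‖₁` with a TV (or pluggable) denoiser;
- depth-from-focus sweeps, all-in-focus composites, and the linear
  shear↔depth calibration;
- TCSPC histogram corrections (background, delay, bin-nonlinearity),
  mono-exponential lifetime fitting, temporal/spectral phasors
  `G = Σ I cos(ωt)/Σ I`, `S = Σ I sin(ωt)/Σ I`, Gaussian-mixture cluster
  probabilities, and four-component amplitude-fraction unmixing;
- synthetic phantoms (beads with decay signatures, Shepp-Logan, sparse bar
  targets), Poisson photon-budget noise, and PSNR/SSIM studies of
  compression ratio `CR = N/N_θ` and photon budget `M`.

## Worked example

`examples/forward_and_reconstruct.py` forward-projects a Shepp-Logan
phantom through 64 orientations spread over 5 views and inverts the
sinogram two ways:

```
plan: 64 angles over 5 views (angles per view: [13, 13, 13, 13, 12])
sinogram: 64 rows x 64 detector pixels
FBP       PSNR =  23.1 dB   SSIM = 0.808
FISTA+TV  PSNR =  46.0 dB   SSIM = 0.995
```

FBP leaves streak artifacts at this angular sampling; the regularized
iterative solver removes them.  The other examples cover refocusing and
extended depth of field (`refocus_and_edof.py`, recovering bead depths of
−4/+4 µm from one acquisition), TCSPC corrections and lifetime fitting
(`lifetime_fitting.py`, resolving 1.5/3.4/4.0 ns bead populations),
phasor unmixing (`phasor_unmixing.py`), and the system-level sweeps
(`system_studies.py`).

A thin CLI mirrors the main entry points:

```sh
lifttomo phantom --kind shepp_logan --n 64 --out scene.tif
lifttomo forward --image scene.tif --k 5 --out sino.h5
lifttomo reconstruct --sinogram sino.h5 --method fista --out recon.tif
lifttomo metrics --n 180 --ntheta 20 --k 15
```

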