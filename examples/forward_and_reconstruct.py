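"""Forward-project a phantom through a view-partitioned plan and invert it.

Builds a Shepp-Logan phantom, distributes 64 projection orientations over
5 pupil views, synthesizes the sinogram, and reconstructs it twice: by
filtered back-projection and by FISTA with total-variation regularization.
Prints PSNR/SSIM of both reconstructions against the phantom — the
iterative solver should win clearly on noiseless data.
"""

import warnings

import lifttomo as lt

warnings.filterwarnings("ignore", message="FISTA did not reach")

N = 64
phantom = lt.shepp_logan(N)
geom = lt.build_view_plan(K=5, Ntheta=N, image_size_N=N)
print(f"plan: {geom.total_angles_Ntheta} angles over {geom.num_views_K} views "
      f"(angles per view: {geom.angles_per_view})")

sino = lt.forward_sinogram(phantom, geom)
print(f"sinogram: {sino.n_rows} rows x {sino.detector_size} detector pixels")

fbp = lt.fbp_reconstruct(sino, geom)
fista = lt.fista_reconstruct(sino, geom,
                             cfg=lt.ReconConfig(mu=0.02, max_iters=100)).image

for name, img in (("FBP", fbp), ("FISTA+TV", fista)):
    psnr, ssim = lt.image_metrics(img, phantom)
    print(f"{name:9s} PSNR = {psnr:5.1f} dB   SSIM = {ssim:.3f}")
print("Higher PSNR/SSIM = closer to the true phantom; FISTA suppresses the "
      "streak artifacts FBP leaves at this angular sampling.")
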