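"""File formats, run configuration, and the reproducible pipeline runner.

HDF5 is the container for multi-axis data (sinograms, time-resolved
scenes, TCSPC histogram sets); TIFF for 2-D images and depth stacks so
results drop straight into microscopy viewers; CSV for tables.  Round
trips are bit-exact for arrays and exact for metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import Sinogram, TimeResolvedScene


class FormatError(ValueError):
    pass


def _require_suffix(path: Path, suffixes: tuple[str, ...], kind: str):
    if path.suffix.lower() not in suffixes:
        raise FormatError(
            f"{kind} expects a {'/'.join(suffixes)} file, got {path.suffix!r}")


# ---------------------------------------------------------------------------
# sinograms
# ---------------------------------------------------------------------------


def save_sinogram(f: Sinogram, path) -> None:
    path = Path(path)
    _require_suffix(path, (".h5", ".hdf5"), "sinogram")
    with h5py.File(path, "w") as h5:
        h5.create_dataset("rows", data=f.rows)
        h5.create_dataset("angles", data=f.angles_deg)
        h5.create_dataset("views", data=f.views)
        if f.noise_sigma_meta is not None:
            h5.attrs["noise_sigma_meta"] = f.noise_sigma_meta


def load_sinogram(path) -> Sinogram:
    path = Path(path)
    _require_suffix(path, (".h5", ".hdf5"), "sinogram")
    try:
        with h5py.File(path, "r") as h5:
            return Sinogram(rows=h5["rows"][...], angles_deg=h5["angles"][...],
                            views=h5["views"][...],
                            noise_sigma_meta=h5.attrs.get("noise_sigma_meta"))
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read sinogram HDF5 at {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


def save_scene(scene: TimeResolvedScene, path) -> None:
    path = Path(path)
    _require_suffix(path, (".h5", ".hdf5"), "scene")
    with h5py.File(path, "w") as h5:
        d = h5.create_dataset("scene", data=scene.voxels)
        d.attrs["axes"] = "ztyx" if scene.wavelength_axis is None else "ztlyx"
        h5.create_dataset("z_planes", data=scene.z_planes)
        h5.create_dataset("time_axis", data=scene.time_axis)
        if scene.wavelength_axis is not None:
            h5.create_dataset("wavelength_axis", data=scene.wavelength_axis)


def load_scene(path) -> TimeResolvedScene:
    path = Path(path)
    _require_suffix(path, (".h5", ".hdf5"), "scene")
    try:
        with h5py.File(path, "r") as h5:
            wl = h5["wavelength_axis"][...] if "wavelength_axis" in h5 else None
            return TimeResolvedScene(voxels=h5["scene"][...],
                                     z_planes=h5["z_planes"][...],
                                     time_axis=h5["time_axis"][...],
                                     wavelength_axis=wl)
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read scene HDF5 at {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# TCSPC histograms
# ---------------------------------------------------------------------------


def save_histograms(counts: np.ndarray, bin_width_ns: float, path) -> None:
    path = Path(path)
    _require_suffix(path, (".h5", ".hdf5"), "tcspc histograms")
    with h5py.File(path, "w") as h5:
        d = h5.create_dataset("tcspc", data=np.asarray(counts, dtype=np.uint32))
        d.attrs["bin_width_ns"] = bin_width_ns


def load_histograms(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    if path.suffix.lower() == ".csv":  # single-pixel fixtures
        return np.atleast_2d(np.loadtxt(path, delimiter=",")), 0.05
    _require_suffix(path, (".h5", ".hdf5"), "tcspc histograms")
    try:
        with h5py.File(path, "r") as h5:
            d = h5["tcspc"]
            return d[...].astype(float), float(d.attrs["bin_width_ns"])
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read histograms at {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------


def save_image_tiff(img: np.ndarray, path, depths_um=None) -> None:
    """2-D image or stack as 32-bit float TIFF with optional depth metadata."""
    path = Path(path)
    _require_suffix(path, (".tif", ".tiff"), "image")
    arr = np.asarray(img, dtype=np.float32)
    meta = None
    if depths_um is not None:
        meta = {"depths_um": [float(d) for d in np.atleast_1d(depths_um)]}
    tifffile.imwrite(path, arr, metadata=meta, photometric="minisblack")


def load_image_tiff(path) -> np.ndarray:
    path = Path(path)
    _require_suffix(path, (".tif", ".tiff"), "image")
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# pipeline runner
# ---------------------------------------------------------------------------

_REQUIRED_BLOCKS = ("geometry",)
_KNOWN_BLOCKS = {"geometry", "reconstruction", "noise", "analysis", "paths"}


def validate_config(config: dict) -> dict:
    """Schema check for a pipeline run configuration (unknown keys rejected)."""
    unknown = set(config) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown config blocks: {sorted(unknown)}")
    for block in _REQUIRED_BLOCKS:
        if block not in config:
            raise ValueError(f"config missing required block {block!r}")
    geo = config["geometry"]
    for key in ("N", "K", "Ntheta"):
        if key not in geo:
            raise ValueError(f"geometry block missing {key!r}")
    return config


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Simulate -> forward -> noise -> reconstruct -> lifetime demo run.

    Writes scene.h5, sinogram.h5, recon_*.tif, lifetime.tif and report.csv
    under ``out_dir`` plus a manifest.json recording seeds and per-stage
    checksums; identical config and seed give identical checksums.  The
    per-stage RNG streams are derived from the global seed with a counter
    so stages can be rerun independently.
    """
    from .geometry import build_view_plan, forward_sinogram
    from .lifetime import fit_lifetime_map
    from .operators import ForwardOperator
    from .recon import ReconConfig, fbp_reconstruct, fista_reconstruct
    from .simulate import (apply_shot_noise, bead_scene_time_resolved,
                           make_beads3d)

    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "config": config, "stages": {}}

    geo = config["geometry"]
    N, K, ntheta = int(geo["N"]), int(geo["K"]), int(geo["Ntheta"])
    geom = build_view_plan(K, ntheta, image_size_N=N)
    noise = config.get("noise", {})
    recon_cfg_block = config.get("reconstruction", {})
    n_bins = int(config.get("analysis", {}).get("n_bins", 120))

    # stage 1: scene
    scene2d = make_beads3d(N, n_beads=int(geo.get("n_beads", max(3, N // 12))),
                           seed=seed * 7919 + 1)
    trs = bead_scene_time_resolved(scene2d, n_bins=n_bins)
    save_scene(trs, out / "scene.h5")
    manifest["stages"]["scene"] = _checksum(trs.voxels)

    # stage 2: forward + noise
    op = ForwardOperator(geom, shears=[0.0] * len(trs.z_planes))
    sino_t = forward_sinogram(trs, geom, shears=[0.0] * len(trs.z_planes),
                              operator=op)
    M = float(noise.get("M", 0) or 0)
    if M > 0:
        counts, scale = apply_shot_noise(sino_t, M, seed=seed * 7919 + 2)
        sino_t = counts / scale
    summed = sino_t.sum(axis=0)
    sino = Sinogram(summed,
                    views=np.array([k for k, _ in geom.angle_assignment]),
                    angles_deg=np.array([t for _, t in geom.angle_assignment]))
    save_sinogram(sino, out / "sinogram.h5")
    manifest["stages"]["sinogram"] = _checksum(sino.rows)

    # stage 3: reconstruction of the time-integrated image
    method = recon_cfg_block.get("method", "fbp")
    if method == "fista":
        cfg = ReconConfig(mu=float(recon_cfg_block.get("mu", 0.02)),
                          max_iters=int(recon_cfg_block.get("iters", 60)))
        recon = fista_reconstruct(sino, geom, cfg=cfg, operator=op).image
    else:
        recon = fbp_reconstruct(sino, geom, operator=op)
    save_image_tiff(recon, out / f"recon_{method}.tif")
    manifest["stages"]["recon"] = _checksum(recon)

    # stage 4: per-bin reconstruction + lifetime fit on bright pixels
    imgs_t = np.stack([fbp_reconstruct(
        Sinogram(sino_t[b], sino.views, sino.angles_deg), geom, operator=op)
        for b in range(sino_t.shape[0])])
    mask = recon > 0.3 * recon.max()
    hist_px = imgs_t.reshape(imgs_t.shape[0], -1).T[mask.ravel()]
    lmap = fit_lifetime_map(np.clip(hist_px, 0, None), trs.time_axis,
                            min_counts=1e-3 * max(hist_px.max(), 1e-30))
    tau_img = np.zeros(N * N, dtype=np.float32)
    tau_img[np.nonzero(mask.ravel())[0][lmap.mask]] = lmap.tau_ns[lmap.mask]
    save_image_tiff(tau_img.reshape(N, N), out / "lifetime.tif")
    manifest["stages"]["lifetime"] = _checksum(tau_img)

    import pandas as pd
    pd.DataFrame({
        "stage": list(manifest["stages"]),
        "checksum": list(manifest["stages"].values()),
    }).to_csv(out / "report.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
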