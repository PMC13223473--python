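"""Synthetic CT-like patch/mask generator.

Emulates the structure of preprocessed nodule patches: fixed-size
(16, 96, 96) volumes at anisotropic spacing in which positive (nodule)
voxels are a small fraction of the total and most nodule diameters are
small.  Each patch contains a low-intensity parenchyma texture, a few
bright tubular "vessels", Gaussian noise and (usually) one nodule — an
ellipsoid whose radius is perturbed by a low-order angular harmonic to
imitate lobulation, rendered brighter than its surroundings.

Defaults draw nodule diameters from a log-normal law (median 6 mm,
sigma_log 0.45) truncated to [3, 30] mm, which concentrates well over 80%
of nodules at or below 10 mm and keeps the positive-voxel fraction of a
default dataset under 1% — the class-imbalance regime the segmentation
loss is designed for.

Everything is driven by a single seed: the same (config, seed) pair
reproduces every byte of a generated dataset.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_io import PATCH_SHAPE, CTVolume, NoduleAnnotation, PatchPair


@dataclass
class NoduleSpec:
    """Parametric description of one synthetic nodule.

    ``center`` is in (z, y, x) voxel coordinates (fractional allowed);
    ``lobulation_amplitude`` scales the angular radius perturbation;
    ``contrast`` is the intensity step over the local background in the
    normalized-image scale; ``spacing`` is the (z, y, x) mm/voxel grid the
    nodule is voxelized on.
    """

    center: tuple[float, float, float]
    diameter_mm: float
    lobulation_amplitude: float = 0.2
    contrast: float = 0.6
    spacing: tuple[float, float, float] = (2.0, 0.7, 0.7)
    harmonic_coeffs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be positive")
        if not 0.0 <= self.lobulation_amplitude <= 0.5:
            raise ValueError("lobulation amplitude must be in [0, 0.5]")


@dataclass
class PhantomConfig:
    n_patches: int = 100
    patch_shape: tuple[int, int, int] = PATCH_SHAPE
    spacing: tuple[float, float, float] = (2.0, 0.7, 0.7)   # (z, y, x) mm
    diameter_median_mm: float = 6.0
    diameter_sigma_log: float = 0.45
    diameter_range_mm: tuple[float, float] = (3.0, 30.0)
    lobulation_amplitude: float = 0.2
    contrast: float = 0.6
    fraction_empty: float = 0.2
    noise_sigma: float = 0.03
    vessel_density: float = 3.0      # expected vessel segments per patch
    background_level: float = 0.1
    seed: int = 0


def sample_nodule_spec(cfg: PhantomConfig, rng: np.random.Generator) -> NoduleSpec:
    """Draw one nodule: truncated log-normal diameter, centre uniform within
    the patch interior (margin = nodule radius plus one voxel per axis)."""
    lo, hi = cfg.diameter_range_mm
    mu = math.log(cfg.diameter_median_mm)
    while True:   # rejection sampling against the truncation window
        d = float(np.exp(rng.normal(mu, cfg.diameter_sigma_log)))
        if lo <= d <= hi:
            break
    r_mm = d / 2.0
    center = []
    for size, sp in zip(cfg.patch_shape, cfg.spacing):
        margin = r_mm / sp + 1.0
        lo_c, hi_c = margin, size - 1 - margin
        if lo_c >= hi_c:   # nodule close to the patch extent on this axis
            center.append((size - 1) / 2.0)
        else:
            center.append(float(rng.uniform(lo_c, hi_c)))
    coeffs = rng.normal(0.0, 1.0, size=5)
    norm = np.linalg.norm(coeffs)
    coeffs = coeffs / norm if norm > 0 else coeffs
    return NoduleSpec(tuple(center), d, cfg.lobulation_amplitude, cfg.contrast,
                      cfg.spacing, tuple(float(c) for c in coeffs))


def _radius_perturbation(spec: NoduleSpec, ux, uy, uz):
    """Low-order angular modulation of the radius (quadrupole-like terms),
    bounded by the lobulation amplitude."""
    c = spec.harmonic_coeffs
    basis = (3.0 * uz * uz - 1.0, ux * ux - uy * uy, ux * uy, ux * uz, uy * uz)
    f = sum(ci * bi for ci, bi in zip(c, basis))
    # each |basis term| <= 2 and |c| = 1, so |f| <= ~3; squash into [-1, 1]
    return spec.lobulation_amplitude * np.tanh(f)


def _nodule_coverage(spec: NoduleSpec, shape, supersample: int = 3) -> np.ndarray:
    """Per-voxel inside-fraction of the perturbed ellipsoid, estimated by
    regular subvoxel sampling (``supersample`` points per axis)."""
    r0 = spec.diameter_mm / 2.0
    sp = np.asarray(spec.spacing)
    cz, cy, cx = spec.center
    # bounding box in voxels, generous for the lobulation
    ext = r0 * (1 + spec.lobulation_amplitude) / sp + 1.5
    lo = np.maximum(np.floor([cz - ext[0], cy - ext[1], cx - ext[2]]).astype(int), 0)
    hi = np.minimum(np.ceil([cz + ext[0], cy + ext[1], cx + ext[2]]).astype(int) + 1,
                    shape)
    cov = np.zeros(shape, dtype=np.float32)
    if np.any(lo >= hi):
        return cov
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    zz = np.arange(lo[0], hi[0])
    yy = np.arange(lo[1], hi[1])
    xx = np.arange(lo[2], hi[2])
    acc = np.zeros((len(zz), len(yy), len(xx)), dtype=np.float32)
    for oz in offs:
        for oy in offs:
            for ox in offs:
                dz = (zz + oz - cz)[:, None, None] * sp[0]
                dy = (yy + oy - cy)[None, :, None] * sp[1]
                dx = (xx + ox - cx)[None, None, :] * sp[2]
                rho = np.sqrt(dz * dz + dy * dy + dx * dx)
                with np.errstate(invalid="ignore", divide="ignore"):
                    ux = np.where(rho > 0, dx / rho, 0.0)
                    uy = np.where(rho > 0, dy / rho, 0.0)
                    uz = np.where(rho > 0, dz / rho, 1.0)
                r = r0 * (1.0 + _radius_perturbation(spec, ux, uy, uz))
                acc += (rho <= r)
    cov[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = acc / supersample ** 3
    return cov


def analytic_nodule_volume_mm3(spec: NoduleSpec, n_theta: int = 200,
                               n_phi: int = 200) -> float:
    """Volume of the perturbed ellipsoid by solid-angle quadrature of
    r(u)^3 / 3 over the unit sphere."""
    theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2.0 * math.pi / n_phi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    ux = np.sin(T) * np.cos(P)
    uy = np.sin(T) * np.sin(P)
    uz = np.cos(T)
    r0 = spec.diameter_mm / 2.0
    r = r0 * (1.0 + _radius_perturbation(spec, ux, uy, uz))
    dodd = np.sin(T) * (math.pi / n_theta) * (2.0 * math.pi / n_phi)
    return float(np.sum(r ** 3 / 3.0 * dodd))


def _render_background(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Parenchyma texture plus bright vessel tubes plus white noise."""
    shape = cfg.patch_shape
    sp = np.asarray(cfg.spacing)
    texture = rng.normal(0.0, 1.0, size=shape)
    texture = ndimage.gaussian_filter(texture, sigma=(1.0, 3.0, 3.0))
    std = texture.std()
    if std > 0:
        texture *= 0.05 / std
    img = cfg.background_level + texture

    n_vessels = rng.poisson(cfg.vessel_density)
    if n_vessels > 0:
        grid = np.stack(np.meshgrid(
            np.arange(shape[0]) * sp[0],
            np.arange(shape[1]) * sp[1],
            np.arange(shape[2]) * sp[2], indexing="ij"), axis=-1)
        extent = np.asarray(shape) * sp
        for _ in range(n_vessels):
            a = rng.uniform(0, extent, size=3)
            b = rng.uniform(0, extent, size=3)
            radius = rng.uniform(0.7, 2.0)
            ab = b - a
            denom = float(ab @ ab)
            if denom < 1e-9:
                continue
            t = np.clip(((grid - a) @ ab) / denom, 0.0, 1.0)
            closest = a + t[..., None] * ab
            dist = np.linalg.norm(grid - closest, axis=-1)
            img += 0.5 * np.clip(1.0 - dist / radius, 0.0, 1.0)

    img += rng.normal(0.0, cfg.noise_sigma, size=shape)
    return img.astype(np.float32)


def render_phantom(spec: NoduleSpec | None, cfg: PhantomConfig,
                   rng: np.random.Generator):
    """Render one patch.

    Returns ``(PatchPair, annotation_row)``; the row is a dict in the
    annotations-CSV dialect (seriesuid, coordX/Y/Z in mm, diameter_mm) and
    is ``None`` for an empty (nodule-free) patch.
    """
    img = _render_background(cfg, rng)
    if spec is None:
        return PatchPair(img, np.zeros(cfg.patch_shape, dtype=np.uint8)), None

    shape = np.asarray(cfg.patch_shape)
    sp = np.asarray(spec.spacing)
    r_vox = (spec.diameter_mm / 2.0) / sp
    center = np.asarray(spec.center, dtype=float)
    lo_ok = r_vox
    hi_ok = shape - 1 - r_vox
    clipped = np.clip(center, np.minimum(lo_ok, (shape - 1) / 2.0),
                      np.maximum(hi_ok, (shape - 1) / 2.0))
    if not np.allclose(clipped, center):
        warnings.warn(f"nodule at {tuple(center)} overflows the patch; re-centred")
        center = clipped
        spec = NoduleSpec(tuple(center), spec.diameter_mm,
                          spec.lobulation_amplitude, spec.contrast,
                          spec.spacing, spec.harmonic_coeffs)

    cov = _nodule_coverage(spec, cfg.patch_shape)
    mask = (cov >= 0.5).astype(np.uint8)
    img = img + spec.contrast * cov          # partial-volume edges
    cz, cy, cx = spec.center
    row = {
        "seriesuid": "",
        "coordX": float(cx * sp[2]),
        "coordY": float(cy * sp[1]),
        "coordZ": float(cz * sp[0]),
        "diameter_mm": float(spec.diameter_mm),
    }
    pair = PatchPair(img.astype(np.float32), mask,
                     center_world=(row["coordX"], row["coordY"], row["coordZ"]))
    return pair, row


def generate_patches(cfg: PhantomConfig, n: int | None = None):
    """Yield ``(PatchPair, annotation_row_or_None)`` deterministically."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patches if n is None else n
    for i in range(n):
        empty = rng.random() < cfg.fraction_empty
        spec = None if empty else sample_nodule_spec(cfg, rng)
        pair, row = render_phantom(spec, cfg, rng)
        pair.series_id = f"phantom-{cfg.seed}-{i:04d}"
        if row is not None:
            row["seriesuid"] = pair.series_id
        yield pair, row


def generate_dataset(cfg: PhantomConfig, outdir: str) -> pd.DataFrame:
    """Write ``n_patches`` pairs plus a manifest CSV, an annotations CSV and
    a stats JSON; returns the manifest frame.

    Patches are stored as .npz archives (keys ``image``, ``mask``); manifest
    columns are (series_id, subset, patch_path, mask_path, diameter_mm).
    Subset tags cycle 0-9 so the standard subset split applies directly.
    """
    os.makedirs(os.path.join(outdir, "patches"), exist_ok=True)
    manifest_rows = []
    ann_rows = []
    pos = 0
    total = 0
    for i, (pair, row) in enumerate(generate_patches(cfg)):
        rel = os.path.join("patches", f"{pair.series_id}.npz")
        np.savez_compressed(os.path.join(outdir, rel),
                            image=pair.image, mask=pair.mask)
        manifest_rows.append({
            "series_id": pair.series_id,
            "subset": i % 10,
            "patch_path": rel,
            "mask_path": rel,
            "diameter_mm": row["diameter_mm"] if row else 0.0,
        })
        if row is not None:
            ann_rows.append(row)
        pos += int(pair.mask.sum())
        total += pair.mask.size
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    pd.DataFrame(ann_rows, columns=["seriesuid", "coordX", "coordY", "coordZ",
                                    "diameter_mm"]
                 ).to_csv(os.path.join(outdir, "annotations.csv"), index=False)
    stats = {
        "n_patches": cfg.n_patches,
        "positive_voxel_fraction": pos / total if total else 0.0,
        "n_nodules": len(ann_rows),
    }
    with open(os.path.join(outdir, "stats.json"), "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
    return manifest


def load_patch(outdir: str, rel_path: str) -> PatchPair:
    with np.load(os.path.join(outdir, rel_path)) as z:
        return PatchPair(z["image"], z["mask"])


def synthetic_thorax(diameter_mm: float = 12.0, shape=(24, 64, 64),
                     spacing_xyz=(1.0, 1.0, 2.0), seed: int = 0):
    """A raw-HU test scene: an air-filled lung ellipsoid inside soft tissue
    with one solid nodule, plus its lung mask and annotation.

    Returns ``(CTVolume, lung_mask, NoduleAnnotation)``; intended for
    exercising the preprocessing pipeline end to end.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    vol = np.full(shape, 40.0, dtype=np.float32)          # soft tissue HU
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    cz, cy, cx = (nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2
    lung = (((zz - cz) / (0.42 * nz)) ** 2 + ((yy - cy) / (0.4 * ny)) ** 2
            + ((xx - cx) / (0.4 * nx)) ** 2) <= 1.0
    vol[lung] = -850.0 + rng.normal(0.0, 15.0, size=int(lung.sum()))
    sp_zyx = np.asarray(spacing_xyz)[::-1]
    r = diameter_mm / 2.0
    dist = np.sqrt(((zz - cz) * sp_zyx[0]) ** 2 + ((yy - cy) * sp_zyx[1]) ** 2
                   + ((xx - cx) * sp_zyx[2]) ** 2)
    vol[dist <= r] = 30.0                                  # solid nodule HU
    ct = CTVolume(vol, origin=(0.0, 0.0, 0.0),
                  spacing=tuple(float(s) for s in spacing_xyz),
                  series_id=f"thorax-{seed}")
    ann = NoduleAnnotation(ct.series_id,
                           (cx * spacing_xyz[0], cy * spacing_xyz[1],
                            cz * spacing_xyz[2]),
                           diameter_mm)
    return ct, lung.astype(np.uint8), ann
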