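"""CT volume I/O and the preprocessing pipeline.

Volumes are MetaImage (.mhd/.raw) files read through SimpleITK into a
:class:`CTVolume` with voxels in (z, y, x) array order and world metadata
(origin, spacing) in (x, y, z) millimetres, matching the annotation CSV
convention (seriesuid, coordX, coordY, coordZ, diameter_mm).

Preprocessing follows the standard nodule-segmentation recipe: multiply by
the binary lung mask, clip to a Hounsfield window and min-max scale to
[0, 1], subtract the in-mask mean, and resample to a target spacing
(trilinear for intensities, nearest-neighbour for masks).  Fixed-size
(16, 96, 96) patches are then cropped around annotated nodule centres.

Ground-truth masks come from per-slice nodule contours stored in LIDC-style
XML files, rasterized with inclusive edges and combined across readers by a
consensus vote.
"""

from __future__ import annotations

import math
import os
import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
import pandas as pd
import SimpleITK as sitk
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon
from skimage.draw import polygon_perimeter as _sk_polygon_perimeter

PATCH_SHAPE = (16, 96, 96)

TRAIN_SUBSETS = tuple(range(8))
VAL_SUBSETS = (8, 9)


@dataclass
class CTVolume:
    """A CT scan: voxels indexed (z, y, x), world metadata in (x, y, z) mm."""

    voxels: np.ndarray
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    series_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError(f"volume must be non-degenerate 3-D, got {self.voxels.shape}")
        if min(self.spacing) <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass(frozen=True)
class NoduleAnnotation:
    series_id: str
    center_world: tuple[float, float, float]   # (x, y, z) mm
    diameter_mm: float

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter_mm}")


@dataclass
class PatchPair:
    """A (16, 96, 96) image patch with its binary nodule mask."""

    image: np.ndarray
    mask: np.ndarray
    series_id: str = ""
    center_world: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError("image/mask shape mismatch")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.mask = self.mask.astype(np.uint8)


@dataclass
class PreprocessConfig:
    hu_window: tuple[float, float] = (-1000.0, 400.0)
    target_spacing: tuple[float, float, float] = (2.0, 0.7, 0.7)   # (z, y, x) mm
    resample: bool = True


# ---------------------------------------------------------------------------
# MetaImage I/O
# ---------------------------------------------------------------------------

_MHD_BYTES = {
    "MET_CHAR": 1, "MET_UCHAR": 1, "MET_SHORT": 2, "MET_USHORT": 2,
    "MET_INT": 4, "MET_UINT": 4, "MET_FLOAT": 4, "MET_DOUBLE": 8,
}


def _check_mhd_payload(path: str):
    """Verify the companion .raw exists and has the byte count the header
    declares; MetaImage loaders otherwise fail with opaque messages."""
    header = {}
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            if "=" in line:
                key, val = line.split("=", 1)
                header[key.strip()] = val.strip()
    datafile = header.get("ElementDataFile", "")
    if not datafile or datafile.upper() == "LOCAL":
        return
    raw_path = os.path.join(os.path.dirname(path) or ".", datafile)
    if not os.path.exists(raw_path):
        raise FileNotFoundError(f"missing raw data file {raw_path!r} for header {path!r}")
    dims = [int(v) for v in re.split(r"\s+", header.get("DimSize", "")) if v]
    etype = header.get("ElementType", "MET_SHORT")
    nchan = int(header.get("ElementNumberOfChannels", 1))
    if dims and etype in _MHD_BYTES:
        expected = int(np.prod(dims)) * _MHD_BYTES[etype] * nchan
        actual = os.path.getsize(raw_path)
        if expected != actual:
            raise ValueError(
                f"truncated or corrupt raw file {raw_path!r}: header {path!r} "
                f"declares {expected} bytes, file has {actual} bytes")


def read_volume(path: str) -> CTVolume:
    """Read a MetaImage volume; voxels come back in HU, axis order (z, y, x)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path!r}")
    if path.endswith(".mhd"):
        _check_mhd_payload(path)
    try:
        img = sitk.ReadImage(path)
    except RuntimeError as exc:
        raise ValueError(f"failed to parse volume {path!r}: {exc}") from exc
    voxels = sitk.GetArrayFromImage(img)          # (z, y, x)
    series_id = os.path.splitext(os.path.basename(path))[0]
    return CTVolume(voxels, tuple(img.GetOrigin()), tuple(img.GetSpacing()),
                    series_id)


def write_volume(vol: CTVolume, path: str):
    img = sitk.GetImageFromArray(vol.voxels)
    img.SetOrigin(tuple(float(v) for v in vol.origin))
    img.SetSpacing(tuple(float(v) for v in vol.spacing))
    sitk.WriteImage(img, path)


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def world_to_voxel(coord_mm, vol: CTVolume) -> tuple[int, int, int]:
    """Map an (x, y, z) mm world coordinate to a 0-based (z, y, x) index."""
    coord = np.asarray(coord_mm, dtype=float)
    idx_xyz = np.round((coord - np.asarray(vol.origin)) / np.asarray(vol.spacing))
    zyx = idx_xyz[::-1].astype(int)
    shape = np.asarray(vol.shape)
    if np.any(zyx < -1) or np.any(zyx > shape):
        raise ValueError(
            f"world coordinate {tuple(coord)} mm maps to voxel {tuple(zyx)} "
            f"outside volume of shape {tuple(shape)} "
            f"(origin {vol.origin}, spacing {vol.spacing})")
    zyx = np.clip(zyx, 0, shape - 1)
    return tuple(int(v) for v in zyx)


def voxel_to_world(index_zyx, vol: CTVolume) -> tuple[float, float, float]:
    """Inverse of :func:`world_to_voxel` (voxel centre, (x, y, z) mm)."""
    idx = np.asarray(index_zyx, dtype=float)[::-1]
    return tuple(idx * np.asarray(vol.spacing) + np.asarray(vol.origin))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _normalize(voxels: np.ndarray, mask: np.ndarray,
               window: tuple[float, float]) -> np.ndarray:
    """Clip to the HU window, min-max scale over in-mask voxels, demean
    in-mask; out-of-mask voxels stay exactly zero.

    The combination is idempotent: re-running it on its own output is a
    no-op, because min-max scaling is invariant to the affine shift the
    demeaning applies and the HU window contains the normalized range.
    """
    m = mask.astype(bool)
    out = np.zeros_like(voxels, dtype=np.float32)
    if not m.any():
        return out
    v = np.clip(voxels[m], window[0], window[1]).astype(np.float32)
    vmin, vmax = float(v.min()), float(v.max())
    if vmax > vmin:
        v = (v - vmin) / (vmax - vmin)
    else:
        v = np.zeros_like(v)
    v -= v.mean()
    out[m] = v
    return out


def resample_to_spacing(vol: CTVolume, target_spacing_zyx, order: int = 1) -> CTVolume:
    """Resample to a new (z, y, x) spacing; ``order=1`` trilinear, ``0`` nearest."""
    spacing_zyx = np.asarray(vol.spacing)[::-1]
    target = np.asarray(target_spacing_zyx, dtype=float)
    zoom = spacing_zyx / target
    voxels = ndimage.zoom(vol.voxels.astype(np.float32), zoom, order=order,
                          mode="nearest", grid_mode=False)
    new_spacing = tuple(float(s) for s in target[::-1])   # back to (x, y, z)
    return CTVolume(voxels, vol.origin, new_spacing, vol.series_id)


def preprocess_volume(vol: CTVolume, lung_mask: np.ndarray,
                      cfg: PreprocessConfig = PreprocessConfig()):
    """Lung masking, normalization and resampling.

    Returns ``(volume, mask)`` where the mask has been carried through the
    same resampling with nearest-neighbour interpolation.
    """
    lung_mask = np.asarray(lung_mask)
    if lung_mask.shape != vol.shape:
        raise ValueError(
            f"lung mask shape {lung_mask.shape} != volume shape {vol.shape}")
    masked = vol.voxels * (lung_mask > 0)
    normalized = _normalize(masked, lung_mask, cfg.hu_window)
    out = CTVolume(normalized, vol.origin, vol.spacing, vol.series_id)
    mask_out = (lung_mask > 0).astype(np.uint8)
    if cfg.resample:
        out = resample_to_spacing(out, cfg.target_spacing)
        mask_vol = resample_to_spacing(
            CTVolume(mask_out.astype(np.float32), vol.origin, vol.spacing),
            cfg.target_spacing, order=0)
        mask_out = mask_vol.voxels.astype(np.uint8)
    return out, mask_out


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

def extract_patch(vol: CTVolume, nodule_mask: np.ndarray, ann: NoduleAnnotation,
                  patch_shape: tuple[int, int, int] = PATCH_SHAPE) -> PatchPair:
    """Crop a fixed-size patch centred on the annotation, zero-padding at
    volume borders; the nodule mask is cropped identically."""
    nodule_mask = np.asarray(nodule_mask)
    if nodule_mask.shape != vol.shape:
        raise ValueError(
            f"nodule mask shape {nodule_mask.shape} != volume shape {vol.shape}")
    center = world_to_voxel(ann.center_world, vol)
    img = np.zeros(patch_shape, dtype=np.float32)
    msk = np.zeros(patch_shape, dtype=np.uint8)
    starts = [c - s // 2 for c, s in zip(center, patch_shape)]
    src = []
    dst = []
    for ax, (start, size, dim) in enumerate(zip(starts, patch_shape, vol.shape)):
        lo = max(start, 0)
        hi = min(start + size, dim)
        if lo >= hi:
            raise ValueError(
                f"annotation centre {center} of {ann.series_id!r} lies outside "
                f"the volume on axis {ax}")
        src.append(slice(lo, hi))
        dst.append(slice(lo - start, hi - start))
    img[tuple(dst)] = vol.voxels[tuple(src)]
    msk[tuple(dst)] = (nodule_mask[tuple(src)] > 0).astype(np.uint8)
    return PatchPair(img, msk, ann.series_id, ann.center_world)


# ---------------------------------------------------------------------------
# LIDC-style XML contour rasterization
# ---------------------------------------------------------------------------

def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _rasterize_slice(xs: np.ndarray, ys: np.ndarray, shape_yx) -> np.ndarray:
    """Fill one polygon with inclusive edges (even-odd interior plus the
    boundary pixels themselves)."""
    sl = np.zeros(shape_yx, dtype=bool)
    if len(xs) == 0:
        return sl
    rr, cc = _sk_polygon(ys, xs, shape=shape_yx)
    sl[rr, cc] = True
    if len(xs) >= 2:
        rr, cc = _sk_polygon_perimeter(ys, xs, shape=shape_yx, clip=True)
        sl[rr, cc] = True
    else:
        sl[int(round(ys[0])) % shape_yx[0], int(round(xs[0])) % shape_yx[1]] = True
    return sl


def lidc_contours_to_mask(xml_doc: str, vol: CTVolume,
                          consensus: float = 0.5) -> np.ndarray:
    """Rasterize per-slice nodule contours from a LIDC-style XML document.

    ``xml_doc`` may be a path or an XML string.  Each reading session
    produces one reader mask (polygon fill per slice, slices matched to the
    volume by world z-position); a voxel is kept when at least
    ``consensus`` of the readers that drew any contour include it.
    """
    if os.path.exists(xml_doc):
        tree = ET.parse(xml_doc)
        root = tree.getroot()
    else:
        root = ET.fromstring(xml_doc)

    z0 = vol.origin[2]
    dz = vol.spacing[2]
    nz = vol.shape[0]
    reader_masks = []
    for session in root.iter():
        if _strip_ns(session.tag) != "readingSession":
            continue
        mask = np.zeros(vol.shape, dtype=bool)
        drew = False
        for roi in session.iter():
            if _strip_ns(roi.tag) != "roi":
                continue
            zpos = None
            xs, ys = [], []
            for el in roi.iter():
                t = _strip_ns(el.tag)
                if t == "imageZposition":
                    zpos = float(el.text)
                elif t == "edgeMap":
                    coords = {_strip_ns(c.tag): float(c.text) for c in el}
                    xs.append(coords["xCoord"])
                    ys.append(coords["yCoord"])
            if not xs:
                continue   # empty contour
            if zpos is None:
                warnings.warn("contour without z-position skipped")
                continue
            zi = (zpos - z0) / dz
            zidx = int(round(zi))
            if abs(zi - zidx) > 0.5 or not (0 <= zidx < nz):
                warnings.warn(
                    f"contour z-position {zpos} mm does not match any slice; skipped")
                continue
            mask[zidx] |= _rasterize_slice(np.asarray(xs), np.asarray(ys),
                                           vol.shape[1:])
            drew = True
        if drew:
            reader_masks.append(mask)
    if not reader_masks:
        return np.zeros(vol.shape, dtype=np.uint8)
    votes = np.sum(reader_masks, axis=0)
    needed = max(1, int(math.ceil(consensus * len(reader_masks))))
    return (votes >= needed).astype(np.uint8)


# ---------------------------------------------------------------------------
# Subset split
# ---------------------------------------------------------------------------

def split_subsets(annotation_table: pd.DataFrame):
    """Split series IDs by their LUNA16-style subset tags.

    Subsets 0-7 train, 8-9 validate; a series never appears in both.
    Expects columns ``series_id`` (or ``seriesuid``) and ``subset``.
    """
    df = annotation_table
    col = "series_id" if "series_id" in df.columns else "seriesuid"
    unknown = set(df["subset"].unique()) - set(TRAIN_SUBSETS) - set(VAL_SUBSETS)
    if unknown:
        raise ValueError(f"unknown subset indices: {sorted(unknown)}")
    train_ids = sorted(df.loc[df["subset"].isin(TRAIN_SUBSETS), col].unique())
    val_ids = sorted(df.loc[df["subset"].isin(VAL_SUBSETS), col].unique())
    overlap = set(train_ids) & set(val_ids)
    if overlap:
        raise ValueError(
            f"series assigned to both train and validation subsets: {sorted(overlap)[:5]}")
    return train_ids, val_ids


def read_annotations(csv_path: str) -> list[NoduleAnnotation]:
    """Read a LUNA16-dialect annotations CSV
    (seriesuid, coordX, coordY, coordZ, diameter_mm)."""
    df = pd.read_csv(csv_path)
    return [
        NoduleAnnotation(str(r.seriesuid),
                         (float(r.coordX), float(r.coordY), float(r.coordZ)),
                         float(r.diameter_mm))
        for r in df.itertuples()
    ]
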