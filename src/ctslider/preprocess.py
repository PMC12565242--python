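"""CT preprocessing: HU recovery, windowing, scanner mask, RGB fusion.

Windowing maps Hounsfield units into 8-bit display range with an inclusive
window ``[level - width/2, level + width/2]``::

    out = round(255 * clip((HU - (level - width/2)) / width, 0, 1))

with round-half-away-from-zero quantisation.  The identification pathway
fuses three organ-specific windows into an RGB composite (enhanced lung,
pulmonary-embolism-specific, mediastinal) resized to a square model input;
the marker-extraction pathway uses the single enhanced-lung window.

The scanner mask harmonises non-anatomical regions across scanners: pixels
that never rise above the outside-field-of-view sentinel in a reference
dataset are forced to air (-1024 HU) in every processed image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.measure import label as cc_label
from skimage.transform import resize as _sk_resize

__all__ = [
    "CTVolume",
    "WindowSpec",
    "ScannerMask",
    "ENHANCED_LUNG_WINDOW",
    "PE_WINDOW",
    "MEDIASTINAL_WINDOW",
    "RGB_WINDOWS",
    "apply_window",
    "rgb_windowing",
    "derive_scanner_mask",
    "apply_scanner_mask",
    "load_dicom_series",
    "export_pm_slices",
]

MASK_FILL_HU = -1024.0
FOV_SENTINEL_HU = -1500.0


@dataclass
class CTVolume:
    """An ordered stack of HU slices for one case, superior to inferior."""

    case_id: str
    slices: np.ndarray            # (M, H, W) float HU
    slice_spacing_mm: float = 4.0
    site_tag: str = ""

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 3:
            raise ValueError(f"{self.case_id}: need at least 3 stacked slices, "
                             f"got shape {self.slices.shape}")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError(f"{self.case_id}: non-finite HU values")

    @property
    def n_slices(self) -> int:
        return int(self.slices.shape[0])


@dataclass(frozen=True)
class WindowSpec:
    level: float
    width: float
    name: str = ""

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


ENHANCED_LUNG_WINDOW = WindowSpec(-700.0, 700.0, "enhanced_lung")
PE_WINDOW = WindowSpec(100.0, 700.0, "pe_specific")
MEDIASTINAL_WINDOW = WindowSpec(40.0, 400.0, "mediastinal")
RGB_WINDOWS = (ENHANCED_LUNG_WINDOW, PE_WINDOW, MEDIASTINAL_WINDOW)


@dataclass
class ScannerMask:
    mask: np.ndarray              # binary (H, W)
    provenance: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("scanner mask has no foreground pixels")


def _quantize8(frac: np.ndarray) -> np.ndarray:
    # round half away from zero; frac is already within [0, 1]
    return np.floor(frac * 255.0 + 0.5).astype(np.uint8)


def apply_window(hu_image: np.ndarray, window: WindowSpec) -> np.ndarray:
    """Map an HU image through a (level, width) window to 8-bit grayscale."""
    hu_image = np.asarray(hu_image, dtype=np.float64)
    lo = window.level - window.width / 2.0
    frac = np.clip((hu_image - lo) / window.width, 0.0, 1.0)
    return _quantize8(frac)


def resize_image(image: np.ndarray, out_size: int) -> np.ndarray:
    """Bilinear resize to a square, preserving value range (float output)."""
    if image.shape[0] == out_size and image.shape[1] == out_size:
        return np.asarray(image, dtype=np.float64)
    return _sk_resize(np.asarray(image, dtype=np.float64), (out_size, out_size),
                      order=1, preserve_range=True, anti_aliasing=False)


def rgb_windowing(hu_image: np.ndarray, out_size: int = 518,
                  order: str = "window_first") -> np.ndarray:
    """Fuse the three fixed windows of one HU slice into an RGB composite.

    ``order='window_first'`` (default) windows the HU image to 8 bits and then
    resizes each channel bilinearly; ``'resize_first'`` resizes the HU image
    once and windows afterwards, avoiding interpolation on quantised values.
    Channels are stacked (enhanced lung, PE-specific, mediastinal).
    """
    if order not in ("window_first", "resize_first"):
        raise ValueError(f"unknown order {order!r}")
    channels = []
    if order == "resize_first":
        hu = resize_image(hu_image, out_size)
        channels = [apply_window(hu, w) for w in RGB_WINDOWS]
    else:
        for w in RGB_WINDOWS:
            ch = resize_image(apply_window(hu_image, w).astype(np.float64), out_size)
            channels.append(np.clip(np.floor(ch + 0.5), 0, 255).astype(np.uint8))
    return np.stack(channels, axis=-1)


def derive_scanner_mask(reference_volumes: list[CTVolume],
                        sentinel: float = FOV_SENTINEL_HU) -> ScannerMask:
    """Field-of-view mask from reference volumes.

    A pixel belongs to the field of view if it ever exceeds the outside-FOV
    sentinel in any reference slice; the largest connected such region is
    kept.  This is a stand-in heuristic — vendor FOV metadata, when present,
    would be authoritative.
    """
    if not reference_volumes:
        raise ValueError("need at least one reference volume")
    fg = None
    for vol in reference_volumes:
        ever = (vol.slices > sentinel).any(axis=0)
        fg = ever if fg is None else (fg | ever)
    if not fg.any():
        raise ValueError("reference volumes contain no in-FOV pixels")
    labels, n = cc_label(fg, return_num=True, connectivity=1)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        fg = labels == (int(np.argmax(sizes)) + 1)
    prov = ",".join(sorted({v.site_tag or v.case_id for v in reference_volumes}))
    return ScannerMask(mask=fg, provenance=prov)


def apply_scanner_mask(hu_image: np.ndarray, mask: ScannerMask | np.ndarray,
                       allow_resample: bool = True) -> np.ndarray:
    """Force outside-mask pixels to air (-1024 HU); inside unchanged."""
    m = mask.mask if isinstance(mask, ScannerMask) else np.asarray(mask, dtype=bool)
    hu_image = np.asarray(hu_image, dtype=np.float64)
    if m.shape != hu_image.shape:
        if not allow_resample:
            raise ValueError(f"mask shape {m.shape} != image shape {hu_image.shape}")
        m = _sk_resize(m.astype(float), hu_image.shape, order=0,
                       preserve_range=True, anti_aliasing=False) > 0.5
    out = hu_image.copy()
    out[~m] = MASK_FILL_HU
    return out


def load_dicom_series(path: str | Path) -> CTVolume:
    """Load one axial DICOM series as HU, sorted superior to inferior.

    HU = stored * RescaleSlope + RescaleIntercept.  Slices are ordered by
    descending patient z so that index 0 is the most superior slice,
    matching the sequential apical-to-diaphragm naming used on export.
    """
    import pydicom

    path = Path(path)
    datasets = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        datasets.append(ds)
    if not datasets:
        raise ValueError(f"{path}: no readable DICOM files")
    series = {str(ds.SeriesInstanceUID) for ds in datasets}
    if len(series) != 1:
        raise ValueError(f"{path}: found {len(series)} series in one directory; "
                         "expected exactly one")
    for ds in datasets:
        if "ImagePositionPatient" not in ds:
            raise ValueError(f"{path}: slice missing ImagePositionPatient geometry")
    datasets.sort(key=lambda ds: -float(ds.ImagePositionPatient[2]))
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    case_id = str(getattr(datasets[0], "PatientID", path.name))
    spacing = float(getattr(datasets[0], "SliceThickness", 4.0))
    return CTVolume(case_id=case_id, slices=np.stack(slices),
                    slice_spacing_mm=spacing)


def export_pm_slices(volume: CTVolume, out_dir: str | Path,
                     mask: ScannerMask | None = None, size: int = 256) -> Path:
    """Write the marker-extraction inputs: enhanced-lung 8-bit PNGs, named
    sequentially from the apical lung to the diaphragm."""
    from PIL import Image

    out = Path(out_dir) / volume.case_id
    out.mkdir(parents=True, exist_ok=True)
    for m, hu in enumerate(volume.slices):
        if mask is not None:
            hu = apply_scanner_mask(hu, mask)
        img = apply_window(hu, ENHANCED_LUNG_WINDOW).astype(np.float64)
        img = np.clip(np.floor(resize_image(img, size) + 0.5), 0, 255).astype(np.uint8)
        Image.fromarray(img, mode="L").save(out / f"slice{m:03d}.png")
    return out
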