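"""Synthetic chest-CT phantoms with known anatomical position markers.

Each phantom is a cartoon axial CT volume in Hounsfield units: a circular
soft-tissue body inside a square field whose corners sit at the -2000 HU
outside-field-of-view sentinel, two aerated-lung ellipses whose cross-section
grows from an apical onset slice, plateaus, and shrinks to nothing at a
disappearance slice, a tracheal air lumen that splits into two bronchial
lumens at a known bifurcation slice, and a liver-like dome in the basal
slices.  Positive (PF-ILD-like) cases additionally receive a subpleural,
basal-predominant high-attenuation texture whose amplitude is controlled by
``fibrosis_severity`` — the knob that sets class separability downstream.

The three anatomical position markers (PMs) used for slice selection are
fully determined by the construction:

* upper  = first slice with aerated lung parenchyma (``apical_onset``),
* middle = first slice with two bronchial lumens (``bifurcation``),
* lower  = three slices superior to bilateral parenchyma disappearance.

``rederive_pm_truth`` recomputes the markers from voxel content alone, which
is how the generator's ground truth is validated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, label as cc_label

from .preprocess import CTVolume
from .pm import PMAnnotation

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom_volume",
    "pm_ground_truth",
    "rederive_pm_truth",
    "generate_cohort",
    "save_case",
    "load_case",
    "write_dicom_series",
]

OUTSIDE_FOV_HU = -2000.0
BODY_HU = 20.0
LUNG_HU = -850.0
AIRWAY_HU = -950.0
LIVER_HU = 60.0
AERATED_THRESHOLD_HU = -500.0

# geometry fractions of the image side (calibrated to a 256 px field)
_LUNG_CX = 0.22       # lateral offset of each lung centre
_LUNG_CY = 0.52
_LUNG_AX = 0.12       # half-axes at full profile
_LUNG_AY = 0.26
_AIRWAY_CY = 0.40
_TRACHEA_R = 0.025
_BRONCHUS_R = 0.022
_MEDIASTINUM_HALF_WIDTH = 0.08
_LIVER_CY = 0.62


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case; indices are 0-based slice numbers."""

    n_slices: int = 75
    apical_onset: int = 6
    bifurcation: int = 30
    disappearance: int = 62
    lung_geometry: dict | None = None
    fibrosis_severity: float = 0.0
    noise_sd: float = 20.0
    image_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.apical_onset < self.bifurcation < self.disappearance <= self.n_slices - 1):
            raise ValueError(
                "phantom requires 0 <= apical_onset < bifurcation < disappearance "
                f"<= n_slices-1, got ({self.apical_onset}, {self.bifurcation}, "
                f"{self.disappearance}) with n_slices={self.n_slices}")
        if not 0.0 <= self.fibrosis_severity <= 1.0:
            raise ValueError(f"fibrosis_severity must be in [0, 1], got {self.fibrosis_severity}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.image_size < 64:
            raise ValueError("image_size below 64 px cannot guarantee the marker geometry")


@dataclass
class PhantomCase:
    """A generated volume together with its marker ground truth and label."""

    volume: CTVolume
    pm_truth: PMAnnotation
    label: int
    spec: PhantomSpec


def pm_ground_truth(spec: PhantomSpec, case_id: str = "phantom") -> PMAnnotation:
    """Apply the marker labelling rules to a spec.

    The lower marker sits exactly three slices superior to the bilateral
    disappearance level (the clinical rule allows three to four; three is
    fixed here for determinism).
    """
    lower = spec.disappearance - 3
    if lower <= spec.bifurcation:
        raise ValueError(
            f"phantom too compressed: lower marker {lower} (= disappearance-3) "
            f"must lie below the bifurcation {spec.bifurcation}")
    return PMAnnotation(case_id=case_id, upper=spec.apical_onset,
                        middle=spec.bifurcation, lower=lower)


def _ellipse(size: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    yy, xx = np.ogrid[:size, :size]
    return ((xx - cx) / max(ax, 1e-9)) ** 2 + ((yy - cy) / max(ay, 1e-9)) ** 2 <= 1.0


def _lung_profile(m: int, spec: PhantomSpec) -> tuple[float, float]:
    """(relative lung cross-section, diaphragm-dome progression), both in
    [0, 1], as a function of slice index.

    The cross-section rises like the square root of the distance from the
    apical onset (the slice-to-slice growth is largest right at the onset,
    making it visually localisable), plateaus, and declines linearly over
    the last eight aerated slices while the dome progression carves the
    basal lungs into increasingly thin crescents.
    """
    a, b, d = spec.apical_onset, spec.bifurcation, spec.disappearance
    decline_start = max(b + 1, d - 8)
    if m < a or m >= d:
        return 0.0, 0.0
    if m < b:
        u = (m - a) / max(b - a, 1)
        return 0.15 + 0.85 * math.sqrt(u), 0.0
    if m < decline_start:
        return 1.0, 0.0
    v = (m - decline_start) / max(d - 1 - decline_start, 1)
    return 1.0 - 0.85 * v, v


def _body_radius(m: int, spec: PhantomSpec) -> float:
    """Body cross-section radius fraction: narrow at the neck, widening to
    the full thorax at the bifurcation level."""
    return 0.30 + 0.15 * min((m + 1) / (spec.bifurcation + 1), 1.0)


def generate_phantom_volume(spec: PhantomSpec, case_id: str = "phantom",
                            site_tag: str = "siteA") -> PhantomCase:
    """Render a phantom volume; deterministic for a given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    geom = {"lung_ax": _LUNG_AX, "lung_ay": _LUNG_AY, "lung_cx": _LUNG_CX}
    if spec.lung_geometry:
        geom.update(spec.lung_geometry)

    # one band-limited texture field per case, reused across basal slices
    fib_field = gaussian_filter(rng.standard_normal((s, s)), sigma=max(1.0, s / 64))
    fib_field = (fib_field - fib_field.min()) / max(np.ptp(fib_field), 1e-12)

    label_flag = int(spec.fibrosis_severity > 0)
    liver_start = max(spec.bifurcation + 1, spec.disappearance - 8)
    b, d = spec.bifurcation, spec.disappearance

    slices = []
    for m in range(spec.n_slices):
        img = np.full((s, s), OUTSIDE_FOV_HU, dtype=np.float64)
        rb = _body_radius(m, spec) * s
        body = _ellipse(s, s / 2, s / 2, rb, rb)
        img[body] = BODY_HU

        if m < spec.apical_onset:
            # shoulder girdle: broad lateral soft-tissue masses that make
            # supra-apical slices look unlike the apical onset
            for side in (-1, +1):
                shoulder = _ellipse(s, s / 2 + side * 0.34 * s, 0.50 * s,
                                    0.16 * s, 0.10 * s)
                img[shoulder] = BODY_HU
                body |= shoulder

        if m >= liver_start:
            frac = (m - liver_start + 1) / max(spec.n_slices - liver_start, 1)
            liver = _ellipse(s, s / 2, _LIVER_CY * s, 0.32 * s * frac, 0.16 * s * frac) & body
            img[liver] = LIVER_HU

        prof, dome = _lung_profile(m, spec)
        lung_mask = np.zeros((s, s), dtype=bool)
        rim_mask = np.zeros((s, s), dtype=bool)
        if prof > 0:
            ax, ay = prof * geom["lung_ax"] * s, prof * geom["lung_ay"] * s
            cy = _LUNG_CY * s
            for side in (-1, +1):
                cx = s / 2 + side * geom["lung_cx"] * s
                lung = _ellipse(s, cx, cy, ax, ay)
                inner = _ellipse(s, cx, cy, 0.75 * ax, 0.75 * ay)
                if dome > 0:
                    # diaphragm dome rising into the basal lung: the aerated
                    # section becomes a superior crescent
                    carve = _ellipse(s, cx, cy + (1.5 - 1.2 * dome) * ay, 1.4 * ax, ay)
                    lung &= ~carve
                    inner &= ~carve
                lung_mask |= lung
                rim_mask |= lung & ~inner
            img[lung_mask] = LUNG_HU

        # airway: single tracheal lumen above the bifurcation, two bronchial
        # lumens separated by a soft-tissue wall at and below it
        if spec.apical_onset <= m < min(b + 10, d):
            cy = _AIRWAY_CY * s
            if m < b:
                img[_ellipse(s, s / 2, cy, _TRACHEA_R * s, _TRACHEA_R * s)] = AIRWAY_HU
            else:
                sep = min(0.03 + 0.012 * (m - b), 0.05) * s
                r = _BRONCHUS_R * s
                for side in (-1, +1):
                    img[_ellipse(s, s / 2 + side * sep, cy, r, r)] = AIRWAY_HU

        # gastric air bubble under the left hemidiaphragm: a gas dome a few
        # slices tall whose apex sits at the upper-diaphragm level — air
        # that is *not* lung parenchyma
        dz = (m - (d - 3)) / 3.5
        if abs(dz) < 1.0:
            rb_bubble = 0.07 * s * math.sqrt(1.0 - dz * dz)
            img[_ellipse(s, s / 2 - 0.12 * s, 0.70 * s, rb_bubble, rb_bubble)] = -750.0

        # subpleural fibrosis-like texture with an apicobasal gradient
        # (positives only); the two most caudal aerated slices are spared so
        # thin basal crescents always keep sub -500 HU parenchyma
        if label_flag and b < m <= d - 3 and rim_mask.any():
            grad = (m - b) / max(d - b, 1)
            img[rim_mask] += (spec.fibrosis_severity * grad
                              * (200.0 + 200.0 * fib_field[rim_mask]))

        if spec.noise_sd > 0:
            noise = rng.normal(0.0, spec.noise_sd, (s, s))
            img[body] += noise[body]
        slices.append(img.astype(np.float32))

    volume = CTVolume(case_id=case_id, slices=np.stack(slices),
                      slice_spacing_mm=4.0, site_tag=site_tag)
    return PhantomCase(volume=volume, pm_truth=pm_ground_truth(spec, case_id),
                       label=label_flag, spec=spec)


def rederive_pm_truth(volume: CTVolume) -> PMAnnotation:
    """Recompute the markers from voxel content alone.

    Aerated lung parenchyma is any sub -500 HU voxel outside the central
    mediastinal column and above the diaphragm line (air below that line,
    e.g. bowel gas, is not parenchyma and is ignored); the bifurcation is
    the first slice whose mediastinal column contains two disconnected air
    lumens; the lower marker is three slices above the first slice (after
    onset) with no aerated parenchyma.
    """
    s = volume.slices.shape[-1]
    xx = np.arange(s)
    column = np.abs(xx - s / 2) < _MEDIASTINUM_HALF_WIDTH * s
    above_diaphragm = np.arange(s) < 0.60 * s

    upper = middle = disappearance = None
    for m, img in enumerate(volume.slices):
        air = img < AERATED_THRESHOLD_HU
        in_body = img > OUTSIDE_FOV_HU + 100
        lung_air = air & in_body & ~column[None, :] & above_diaphragm[:, None]
        if upper is None and lung_air.any():
            upper = m
        if middle is None:
            med_air = air & in_body & column[None, :]
            n_lumen = cc_label(med_air)[1]
            if n_lumen >= 2:
                middle = m
        if upper is not None and disappearance is None and m > upper and not lung_air.any():
            disappearance = m
    if upper is None or middle is None or disappearance is None:
        raise ValueError("volume does not contain the expected anatomical structures")
    return PMAnnotation(case_id=volume.case_id, upper=upper, middle=middle,
                        lower=disappearance - 3)


def generate_cohort(n_cases: int, prevalence: float,
                    base_spec: PhantomSpec | None = None,
                    jitter: dict[str, int] | None = None,
                    seed: int = 0,
                    severity_range: tuple[float, float] = (0.7, 1.0),
                    ) -> list[PhantomCase]:
    """Simulate a cohort of phantoms with jittered marker positions.

    Labels are Bernoulli(prevalence); positive cases draw their fibrosis
    severity uniformly from ``severity_range``.  Cases alternate between two
    site tags to exercise multi-site bookkeeping.  Deterministic given seed.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    base = base_spec or PhantomSpec()
    jit = {"apical_onset": 2, "bifurcation": 3, "disappearance": 3}
    if jitter:
        jit.update(jitter)

    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        y = int(rng.random() < prevalence)
        severity = float(rng.uniform(*severity_range)) if y else 0.0
        offsets = {k: int(rng.integers(-v, v + 1)) if v else 0 for k, v in jit.items()}
        spec = replace(
            base,
            apical_onset=base.apical_onset + offsets["apical_onset"],
            bifurcation=base.bifurcation + offsets["bifurcation"],
            disappearance=base.disappearance + offsets["disappearance"],
            fibrosis_severity=severity,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case = generate_phantom_volume(spec, case_id=f"case{i:04d}",
                                       site_tag="siteA" if i % 2 == 0 else "siteB")
        cases.append(case)
    return cases


# ---------------------------------------------------------------------------
# on-disk layout: one 16-bit grayscale PNG per slice + a JSON sidecar
# ---------------------------------------------------------------------------

_HU_OFFSET = 2048  # stored uint16 = HU + 2048


def save_case(case: PhantomCase, out_dir: str | Path) -> Path:
    from PIL import Image

    out = Path(out_dir) / case.volume.case_id
    out.mkdir(parents=True, exist_ok=True)
    for m, img in enumerate(case.volume.slices):
        stored = np.clip(np.round(img + _HU_OFFSET), 0, 65535).astype(np.uint16)
        Image.fromarray(stored, mode="I;16").save(out / f"slice{m:03d}.png")
    meta = {
        "case_id": case.volume.case_id,
        "n_slices": int(case.volume.slices.shape[0]),
        "slice_spacing_mm": case.volume.slice_spacing_mm,
        "site_tag": case.volume.site_tag,
        "pm": {"upper": case.pm_truth.upper, "middle": case.pm_truth.middle,
               "lower": case.pm_truth.lower},
        "label": case.label,
        "fibrosis_severity": case.spec.fibrosis_severity,
        "hu_offset": _HU_OFFSET,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=1))
    return out


def load_case(case_dir: str | Path) -> tuple[CTVolume, PMAnnotation, int]:
    from PIL import Image

    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "metadata.json").read_text())
    paths = sorted(case_dir.glob("slice*.png"))
    if len(paths) != meta["n_slices"]:
        raise ValueError(f"{case_dir}: expected {meta['n_slices']} slices, found {len(paths)}")
    slices = np.stack([
        np.asarray(Image.open(p), dtype=np.float32) - meta["hu_offset"] for p in paths
    ])
    volume = CTVolume(case_id=meta["case_id"], slices=slices,
                      slice_spacing_mm=meta["slice_spacing_mm"],
                      site_tag=meta["site_tag"])
    pm = PMAnnotation(case_id=meta["case_id"], upper=meta["pm"]["upper"],
                      middle=meta["pm"]["middle"], lower=meta["pm"]["lower"])
    return volume, pm, int(meta["label"])


def write_dicom_series(volume: CTVolume, out_dir: str | Path,
                       shuffle_names_seed: int | None = None) -> Path:
    """Emit the volume as a minimal axial CT DICOM series (for I/O tests).

    Slice order on disk is conveyed only through ImagePositionPatient (the
    superior slice has the largest z), so file naming is irrelevant; pass
    ``shuffle_names_seed`` to scramble file names deliberately.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    n = volume.slices.shape[0]
    order = np.arange(n)
    if shuffle_names_seed is not None:
        order = np.random.default_rng(shuffle_names_seed).permutation(n)
    for name_idx, m in enumerate(order):
        img = volume.slices[m]
        ds = Dataset()
        ds.SOPClassUID = "1.2.840.10008.5.1.4.1.1.2"  # CT Image Storage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "CT"
        ds.PatientID = volume.case_id
        ds.InstanceNumber = int(m) + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        # superior slices have larger patient z; 4 mm spacing
        ds.ImagePositionPatient = [0.0, 0.0, float(-volume.slice_spacing_mm * m)]
        ds.PixelSpacing = [1.0, 1.0]
        ds.SliceThickness = volume.slice_spacing_mm
        ds.Rows, ds.Columns = img.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -3000.0
        stored = np.clip(np.round(img - ds.RescaleIntercept), 0, 65535).astype(np.uint16)
        ds.PixelData = stored.tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        pydicom.dcmwrite(out / f"IM{name_idx:04d}.dcm", ds,
                         enforce_file_format=True)
    return out
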