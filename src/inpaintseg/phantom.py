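"""Synthetic 2D phantoms: MRI-like and CT-like slices with ground truth.

Each phantom carries four disjoint tissue structures (axis-aligned ellipses,
one rendered as an annulus) on a constant background, one structure per
segmentation class.  MRI phantoms additionally carry a per-pixel T2
relaxation-time map (piecewise constant per class, optional Gaussian
jitter); CT phantoms are generated directly in Hounsfield Units.  Class
shapes are confined to image quadrants with jittered centers, which makes
them trivially disjoint and keeps per-class areas analytically checkable.

All randomness derives from ``(spec.seed, index)``, so samples are
bit-reproducible.  The generator emulates only what downstream stages need
-- tissue classes with distinct intensities, quantitative maps, calibrated
pixel spacing -- not anatomy or MR physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "PhantomSpec",
    "Sample",
    "generate_sample",
    "generate_dataset",
    "load_dataset",
    "load_manifest",
    "MRI_INTENSITY",
    "CT_INTENSITY",
    "MRI_T2",
]

Modality = Literal["mri", "ct"]

N_CLASSES = 4
HU_MIN, HU_MAX = -1024, 3071

#: default class mean intensities (arbitrary units) for MRI phantoms
MRI_INTENSITY = {1: 120.0, 2: 90.0, 3: 60.0, 4: 150.0}
#: default class mean HU for CT phantoms (fat-like classes 1-3, muscle-like 4)
CT_INTENSITY = {1: -100.0, 2: -80.0, 3: -60.0, 4: 45.0}
#: default per-class T2 relaxation times, milliseconds
MRI_T2 = {1: 35.0, 2: 40.0, 3: 45.0, 4: 20.0}

MRI_BACKGROUND = 5.0
CT_BACKGROUND = -1000.0  # air


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    ``intensity_table`` maps class id (1..4) to the class mean intensity (HU
    for CT, arbitrary units for MRI); ``t2_table`` maps class id to T2 in
    milliseconds (MRI only).  ``noise_sigma`` is the scale of additive
    Gaussian noise; ``t2_jitter`` likewise for the T2 map.
    """

    height: int = 128
    width: int = 128
    modality: Modality = "mri"
    n_structures: int = N_CLASSES
    intensity_table: dict[int, float] | None = None
    t2_table: dict[int, float] | None = None
    noise_sigma: float = 5.0
    t2_jitter: float = 0.0
    pixel_spacing: float = 0.5
    slice_thickness: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 64 or self.width < 64:
            raise ValueError(f"phantom must be at least 64x64, got {self.height}x{self.width}")
        if self.modality not in ("mri", "ct"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_structures != N_CLASSES:
            raise ValueError(f"exactly {N_CLASSES} foreground classes are supported")
        if self.modality != "mri" and self.t2_table is not None:
            raise ValueError("t2_table is only meaningful for MRI phantoms")
        if set(self.intensities) != set(range(1, N_CLASSES + 1)):
            raise ValueError("intensity_table must map classes 1..4")
        if self.modality == "mri" and set(self.t2s) != set(range(1, N_CLASSES + 1)):
            raise ValueError("t2_table must map classes 1..4")
        if self.modality == "ct":
            for cls, hu in self.intensities.items():
                if not (HU_MIN <= hu <= HU_MAX):
                    raise ValueError(f"class {cls} HU {hu} outside [{HU_MIN}, {HU_MAX}]")
        if self.noise_sigma < 0 or self.t2_jitter < 0:
            raise ValueError("noise scales must be >= 0")

    @property
    def intensities(self) -> dict[int, float]:
        if self.intensity_table is not None:
            return self.intensity_table
        return MRI_INTENSITY if self.modality == "mri" else CT_INTENSITY

    @property
    def t2s(self) -> dict[int, float] | None:
        if self.modality != "mri":
            return None
        return self.t2_table if self.t2_table is not None else MRI_T2

    @property
    def background(self) -> float:
        return MRI_BACKGROUND if self.modality == "mri" else CT_BACKGROUND


@dataclass
class Sample:
    """One phantom slice: image, labels, optional T2 map, spatial metadata."""

    image: np.ndarray
    label_map: np.ndarray
    t2_map: np.ndarray | None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape != self.label_map.shape:
            raise ValueError("image and label_map must share dimensions")
        if self.t2_map is not None and self.t2_map.shape != self.image.shape:
            raise ValueError("t2_map must share image dimensions")


class PlacementError(RuntimeError):
    """Raised when a structure cannot be placed after bounded retries."""


MIN_CLASS_FRACTION = 0.005  # each class occupies at least 0.5% of pixels


def _ellipse_mask(h, w, cr, cc, ar, ac, inner: float = 0.0) -> np.ndarray:
    rr, cc_grid = np.mgrid[0:h, 0:w]
    d2 = ((rr - cr) / ar) ** 2 + ((cc_grid - cc) / ac) ** 2
    mask = d2 <= 1.0
    if inner > 0:
        mask &= d2 > inner**2
    return mask


def generate_sample(spec: PhantomSpec, index: int) -> Sample:
    """Generate one phantom slice, deterministic given ``(spec.seed, index)``.

    Classes 1..4 sit in the four image quadrants; class 4 is rendered as an
    annulus.  In the noiseless image the per-class mean intensity equals the
    ``intensity_table`` entry exactly.
    """
    rng = np.random.default_rng([spec.seed, int(index)])
    h, w = spec.height, spec.width
    label = np.zeros((h, w), dtype=np.uint8)
    quads = [(0, 0), (0, 1), (1, 0), (1, 1)]
    qh, qw = h // 2, w // 2
    min_px = MIN_CLASS_FRACTION * h * w
    for cls, (qr, qc) in zip(range(1, N_CLASSES + 1), quads):
        placed = False
        for _ in range(50):
            ar = rng.uniform(0.16, 0.30) * qh
            ac = rng.uniform(0.16, 0.30) * qw
            # jitter the center but keep the ellipse strictly inside its quadrant
            cr = qr * qh + qh / 2 + rng.uniform(-1, 1) * (qh / 2 - ar - 2)
            cc = qc * qw + qw / 2 + rng.uniform(-1, 1) * (qw / 2 - ac - 2)
            inner = 0.5 if cls == 4 else 0.0
            mask = _ellipse_mask(h, w, cr, cc, ar, ac, inner)
            if mask.sum() >= min_px:
                label[mask] = cls
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place structure for class {cls} above "
                f"{MIN_CLASS_FRACTION:.1%} area after bounded retries"
            )
    image = np.full((h, w), spec.background, dtype=np.float32)
    for cls, mean in spec.intensities.items():
        image[label == cls] = mean
    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma, size=(h, w)).astype(np.float32)
    t2_map = None
    if spec.modality == "mri":
        t2_map = np.zeros((h, w), dtype=np.float32)
        for cls, t2 in spec.t2s.items():
            t2_map[label == cls] = t2
        if spec.t2_jitter > 0:
            jitter = rng.normal(0, spec.t2_jitter, size=(h, w)).astype(np.float32)
            t2_map = np.where(label > 0, t2_map + jitter, t2_map)
    meta = {
        "id": f"phantom_{index:04d}",
        "index": int(index),
        "modality": spec.modality,
        "pixel_spacing": spec.pixel_spacing,
        "slice_thickness": spec.slice_thickness,
    }
    return Sample(image.astype(np.float32), label, t2_map, meta)


# ---------------------------------------------------------------------------
# on-disk datasets
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "id", "split", "image_path", "label_path", "t2_path",
    "pixel_spacing_mm", "slice_thickness_mm", "modality",
]


def _write_nifti(arr: np.ndarray, path: Path, spacing: float, thickness: float) -> None:
    import nibabel as nib

    affine = np.diag([spacing, spacing, thickness, 1.0])
    nib.save(nib.Nifti1Image(arr[..., None], affine), str(path))


def _read_nifti(path: Path) -> np.ndarray:
    import nibabel as nib

    data = np.asanyarray(nib.load(str(path)).dataobj)
    return data[..., 0] if data.ndim == 3 else data


def _write_png16(arr: np.ndarray, path: Path) -> None:
    """16-bit PNG plus a JSON sidecar with the affine scale for inversion."""
    import imageio.v3 as iio

    lo, hi = float(arr.min()), float(arr.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    quant = np.round((arr - lo) / slope).astype(np.uint16)
    iio.imwrite(path, quant)
    path.with_suffix(".json").write_text(json.dumps({"offset": lo, "slope": slope}))


def _read_png16(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    raw = iio.imread(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        scale = json.loads(sidecar.read_text())
        return raw.astype(np.float32) * scale["slope"] + scale["offset"]
    return np.asarray(raw)


def generate_dataset(
    spec: PhantomSpec,
    n_labeled: int,
    n_unlabeled: int,
    out_dir,
    fmt: Literal["nifti", "png16"] = "nifti",
) -> pd.DataFrame:
    """Write a phantom dataset (images, labels, T2 maps, CSV manifest) to disk.

    Labeled samples use indices ``0..n_labeled-1``, unlabeled continue after
    them; re-running with the same spec reproduces identical grids.  Returns
    the manifest; paths are relative to ``out_dir``.
    """
    if n_labeled < 0 or n_unlabeled < 0:
        raise ValueError("sample counts must be >= 0")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if fmt == "nifti" else ".png"
    rows = []
    for i in range(n_labeled + n_unlabeled):
        labeled = i < n_labeled
        sample = generate_sample(spec, i)
        sid = sample.metadata["id"]
        img_rel = f"{sid}_image{ext}"
        if fmt == "nifti":
            _write_nifti(sample.image, out / img_rel, spec.pixel_spacing, spec.slice_thickness)
        else:
            _write_png16(sample.image, out / img_rel)
        lbl_rel = t2_rel = ""
        if labeled:
            lbl_rel = f"{sid}_label{ext}"
            if fmt == "nifti":
                _write_nifti(sample.label_map.astype(np.uint8), out / lbl_rel,
                             spec.pixel_spacing, spec.slice_thickness)
            else:
                import imageio.v3 as iio

                iio.imwrite(out / lbl_rel, sample.label_map.astype(np.uint8))
            if sample.t2_map is not None:
                t2_rel = f"{sid}_t2{ext}"
                if fmt == "nifti":
                    _write_nifti(sample.t2_map, out / t2_rel,
                                 spec.pixel_spacing, spec.slice_thickness)
                else:
                    _write_png16(sample.t2_map, out / t2_rel)
        rows.append({
            "id": sid,
            "split": "labeled" if labeled else "unlabeled",
            "image_path": img_rel,
            "label_path": lbl_rel,
            "t2_path": t2_rel,
            "pixel_spacing_mm": spec.pixel_spacing,
            "slice_thickness_mm": spec.slice_thickness,
            "modality": spec.modality,
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_manifest(manifest_path) -> pd.DataFrame:
    df = pd.read_csv(manifest_path, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    return df


def load_dataset(manifest_path) -> list[Sample]:
    """Read a dataset written by :func:`generate_dataset` back into memory."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    samples = []
    for _, row in load_manifest(manifest_path).iterrows():

        def read(rel):
            p = root / rel
            if rel.endswith(".nii.gz"):
                return _read_nifti(p)
            return _read_png16(p)

        image = np.asarray(read(row["image_path"]), dtype=np.float32)
        label = t2 = None
        if row["label_path"]:
            label = np.asarray(read(row["label_path"])).astype(np.uint8)
        if row["t2_path"]:
            t2 = np.asarray(read(row["t2_path"]), dtype=np.float32)
        samples.append(Sample(
            image,
            label if label is not None else np.zeros_like(image, dtype=np.uint8),
            t2,
            {
                "id": row["id"],
                "split": row["split"],
                "modality": row["modality"],
                "pixel_spacing": float(row["pixel_spacing_mm"]),
                "slice_thickness": float(row["slice_thickness_mm"]),
            },
        ))
    return samples
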