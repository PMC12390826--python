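"""Volume loading, 2D slicing, manifests, patient-level splits, augmentation.

3D MRI volumes (NIfTI files or DICOM series) are cut into 2D slices along
the first voxel axis; each slice is resized to a square target (default
256x256), min-max scaled to [0,1] and written as a 16-bit grayscale PNG.
Slices that are entirely zero (empty field of view) are dropped and logged.
The manifest is a plain CSV (patient_id, slice_index, label, path, split);
splitting is patient-grouped by default so no patient's slices leak across
the train/validation/test boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.transform import resize

logger = logging.getLogger(__name__)

LABELS = ("favourable", "poor")
SPLITS = ("train", "val", "test")


@dataclass
class VolumeMeta:
    patient_id: str
    shape: tuple[int, int, int]
    source_format: str  # "nifti" | "dicom"
    label: str | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass
class SliceRecord:
    patient_id: str
    slice_index: int
    label: str
    path: str
    split: str = "unassigned"


@dataclass
class SplitSpec:
    """Fractions of patients (or slices) per split; must sum to one."""
    train: float = 0.70
    val: float = 0.10
    test: float = 0.20
    unit: str = "patient"
    seed: int = 0

    def __post_init__(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.unit not in ("patient", "slice"):
            raise ValueError("split unit must be 'patient' or 'slice'")


def load_volume(path, patient_id: str | None = None,
                label: str | None = None) -> tuple[np.ndarray, VolumeMeta]:
    """Load a NIfTI file or a DICOM series directory as a voxel array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    if path.is_dir():
        return _load_dicom_series(path, patient_id, label)
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.get_fdata(), dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {vol.shape}")
    pid = patient_id or path.name.split(".")[0]
    meta = VolumeMeta(pid, tuple(vol.shape), "nifti", label)
    return vol, meta


def _load_dicom_series(directory: Path, patient_id, label):
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix == ".dcm")
    if not files:
        raise ValueError(f"no DICOM files in {directory}")
    slices = []
    for f in files:
        ds = pydicom.dcmread(str(f))
        slices.append((int(ds.InstanceNumber), ds.pixel_array.astype(np.float64)))
    slices.sort(key=lambda t: t[0])
    numbers = [n for n, _ in slices]
    expected = range(numbers[0], numbers[-1] + 1)
    missing = sorted(set(expected) - set(numbers))
    if missing:
        raise ValueError(
            f"DICOM series {directory} has gaps in instance numbers; "
            f"missing instances: {missing}")
    vol = np.stack([arr for _, arr in slices], axis=0)
    pid = patient_id or directory.name
    meta = VolumeMeta(pid, tuple(vol.shape), "dicom", label)
    return vol, meta


def _prepare_slice(sl: np.ndarray, size: int) -> np.ndarray:
    """Resize to (size, size), min-max scale to [0,1], as float64."""
    if sl.shape != (size, size):
        sl = resize(sl, (size, size), order=1, mode="reflect",
                    anti_aliasing=False, preserve_range=True)
    lo, hi = float(sl.min()), float(sl.max())
    if hi > lo:
        sl = (sl - lo) / (hi - lo)
    else:
        sl = np.zeros_like(sl)
    return sl


def write_slice_png(image01: np.ndarray, path) -> None:
    """Write a [0,1] image as a 16-bit grayscale PNG."""
    arr = np.round(np.clip(image01, 0.0, 1.0) * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(str(path))


def read_slice_png(path) -> np.ndarray:
    """Read a 16-bit grayscale PNG back to a [0,1] float array."""
    arr = np.asarray(Image.open(str(path)), dtype=np.float64)
    return arr / 65535.0


def slice_volume(vol: np.ndarray, meta: VolumeMeta, out_dir, axis: int = 0,
                 size: int = 256, drop_empty: bool = True) -> list[SliceRecord]:
    """Cut a volume into labelled 2D slices written as 16-bit PNGs."""
    if meta.label is None:
        raise ValueError(f"patient {meta.patient_id} has no prognosis label")
    if vol.shape[axis] == 0:
        raise ValueError("slicing axis has length 0")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol = np.moveaxis(vol, axis, 0)
    records: list[SliceRecord] = []
    n_dropped = 0
    for idx in range(vol.shape[0]):
        sl = vol[idx]
        if drop_empty and not np.any(sl):
            n_dropped += 1
            continue
        img = _prepare_slice(sl, size)
        path = out_dir / f"{meta.patient_id}_{idx:04d}.png"
        write_slice_png(img, path)
        records.append(SliceRecord(meta.patient_id, idx, meta.label,
                                   str(path)))
    if n_dropped:
        logger.info("dropped %d all-zero slices from patient %s",
                    n_dropped, meta.patient_id)
    return records


MANIFEST_COLUMNS = ["patient_id", "slice_index", "label", "path", "split"]


def build_manifest(records: list[SliceRecord]) -> pd.DataFrame:
    if not records:
        raise ValueError("cannot build a manifest from zero slice records")
    df = pd.DataFrame([vars(r) for r in records], columns=MANIFEST_COLUMNS)
    dupes = df.duplicated(subset=["patient_id", "slice_index"])
    if dupes.any():
        keys = df.loc[dupes, ["patient_id", "slice_index"]].values.tolist()
        raise ValueError(f"duplicate (patient_id, slice_index) keys: {keys}")
    return df


def manifest_summary(manifest: pd.DataFrame) -> pd.DataFrame:
    """Totals per split and per class, plus grand totals."""
    table = manifest.pivot_table(index="label", columns="split",
                                 values="path", aggfunc="count",
                                 fill_value=0)
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table.astype(int)


def write_manifest(manifest: pd.DataFrame, path, summary_path=None) -> None:
    manifest.to_csv(path, index=False)
    if summary_path is not None:
        manifest_summary(manifest).to_csv(summary_path)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    return df


def _apportion(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Integer counts per split by largest remainder; sums to n."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in range(remainder):
        counts[order[i]] += 1
    return counts


def split_dataset(manifest: pd.DataFrame, spec: SplitSpec) -> pd.DataFrame:
    """Fill the manifest's split column with a seeded 70/10/20 partition.

    With ``unit='patient'`` every slice of a patient lands in the same
    split, so patient counts (not slice counts) follow the fractions.
    """
    manifest = manifest.copy()
    rng = np.random.default_rng(spec.seed)
    fractions = (spec.train, spec.val, spec.test)
    if spec.unit == "patient":
        patients = sorted(manifest["patient_id"].unique())
        if len(patients) < 3:
            raise ValueError(
                f"need at least 3 patients for a 3-way split, "
                f"got {len(patients)}")
        perm = rng.permutation(len(patients))
        counts = _apportion(len(patients), fractions)
        assignment: dict[str, str] = {}
        start = 0
        for split_name, count in zip(SPLITS, counts):
            for j in perm[start:start + count]:
                assignment[patients[j]] = split_name
            start += count
        manifest["split"] = manifest["patient_id"].map(assignment)
    else:
        n = len(manifest)
        if n < 3:
            raise ValueError("need at least 3 slices for a 3-way split")
        perm = rng.permutation(n)
        counts = _apportion(n, fractions)
        labels = np.empty(n, dtype=object)
        start = 0
        for split_name, count in zip(SPLITS, counts):
            labels[perm[start:start + count]] = split_name
            start += count
        manifest["split"] = labels
    return manifest


@dataclass
class AugmentConfig:
    """The augmentation family: rotation, horizontal flip, photometric
    jitter.  Saturation and hue factors are drawn but act as identities on
    single-channel images."""
    rotation_deg: float = 15.0
    flip_prob: float = 0.5
    jitter: float = 0.2
    hue: float = 0.05


def augment_slice(image: np.ndarray, seed: int,
                  cfg: AugmentConfig | None = None) -> np.ndarray:
    """Seeded augmentation of a [0,1] grayscale slice; shape preserved."""
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=np.float64)
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    do_flip = rng.random() < cfg.flip_prob
    brightness = rng.uniform(1 - cfg.jitter, 1 + cfg.jitter)
    contrast = rng.uniform(1 - cfg.jitter, 1 + cfg.jitter)
    _saturation = rng.uniform(1 - cfg.jitter, 1 + cfg.jitter)  # identity: 1ch
    _hue = rng.uniform(-cfg.hue, cfg.hue)                      # identity: 1ch
    if angle != 0.0:
        out = ndimage.rotate(out, angle, reshape=False, order=1,
                             mode="nearest")
    if do_flip:
        out = out[:, ::-1]
    out = out * brightness
    out = out.mean() + (out - out.mean()) * contrast
    return np.clip(out, 0.0, 1.0)
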