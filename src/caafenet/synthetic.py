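"""Seeded synthetic MRI-like slice generator for end-to-end testing.

Two classes of grayscale square slices emulate the *structure* of the real
task (class imbalance, per-patient volumes, multiscale class-discriminative
texture) without claiming anatomical realism:

* class 0 ("favourable"): a smooth, low-contrast background field with a
  faint broad bump;
* class 1 ("poor"): the same background plus an irregular high-intensity
  blob carrying mixed coarse and fine texture, so the discriminative signal
  lives at more than one spatial scale and exercises the dilated branches.

Everything is reproducible bit-for-bit from (config, seed): per-patient
random generators are derived with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import SliceRecord, build_manifest, slice_volume, VolumeMeta

FAVOURABLE_FRACTION = 407.0 / 1477.0  # observed slice-level class balance


@dataclass
class SynthConfig:
    n_patients: int = 24
    slices_per_patient: int = 8
    image_size: int = 64
    favourable_fraction: float = FAVOURABLE_FRACTION
    coarse_radius_frac: float = 0.20   # blob radius as a fraction of the side
    fine_sigma: float = 1.0            # pixels; fine-texture scale
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.favourable_fraction < 1.0:
            raise ValueError("favourable_fraction must lie in (0, 1)")
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")


def _background(size: int, rng: np.random.Generator) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.normal(size=(size, size)),
                                    sigma=size / 8.0)
    span = field.max() - field.min()
    if span > 0:
        field = (field - field.min()) / span - 0.5
    return 0.35 + 0.05 * field


def _disc_mask(size: int, centre, radius: float,
               rng: np.random.Generator) -> np.ndarray:
    """A disc with a wobbly (irregular) edge."""
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - centre[0], xx - centre[1])
    wobble = ndimage.gaussian_filter(rng.normal(size=(size, size)),
                                     sigma=size / 16.0)
    return r < radius * (1.0 + 0.25 * wobble)


def generate_slice(class_label: int, cfg: SynthConfig,
                   rng: np.random.Generator | int) -> np.ndarray:
    """One [0,1] grayscale slice of the requested class."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    size = cfg.image_size
    img = _background(size, rng)
    centre = rng.uniform(0.3 * size, 0.7 * size, size=2)
    if class_label == 0:
        # faint smooth bump: low contrast, no sharp edges
        yy, xx = np.mgrid[0:size, 0:size]
        r2 = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2
        img = img + 0.08 * np.exp(-r2 / (2 * (size / 5.0) ** 2))
    elif class_label == 1:
        mask = _disc_mask(size, centre, cfg.coarse_radius_frac * size, rng)
        img = np.where(mask, 0.90, img)
        fine = ndimage.gaussian_filter(rng.normal(size=(size, size)),
                                       sigma=cfg.fine_sigma)
        img = img + np.where(mask, 0.08 * fine / max(fine.std(), 1e-9), 0.0)
    else:
        raise ValueError(f"class_label must be 0 or 1, got {class_label}")
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=(size, size))
    return np.clip(img, 0.0, 1.0)


def patient_labels(cfg: SynthConfig) -> list[int]:
    """Deterministic class assignment: favourable patients first."""
    n_fav = int(round(cfg.n_patients * cfg.favourable_fraction))
    if n_fav == 0 or n_fav == cfg.n_patients:
        raise ValueError(
            f"favourable_fraction {cfg.favourable_fraction} leaves a class "
            f"empty with {cfg.n_patients} patients")
    return [0] * n_fav + [1] * (cfg.n_patients - n_fav)


def generate_volume(patient_idx: int, class_label: int,
                    cfg: SynthConfig) -> np.ndarray:
    """A (slices, size, size) volume for one synthetic patient."""
    seq = np.random.SeedSequence([cfg.seed, patient_idx])
    rng = np.random.default_rng(seq)
    return np.stack([
        generate_slice(class_label, cfg, rng)
        for _ in range(cfg.slices_per_patient)
    ])


def generate_arrays(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """All slices in memory: (N,1,H,W) float32 images, labels, patient ids."""
    images, labels, pids = [], [], []
    for idx, lab in enumerate(patient_labels(cfg)):
        vol = generate_volume(idx, lab, cfg)
        for sl in vol:
            images.append(sl[None].astype(np.float32))
            labels.append(lab)
            pids.append(f"synth{idx:03d}")
    return np.stack(images), np.asarray(labels), pids


def generate_dataset(cfg: SynthConfig, out_dir):
    """Write per-patient NIfTI volumes plus a sliced PNG dataset + manifest.

    Returns the manifest DataFrame (split column unassigned).
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    vol_dir = out_dir / "volumes"
    png_dir = out_dir / "slices"
    vol_dir.mkdir(parents=True, exist_ok=True)
    records: list[SliceRecord] = []
    label_names = {0: "favourable", 1: "poor"}
    for idx, lab in enumerate(patient_labels(cfg)):
        vol = generate_volume(idx, lab, cfg)
        pid = f"synth{idx:03d}"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), np.eye(4)),
                 str(vol_dir / f"{pid}.nii.gz"))
        meta = VolumeMeta(pid, tuple(vol.shape), "nifti", label_names[lab])
        records.extend(slice_volume(vol, meta, png_dir, axis=0,
                                    size=cfg.image_size))
    return build_manifest(records)
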