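"""Synthetic neck-CT phantoms with known thyroid and nodule ground truth.

The phantom emulates the appearance an axial neck CT presents to a
segmentation network at desk scale: a bilobed thyroid (two ellipsoidal
lobes joined by an anterior isthmus bridge) brighter than the soft-tissue
background, a dark air-filled tracheal tube between the lobes, optional
hypodense nodules inside the gland, and additive Gaussian noise.  It does
not attempt HU calibration or contrast-media kinetics; only relative
contrast matters for exercising the pipeline.

Geometry is expressed in mm in a coordinate frame centered in-plane on the
volume, with ``x`` across columns (left-right), ``y`` across rows
(anterior-posterior) and ``z`` along slices.  The default grid is
64 x 64 x 40 voxels at 0.9 mm pixel spacing and 2.5 mm slice thickness,
giving an adult-scale gland of roughly 40 x 25 x 30 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path


import numpy as np

from .io import CTVolume, MaskVolume, save_mask, save_volume, split_dataset

__all__ = ["PhantomSpec", "Nodule", "generate_phantom", "generate_cohort", "save_cohort"]


@dataclass(frozen=True)
class Nodule:
    """A spherical lesion: center offset from the volume center in mm."""

    center_mm: tuple[float, float, float]  # (z, y, x) offset
    radius_mm: float
    label: str = "tumor"

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ValueError("nodule radius must be > 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom; all lengths in mm.

    ``lobe_semi_axes_mm`` are the (x, y, z) semi-axes of each ellipsoidal
    lobe; the two lobes are mirrored about the midline at ``±lobe_offset_mm``
    across columns.  Intensities are on a normalized 0-1 scale.
    """

    shape: tuple[int, int, int] = (40, 64, 64)  # (slices, rows, cols)
    pixel_spacing_mm: float = 0.9
    slice_thickness_mm: float = 2.5
    lobe_semi_axes_mm: tuple[float, float, float] = (8.0, 11.0, 15.0)
    lobe_offset_mm: float = 11.0
    isthmus_radius_mm: float = 4.0
    isthmus_anterior_mm: float = 7.0  # y offset of isthmus axis (towards the front)
    trachea_radius_mm: float = 7.0
    nodules: tuple[Nodule, ...] = ()
    background_intensity: float = 0.30
    thyroid_intensity: float = 0.65
    trachea_intensity: float = 0.08
    nodule_intensity: float = 0.45
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.lobe_semi_axes_mm) <= 0 or self.isthmus_radius_mm < 0:
            raise ValueError("all phantom lengths must be > 0 (isthmus radius 0 omits it)")
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("spacings must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _grid_mm(spec: PhantomSpec):
    """Voxel-center coordinates (z, y, x) in mm, origin at the volume center."""
    ns, nr, nc = spec.shape
    z = (np.arange(ns) - (ns - 1) / 2.0) * spec.slice_thickness_mm
    y = (np.arange(nr) - (nr - 1) / 2.0) * spec.pixel_spacing_mm
    x = (np.arange(nc) - (nc - 1) / 2.0) * spec.pixel_spacing_mm
    return np.meshgrid(z, y, x, indexing="ij")


def _gland_inside(spec: PhantomSpec, zz, yy, xx):
    """Boolean inside-test of (lobes ∪ isthmus) on the mm grid."""
    ax, ay, az = spec.lobe_semi_axes_mm
    left = ((xx + spec.lobe_offset_mm) / ax) ** 2 + (yy / ay) ** 2 + (zz / az) ** 2 <= 1.0
    right = ((xx - spec.lobe_offset_mm) / ax) ** 2 + (yy / ay) ** 2 + (zz / az) ** 2 <= 1.0
    # isthmus: a cylinder along x bridging the lobes, anterior to the trachea;
    # radius 0 means no isthmus (two disconnected lobes)
    r = spec.isthmus_radius_mm
    if r <= 0:
        return left | right
    isth = (
        ((yy - spec.isthmus_anterior_mm) ** 2 + zz**2 <= r**2)
        & (np.abs(xx) <= spec.lobe_offset_mm)
    )
    return left | right | isth


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, MaskVolume, list[Nodule]]:
    """Render one phantom: CT-like image, thyroid ground-truth mask, nodules.

    The mask is the voxelized (lobes ∪ isthmus); nodules must lie inside one
    of the lobes and are rendered with their own intensity but are *not*
    part of the thyroid mask (they are separate tumor-material metadata).
    Identical specs (same seed) produce bit-identical volumes.
    """
    zz, yy, xx = _grid_mm(spec)
    gland = _gland_inside(spec, zz, yy, xx)

    img = np.full(spec.shape, spec.background_intensity, dtype=np.float32)
    # dark tracheal tube along z at the midline, posterior to the isthmus
    trachea = (xx**2 + (yy + 2.0) ** 2) <= spec.trachea_radius_mm**2
    img[trachea & ~gland] = spec.trachea_intensity
    img[gland] = spec.thyroid_intensity

    ax, ay, az = spec.lobe_semi_axes_mm
    for nod in spec.nodules:
        cz, cy, cx = nod.center_mm
        in_left = ((cx + spec.lobe_offset_mm) / ax) ** 2 + (cy / ay) ** 2 + (cz / az) ** 2 <= 1.0
        in_right = ((cx - spec.lobe_offset_mm) / ax) ** 2 + (cy / ay) ** 2 + (cz / az) ** 2 <= 1.0
        if not (in_left or in_right):
            raise ValueError(f"nodule center {nod.center_mm} lies outside both lobes")
        ball = ((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= nod.radius_mm**2
        img[ball & gland] = spec.nodule_intensity

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    volume = CTVolume(img, spec.pixel_spacing_mm, spec.slice_thickness_mm, (0.0, 1.0))
    mask = MaskVolume(
        gland.astype(np.uint8), spec.pixel_spacing_mm, spec.slice_thickness_mm, "thyroid"
    )
    return volume, mask, list(spec.nodules)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: spec fields that may be jittered per phantom, with their default ranges
DEFAULT_JITTER: dict[str, tuple[float, float]] = {
    "lobe_ax": (0.85, 1.15),       # multiplicative, x semi-axis
    "lobe_ay": (0.85, 1.15),
    "lobe_az": (0.85, 1.15),
    "lobe_offset_mm": (10.0, 12.5),
    "isthmus_radius_mm": (3.0, 5.0),
    "noise_sd": (0.04, 0.07),
}


@dataclass
class Cohort:
    """A generated phantom dataset with its train/validation/test split."""

    specs: list[PhantomSpec]
    volumes: list[CTVolume]
    masks: list[MaskVolume]
    split: dict[str, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.specs)

    def members(self, subset: str) -> list[tuple[CTVolume, MaskVolume]]:
        return [(self.volumes[i], self.masks[i]) for i in self.split[subset]]


def _jittered_spec(base: PhantomSpec, jitter: dict, rng: np.random.Generator, seed: int) -> PhantomSpec:
    ax, ay, az = base.lobe_semi_axes_mm
    kwargs: dict = {"seed": seed}
    for key, (lo, hi) in jitter.items():
        if hi < lo:
            raise ValueError(f"jitter range for {key} is empty: ({lo}, {hi})")
        val = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        if key == "lobe_ax":
            ax = base.lobe_semi_axes_mm[0] * val
        elif key == "lobe_ay":
            ay = base.lobe_semi_axes_mm[1] * val
        elif key == "lobe_az":
            az = base.lobe_semi_axes_mm[2] * val
        elif hasattr(base, key):
            kwargs[key] = val
        else:
            raise ValueError(f"unknown jitter parameter {key!r}")
    kwargs["lobe_semi_axes_mm"] = (ax, ay, az)
    return replace(base, **kwargs)


def generate_cohort(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    ratio: tuple[int, int, int] = (3, 1, 1),
) -> Cohort:
    """Generate ``n`` phantoms with per-phantom jittered specs + random split.

    ``jitter`` maps spec parameters to uniform ranges (``lobe_a{x,y,z}`` are
    multiplicative factors on the base semi-axes); an equal-bounds range
    pins the parameter.  Pass ``jitter={}`` for ``n`` identical geometries
    (noise still differs through per-phantom seeds).  ``ratio`` is the
    train:validation:test proportion (default 3:1:1; 4:1:1 gives the
    40/10/10 split of a 60-phantom cohort).  Reproducible under ``seed``.
    """
    if n < 5:
        raise ValueError("cohort needs n >= 5 for a 3:1:1 split")
    if base_spec is None:
        base_spec = PhantomSpec()
    if jitter is None:
        jitter = dict(DEFAULT_JITTER)
    rng = np.random.default_rng(seed)
    specs, volumes, masks = [], [], []
    for i in range(n):
        sub = int(rng.integers(0, 2**31 - 1))
        spec_i = _jittered_spec(base_spec, jitter, rng, seed=sub)
        specs.append(spec_i)
        vol, mask, _ = generate_phantom(spec_i)
        volumes.append(vol)
        masks.append(mask)
    train, val, test = split_dataset(list(range(n)), seed=seed, ratio=ratio)
    return Cohort(specs, volumes, masks, {"train": train, "validation": val, "test": test})


def save_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort as PNG-stack volumes/masks plus a manifest CSV."""
    import csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    member_split = {}
    for name, idxs in cohort.split.items():
        for i in idxs:
            member_split[i] = name
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["id", "split", "lobe_ax_mm", "lobe_ay_mm", "lobe_az_mm",
             "lobe_offset_mm", "isthmus_radius_mm", "noise_sd", "seed"]
        )
        for i, spec in enumerate(cohort.specs):
            case = f"case_{i:03d}"
            save_volume(cohort.volumes[i], directory / case / "image")
            save_mask(cohort.masks[i], directory / case / "mask")
            ax, ay, az = spec.lobe_semi_axes_mm
            writer.writerow(
                [case, member_split[i], f"{ax:.3f}", f"{ay:.3f}", f"{az:.3f}",
                 f"{spec.lobe_offset_mm:.3f}", f"{spec.isthmus_radius_mm:.3f}",
                 f"{spec.noise_sd:.4f}", spec.seed]
            )
    return directory
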