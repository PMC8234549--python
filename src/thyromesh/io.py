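"""Volume, mask and annotation I/O for the thyroid-model pipeline.

Conventions
-----------
* Voxel arrays are indexed ``(slice, row, col)``, 0-based, with pixel centers
  at integer coordinates.
* Axial CT-like sources are single-channel grayscale.  Source images are
  conventionally 512x512 and are center-cropped to 256x256 before entering
  the segmentation network (desk-scale phantoms use smaller grids).
* The portable on-disk format is a PNG stack (one 8-bit grayscale PNG per
  slice) plus a ``meta.json`` sidecar carrying ``pixel_spacing_mm`` and
  ``slice_thickness_mm``.  DICOM series (uncompressed grayscale) are read,
  never written.
* Masks are stored 0/255 on disk and 0/1 in memory.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

__all__ = [
    "CTVolume",
    "MaskVolume",
    "AnnotationSet",
    "VolumeFormatError",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "load_annotations",
    "center_crop",
    "polygons_to_mask",
    "split_dataset",
]


class VolumeFormatError(ValueError):
    """Raised for malformed volume sources (ragged slices, missing metadata)."""


@dataclass
class CTVolume:
    """A 3-D grayscale voxel grid with physical spacing metadata.

    ``voxels`` is ``(slices, rows, cols)`` float32; ``intensity_range``
    declares the min/max of the stored scale (``(0, 255)`` for 8-bit stacks,
    ``(0, 1)`` for normalized synthetic volumes).
    """

    voxels: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float
    intensity_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"voxels must be 3-D (slices, rows, cols); got ndim={self.voxels.ndim}"
            )
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise VolumeFormatError("pixel spacing and slice thickness must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def physical_extent_mm(self) -> tuple[float, float, float]:
        """(z, y, x) physical size of the voxel grid in mm."""
        s, r, c = self.voxels.shape
        return (
            s * self.slice_thickness_mm,
            r * self.pixel_spacing_mm,
            c * self.pixel_spacing_mm,
        )

    def normalized(self) -> np.ndarray:
        """Voxels rescaled to [0, 1] using the declared intensity range."""
        lo, hi = self.intensity_range
        if hi <= lo:
            return np.zeros_like(self.voxels)
        return (self.voxels - lo) / (hi - lo)


@dataclass
class MaskVolume:
    """Binary voxel grid aligned with a :class:`CTVolume`."""

    voxels: np.ndarray
    pixel_spacing_mm: float
    slice_thickness_mm: float
    label: str = "thyroid"

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise VolumeFormatError("mask voxels must be 3-D (slices, rows, cols)")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeFormatError(f"mask values must be in {{0, 1}}; got {vals[:8]}")
        self.voxels = arr.astype(np.uint8)
        if self.pixel_spacing_mm <= 0 or self.slice_thickness_mm <= 0:
            raise VolumeFormatError("pixel spacing and slice thickness must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.pixel_spacing_mm**2 * self.slice_thickness_mm


@dataclass
class AnnotationSet:
    """Per-slice closed polygons (labelme-style), vertices in (row, col) pixels."""

    # polygons[slice_index] -> list of (label, vertices[N,2]) tuples
    polygons: dict[int, list[tuple[str, np.ndarray]]] = field(default_factory=dict)

    def add(self, slice_index: int, vertices: Sequence[Sequence[float]], label: str = "thyroid") -> None:
        verts = np.asarray(vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("polygon needs >=3 (row, col) vertices")
        self.polygons.setdefault(slice_index, []).append((label, verts))

    def __len__(self) -> int:
        return sum(len(v) for v in self.polygons.values())


# ---------------------------------------------------------------------------
# Loading and saving
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _numeric_sort(paths: list[Path]) -> list[Path]:
    def key(p: Path):
        nums = _NUM_RE.findall(p.stem)
        return (int(nums[-1]) if nums else -1, p.name)

    return sorted(paths, key=key)


def _load_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".dicom"))
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception as exc:  # non-DICOM stragglers in the directory
            raise VolumeFormatError(f"cannot read DICOM file {p.name}: {exc}") from exc
    if not datasets:
        raise VolumeFormatError(f"no DICOM slices found in {directory}")

    def z_of(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=z_of)
    shape0 = datasets[0].pixel_array.shape
    slices = []
    for i, ds in enumerate(datasets):
        arr = ds.pixel_array
        if arr.shape != shape0:
            raise VolumeFormatError(
                f"slice {i} has shape {arr.shape}, expected {shape0}"
            )
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr.astype(np.float32) * slope + intercept)
    ds0 = datasets[0]
    if not hasattr(ds0, "PixelSpacing"):
        raise VolumeFormatError("DICOM series lacks PixelSpacing")
    spacing = float(ds0.PixelSpacing[0])
    thickness = float(getattr(ds0, "SliceThickness", 0) or 0)
    if thickness <= 0:
        if len(datasets) > 1:
            thickness = abs(z_of(datasets[1]) - z_of(datasets[0]))
        else:
            raise VolumeFormatError("DICOM series lacks SliceThickness")
    vox = np.stack(slices)
    return CTVolume(vox, spacing, thickness, (float(vox.min()), float(vox.max())))


def _load_png_stack(
    directory: Path,
    pixel_spacing_mm: float | None,
    slice_thickness_mm: float | None,
) -> CTVolume:
    meta_path = directory / "meta.json"
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    spacing = pixel_spacing_mm if pixel_spacing_mm is not None else meta.get("pixel_spacing_mm")
    thickness = (
        slice_thickness_mm if slice_thickness_mm is not None else meta.get("slice_thickness_mm")
    )
    if spacing is None or thickness is None:
        raise VolumeFormatError(
            f"{directory}: pixel_spacing_mm / slice_thickness_mm not in meta.json "
            "and not supplied as overrides"
        )
    files = _numeric_sort([p for p in directory.glob("*.png")])
    if not files:
        raise VolumeFormatError(f"no PNG slices found in {directory}")
    slices = []
    shape0 = None
    for i, p in enumerate(files):
        arr = np.asarray(Image.open(p).convert("L"), dtype=np.float32)
        if shape0 is None:
            shape0 = arr.shape
        elif arr.shape != shape0:
            raise VolumeFormatError(f"slice {i} ({p.name}) has shape {arr.shape}, expected {shape0}")
        slices.append(arr)
    rng = tuple(meta.get("intensity_range", (0.0, 255.0)))
    return CTVolume(np.stack(slices), float(spacing), float(thickness), rng)


def load_volume(
    source: str | Path,
    *,
    pixel_spacing_mm: float | None = None,
    slice_thickness_mm: float | None = None,
) -> CTVolume:
    """Read a CT-like volume from a DICOM series directory or a PNG stack.

    A directory containing ``*.png`` (plus a ``meta.json`` sidecar, unless
    spacings are supplied as overrides) is read as an ordered grayscale
    stack; anything else is treated as a DICOM series.  Slices are ordered
    by axial position (DICOM) or numeric filename suffix (stack).
    """
    source = Path(source)
    if not source.is_dir():
        raise VolumeFormatError(f"{source} is not a directory")
    if any(source.glob("*.png")):
        return _load_png_stack(source, pixel_spacing_mm, slice_thickness_mm)
    return _load_dicom_series(source)


def save_volume(volume: CTVolume, directory: str | Path) -> Path:
    """Write a volume as an 8-bit grayscale PNG stack + ``meta.json``.

    Intensities are mapped to 8-bit through the declared intensity range
    (a full-range window), single channel retained; a volume already on the
    0-255 scale round-trips bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lo, hi = volume.intensity_range
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    for i, sl in enumerate(volume.voxels):
        arr = np.clip(np.round((sl - lo) * scale), 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / f"slice_{i:04d}.png")
    meta = {
        "pixel_spacing_mm": volume.pixel_spacing_mm,
        "slice_thickness_mm": volume.slice_thickness_mm,
        "intensity_range": [0.0, 255.0],
        "n_slices": int(volume.n_slices),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def save_mask(mask: MaskVolume, directory: str | Path) -> Path:
    """Write a binary mask as a 0/255 PNG stack + ``meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, sl in enumerate(mask.voxels):
        Image.fromarray((sl * 255).astype(np.uint8), mode="L").save(
            directory / f"slice_{i:04d}.png"
        )
    meta = {
        "pixel_spacing_mm": mask.pixel_spacing_mm,
        "slice_thickness_mm": mask.slice_thickness_mm,
        "label": mask.label,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def load_mask(directory: str | Path) -> MaskVolume:
    """Read a 0/255 PNG mask stack back to a 0/1 :class:`MaskVolume`."""
    vol = _load_png_stack(Path(directory), None, None)
    meta = json.loads((Path(directory) / "meta.json").read_text())
    return MaskVolume(
        (vol.voxels > 127).astype(np.uint8),
        vol.pixel_spacing_mm,
        vol.slice_thickness_mm,
        label=meta.get("label", "thyroid"),
    )


def load_annotations(path: str | Path) -> AnnotationSet:
    """Read labelme-style JSON polygon annotations.

    Accepts either one JSON file with ``{"slices": {"<idx>": [{"label":...,
    "points": [[x, y], ...]}, ...]}}`` or a directory of per-slice labelme
    files named ``*_<idx>.json`` each carrying a ``shapes`` list.  labelme
    points are (x, y) = (col, row); they are flipped to (row, col) here.
    """
    path = Path(path)
    ann = AnnotationSet()

    def add_shapes(idx: int, shapes: list[dict]) -> None:
        for shape in shapes:
            pts = np.asarray(shape["points"], dtype=float)[:, ::-1]  # (x,y)->(row,col)
            ann.add(idx, pts, label=shape.get("label", "thyroid"))

    if path.is_dir():
        for f in _numeric_sort(list(path.glob("*.json"))):
            nums = _NUM_RE.findall(f.stem)
            idx = int(nums[-1]) if nums else 0
            add_shapes(idx, json.loads(f.read_text()).get("shapes", []))
    else:
        data = json.loads(path.read_text())
        for key, shapes in data.get("slices", {}).items():
            add_shapes(int(key), shapes)
    return ann


# ---------------------------------------------------------------------------
# Geometry operations
# ---------------------------------------------------------------------------


def center_crop(volume: CTVolume, size: int) -> CTVolume:
    """Centered ``size x size`` in-plane window of every slice.

    For even sizes the window starts at ``(D - size) // 2`` on each axis
    (512 -> offset 128), so a 512x512 source maps pixel (128, 128) to (0, 0).
    Spacing metadata is unchanged.
    """
    _, rows, cols = volume.shape
    if size > rows or size > cols:
        raise ValueError(f"crop size {size} exceeds slice dimensions {(rows, cols)}")
    r0 = (rows - size) // 2
    c0 = (cols - size) // 2
    return CTVolume(
        volume.voxels[:, r0 : r0 + size, c0 : c0 + size].copy(),
        volume.pixel_spacing_mm,
        volume.slice_thickness_mm,
        volume.intensity_range,
    )


def center_crop_mask(mask: MaskVolume, size: int) -> MaskVolume:
    """The mask counterpart of :func:`center_crop` (same window arithmetic)."""
    _, rows, cols = mask.shape
    if size > rows or size > cols:
        raise ValueError(f"crop size {size} exceeds slice dimensions {(rows, cols)}")
    r0 = (rows - size) // 2
    c0 = (cols - size) // 2
    return MaskVolume(
        mask.voxels[:, r0 : r0 + size, c0 : c0 + size].copy(),
        mask.pixel_spacing_mm,
        mask.slice_thickness_mm,
        mask.label,
    )


_EDGE_TOL = 1e-9


def _rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boundary-inclusive polygon fill on a pixel grid.

    A pixel (integer center) is set when its center lies strictly inside the
    polygon (even-odd crossing rule) or exactly on an edge.  Vectorized over
    the polygon's bounding box; tests check it against a per-pixel
    point-in-polygon brute force.
    """
    out = np.zeros(shape, dtype=np.uint8)
    r_lo = max(int(math.floor(vertices[:, 0].min())), 0)
    r_hi = min(int(math.ceil(vertices[:, 0].max())), shape[0] - 1)
    c_lo = max(int(math.floor(vertices[:, 1].min())), 0)
    c_hi = min(int(math.ceil(vertices[:, 1].max())), shape[1] - 1)
    if r_hi < r_lo or c_hi < c_lo:
        return out
    pr, pc = np.meshgrid(
        np.arange(r_lo, r_hi + 1, dtype=float),
        np.arange(c_lo, c_hi + 1, dtype=float),
        indexing="ij",
    )
    inside = np.zeros(pr.shape, dtype=bool)
    on_edge = np.zeros(pr.shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        ar, ac = vertices[i]
        br, bc = vertices[(i + 1) % n]
        # on-segment test: zero cross product and projection within [0, |AB|^2]
        cross = (br - ar) * (pc - ac) - (bc - ac) * (pr - ar)
        dot = (pr - ar) * (br - ar) + (pc - ac) * (bc - ac)
        ab2 = (br - ar) ** 2 + (bc - ac) ** 2
        scale = max(ab2, 1.0)
        on_edge |= (np.abs(cross) <= _EDGE_TOL * scale) & (dot >= -_EDGE_TOL * scale) & (
            dot <= ab2 + _EDGE_TOL * scale
        )
        # even-odd crossing of the horizontal ray towards +col
        cond = (ar > pr) != (br > pr)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_int = ac + (pr - ar) * (bc - ac) / (br - ar)
        inside ^= cond & (pc < c_int)
    out[r_lo : r_hi + 1, c_lo : c_hi + 1] = (inside | on_edge).astype(np.uint8)
    return out


def polygons_to_mask(annotations: AnnotationSet, volume: CTVolume) -> MaskVolume:
    """Rasterize per-slice polygons to a binary mask aligned with ``volume``.

    Boundary-inclusive: pixels strictly inside or on a polygon edge become 1;
    overlapping polygons union.
    """
    n_slices, rows, cols = volume.shape
    vox = np.zeros((n_slices, rows, cols), dtype=np.uint8)
    for idx, shapes in annotations.polygons.items():
        if not 0 <= idx < n_slices:
            raise ValueError(f"annotation references slice {idx} outside volume ({n_slices} slices)")
        for _label, verts in shapes:
            if verts.shape[0] < 3:
                raise ValueError("polygon with <3 vertices")
            vox[idx] |= _rasterize_polygon(verts, (rows, cols))
    return MaskVolume(vox, volume.pixel_spacing_mm, volume.slice_thickness_mm)


def split_dataset(
    series_ids: Sequence, seed: int, ratio: tuple[int, int, int] = (3, 1, 1)
) -> tuple[list, list, list]:
    """Random 3:1:1 train/validation/test partition of series identifiers.

    Train and validation sizes are floored at ``n * r / sum(ratio)``; the
    remainder goes to the test set.  Deterministic under ``seed``; the
    partition is disjoint and exhaustive.
    """
    ids = list(series_ids)
    n = len(ids)
    if n < len(ratio) + 2:
        raise ValueError(f"need at least 5 series to split 3:1:1; got {n}")
    total = sum(ratio)
    n_train = n * ratio[0] // total
    n_val = n * ratio[1] // total
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [ids[i] for i in order]
    train = shuffled[:n_train]
    val = shuffled[n_train : n_train + n_val]
    test = shuffled[n_train + n_val :]
    return train, val, test
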