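"""Programmatic correction of inferred masks and nodule marking.

In clinical use the network's inference is reviewed by a physician who adds
or removes wrongly segmented regions and marks the nodules relevant to the
surgical plan.  Here those interactions are a replayable *edit script* — an
ordered list of per-slice polygon or disk edits, serializable to JSON — so
every correction is testable and auditable without a GUI.

Because no pre-annotated ground truth exists prospectively, the corrected
mask is regarded as the ground truth; the *prospective DSC* scores the raw
inference against it, and an inference the physician did not touch scores
exactly 1.000.

Nodules are kept as geometric metadata (sphere center and radius in mm),
not burned into the thyroid mask: downstream they become the second
(tumor) printing material.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .io import CTVolume, MaskVolume, _rasterize_polygon
from .network import dice_coefficient
from .phantom import Nodule

__all__ = [
    "Edit",
    "EditScript",
    "NoduleSet",
    "apply_edits",
    "prospective_dsc",
    "mark_nodule",
]


@dataclass(frozen=True)
class Edit:
    """One edit: paint a polygon or disk on a slice as mask 1 (add) or 0 (remove).

    ``shape`` is ``("polygon", vertices[(row, col), ...])`` or
    ``("disk", (row, col), radius_px)``.
    """

    slice_index: int
    shape: tuple
    action: Literal["add", "remove"]

    def footprint(self, slice_shape: tuple[int, int]) -> np.ndarray:
        kind = self.shape[0]
        if kind == "polygon":
            verts = np.asarray(self.shape[1], dtype=float)
            if verts.shape[0] < 3:
                raise ValueError("polygon edit needs >=3 vertices")
            return _rasterize_polygon(verts, slice_shape)
        if kind == "disk":
            (r, c), radius = self.shape[1], float(self.shape[2])
            if radius <= 0:
                raise ValueError("disk radius must be > 0")
            rr, cc = np.ogrid[: slice_shape[0], : slice_shape[1]]
            return ((rr - r) ** 2 + (cc - c) ** 2 <= radius**2).astype(np.uint8)
        raise ValueError(f"unknown edit shape {kind!r}")


@dataclass
class EditScript:
    edits: list[Edit] = field(default_factory=list)

    def add_polygon(self, slice_index: int, vertices, action: str = "add") -> "EditScript":
        self.edits.append(Edit(slice_index, ("polygon", [list(v) for v in vertices]), action))
        return self

    def add_disk(self, slice_index: int, center, radius_px: float, action: str = "add") -> "EditScript":
        self.edits.append(Edit(slice_index, ("disk", tuple(center), radius_px), action))
        return self

    def to_json(self, path: str | Path | None = None) -> str:
        payload = [
            {"slice": e.slice_index, "shape": _shape_to_json(e.shape), "action": e.action}
            for e in self.edits
        ]
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EditScript":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        script = cls()
        for item in payload:
            shape = _shape_from_json(item["shape"])
            script.edits.append(Edit(int(item["slice"]), shape, item["action"]))
        return script


def _shape_to_json(shape: tuple) -> dict:
    if shape[0] == "polygon":
        return {"kind": "polygon", "vertices": shape[1]}
    return {"kind": "disk", "center": list(shape[1]), "radius_px": shape[2]}


def _shape_from_json(d: dict) -> tuple:
    if d["kind"] == "polygon":
        return ("polygon", d["vertices"])
    return ("disk", tuple(d["center"]), d["radius_px"])


def apply_edits(mask: MaskVolume, script: EditScript) -> MaskVolume:
    """Replay ``script`` on a copy of ``mask``, in order; output stays binary."""
    vox = mask.voxels.copy()
    n_slices = vox.shape[0]
    for e in script.edits:
        if not 0 <= e.slice_index < n_slices:
            raise ValueError(f"edit references slice {e.slice_index} outside volume")
        if e.action not in ("add", "remove"):
            raise ValueError(f"unknown edit action {e.action!r}")
        fp = e.footprint(vox.shape[1:])
        if e.action == "add":
            vox[e.slice_index] |= fp
        else:
            vox[e.slice_index] &= 1 - fp
    return MaskVolume(vox, mask.pixel_spacing_mm, mask.slice_thickness_mm, mask.label)


def prospective_dsc(inferred: MaskVolume, corrected: MaskVolume) -> float:
    """DSC of the raw inference against the physician-corrected ground truth.

    Exactly 1.0 whenever the correction left the inference unchanged
    (including the all-empty case).
    """
    if inferred.shape != corrected.shape:
        raise ValueError(f"shape mismatch: {inferred.shape} vs {corrected.shape}")
    return dice_coefficient(corrected, inferred)


@dataclass
class NoduleSet:
    """Physician-marked lesions, spheres in volume-centered mm coordinates."""

    nodules: list[Nodule] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodules)

    def __iter__(self):
        return iter(self.nodules)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = [
            {"center_mm": list(n.center_mm), "radius_mm": n.radius_mm, "label": n.label}
            for n in self.nodules
        ]
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NoduleSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(
            [
                Nodule(tuple(d["center_mm"]), float(d["radius_mm"]), d.get("label", "tumor"))
                for d in json.loads(text)
            ]
        )


def mark_nodule(
    volume: CTVolume,
    center_mm: Sequence[float],
    radius_mm: float,
    label: str = "tumor",
    nodule_set: NoduleSet | None = None,
) -> NoduleSet:
    """Append a spherical nodule mark; center in volume-centered (z, y, x) mm.

    The center must lie inside the volume's physical bounds; the mm <-> voxel
    conversion uses pixel spacing in-plane and slice thickness along z.
    """
    if radius_mm <= 0:
        raise ValueError("nodule radius must be > 0")
    cz, cy, cx = (float(v) for v in center_mm)
    ez, ey, ex = volume.physical_extent_mm()
    if abs(cz) > ez / 2 or abs(cy) > ey / 2 or abs(cx) > ex / 2:
        raise ValueError(
            f"nodule center {center_mm} outside physical bounds "
            f"(±{ez / 2:.1f}, ±{ey / 2:.1f}, ±{ex / 2:.1f}) mm"
        )
    if nodule_set is None:
        nodule_set = NoduleSet()
    nodule_set.nodules.append(Nodule((cz, cy, cx), float(radius_mm), label))
    return nodule_set


def nodule_slice_span(volume: CTVolume, nodule: Nodule) -> tuple[int, int]:
    """Inclusive range of slice indices whose z-planes intersect the nodule."""
    cz = nodule.center_mm[0]
    ns = volume.n_slices
    z_of = lambda i: (i - (ns - 1) / 2.0) * volume.slice_thickness_mm
    lo = next((i for i in range(ns) if abs(z_of(i) - cz) <= nodule.radius_mm), None)
    if lo is None:
        raise ValueError("nodule intersects no slice plane")
    hi = max(i for i in range(ns) if abs(z_of(i) - cz) <= nodule.radius_mm)
    return lo, hi
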