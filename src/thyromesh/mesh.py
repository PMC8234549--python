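"""Mesh-type 3D model construction and two-material STL export.

The printable model is not a closed surface shell but an open lattice: the
corrected thyroid mask is contoured slice by slice, each contour is
resampled to equally spaced nodes, and the model places a small sphere at
every node with cylinders joining consecutive nodes along each contour ring
(and, optionally, linking each node to its nearest node on the adjacent
slice's matching contour).  Physician-marked nodules become rings of
tumor-material spheres and cylinders — one circle per slice plane the
sphere intersects — so a two-color FDM printer can render gland and tumor
in different materials.

Coordinates are mm in the volume-centered frame (z along slices, y along
rows, x along columns).  Export writes one binary (or ASCII) STL per
material; each primitive is tessellated as a closed triangle surface
(2*res*(res-1) facets per sphere, 4*res per cylinder), and overlapping
shells are left un-unioned because slicers union overlapping solids.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import MaskVolume
from .phantom import Nodule

__all__ = [
    "MeshParams",
    "MeshModel",
    "Contour",
    "extract_contours",
    "resample_contour",
    "build_mesh",
    "export_stl",
    "sphere_mesh",
    "cylinder_mesh",
]


@dataclass(frozen=True)
class MeshParams:
    node_spacing_mm: float = 3.0
    sphere_radius_mm: float = 1.2
    cylinder_radius_mm: float = 0.8
    resolution: int = 16          # longitudes = latitudes = resolution
    link_slices: bool = True
    scale: float = 1.0            # 1.0 = life-size
    solid_nodules: bool = False   # render nodules as solid spheres, not rings
    nodule_plane_spacing_mm: float = 2.5  # ring planes when no slice grid given

    def __post_init__(self):
        if self.sphere_radius_mm <= 0 or self.cylinder_radius_mm <= 0:
            raise ValueError("primitive radii must be > 0")
        if self.node_spacing_mm <= 0:
            raise ValueError("node spacing must be > 0")
        if self.resolution < 6:
            raise ValueError("tessellation resolution must be >= 6")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass
class Contour:
    """A closed polyline in mm: ``points`` is (N, 2) as (y, x); one z per slice."""

    slice_index: int
    z_mm: float
    points: np.ndarray

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def area(self) -> float:
        y, x = self.points[:, 0], self.points[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass
class MeshModel:
    """Sphere and cylinder primitives per material (``gland`` / ``tumor``)."""

    spheres: list[tuple[np.ndarray, float, str]] = field(default_factory=list)
    cylinders: list[tuple[np.ndarray, np.ndarray, float, str]] = field(default_factory=list)

    def add_sphere(self, center, radius: float, material: str) -> None:
        self.spheres.append((np.asarray(center, dtype=float), float(radius), material))

    def add_cylinder(self, a, b, radius: float, material: str) -> None:
        self.cylinders.append(
            (np.asarray(a, dtype=float), np.asarray(b, dtype=float), float(radius), material)
        )

    def materials(self) -> list[str]:
        mats = {m for *_, m in self.spheres} | {m for *_, m in self.cylinders}
        return sorted(mats)

    def bounds(self, material: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corner over primitive surfaces (centers inflated by radii)."""
        los, his = [], []
        for c, r, m in self.spheres:
            if material in (None, m):
                los.append(c - r)
                his.append(c + r)
        for a, b, r, m in self.cylinders:
            if material in (None, m):
                los.append(np.minimum(a, b) - r)
                his.append(np.maximum(a, b) + r)
        if not los:
            raise ValueError("no primitives for requested material")
        return np.min(los, axis=0), np.max(his, axis=0)

    def summary(self) -> dict:
        out: dict = {}
        for mat in self.materials():
            lo, hi = self.bounds(mat)
            out[mat] = {
                "n_spheres": sum(m == mat for *_, m in self.spheres),
                "n_cylinders": sum(m == mat for *_, m in self.cylinders),
                "bounds_min_mm": [round(float(v), 4) for v in lo],
                "bounds_max_mm": [round(float(v), 4) for v in hi],
            }
        return out


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------


def extract_contours(mask: MaskVolume) -> list[Contour]:
    """Trace the 0/1 interface of every slice as closed polylines in mm.

    Marching squares at level 0.5 on a zero-padded slice, so boundaries
    touching the image edge still close.  Vertices are scaled by pixel
    spacing into the volume-centered frame; ``z = (i - (n-1)/2) * thickness``.
    An empty mask yields an empty list.
    """
    from skimage import measure

    ns, nr, nc = mask.shape
    s = mask.pixel_spacing_mm
    out: list[Contour] = []
    for i in range(ns):
        sl = mask.voxels[i]
        if not sl.any():
            continue
        padded = np.pad(sl.astype(float), 1)
        z = (i - (ns - 1) / 2.0) * mask.slice_thickness_mm
        for ring in measure.find_contours(padded, 0.5):
            pts = ring[:-1] if np.allclose(ring[0], ring[-1]) else ring
            if len(pts) < 3:
                continue
            yx = np.empty_like(pts)
            yx[:, 0] = (pts[:, 0] - 1 - (nr - 1) / 2.0) * s
            yx[:, 1] = (pts[:, 1] - 1 - (nc - 1) / 2.0) * s
            out.append(Contour(i, z, yx))
    return out


def resample_contour(polyline: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Resample a closed polyline to nodes equally spaced by arc length.

    The node count is ``max(3, round(perimeter / spacing))`` — at least a
    triangle, so a ring can always be formed — and the first node sits at
    the polyline's starting vertex.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be > 0")
    pts = np.asarray(polyline, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    perimeter = float(seg.sum())
    if perimeter <= 0:
        raise ValueError("degenerate zero-length polyline")
    n = max(3, int(round(perimeter / spacing_mm)))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n) * (perimeter / n)
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    return closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------


def _to_3d(points_yx: np.ndarray, z: float) -> np.ndarray:
    out = np.empty((len(points_yx), 3))
    out[:, 0] = points_yx[:, 1]  # x
    out[:, 1] = points_yx[:, 0]  # y
    out[:, 2] = z
    return out


def _overlap_area(a: Contour, b: Contour) -> float:
    from shapely.geometry import Polygon

    pa = Polygon(a.points[:, ::-1])
    pb = Polygon(b.points[:, ::-1])
    if not (pa.is_valid and pb.is_valid):
        pa, pb = pa.buffer(0), pb.buffer(0)
    return float(pa.intersection(pb).area)


def _ring(model: MeshModel, nodes3d: np.ndarray, params: MeshParams, material: str) -> None:
    n = len(nodes3d)
    for p in nodes3d:
        model.add_sphere(p, params.sphere_radius_mm, material)
    for i in range(n):
        model.add_cylinder(nodes3d[i], nodes3d[(i + 1) % n], params.cylinder_radius_mm, material)


def build_mesh(
    contours: Sequence[Contour],
    nodules: Iterable[Nodule] = (),
    params: MeshParams | None = None,
    slice_z_mm: Sequence[float] | None = None,
) -> MeshModel:
    """Assemble the sphere+cylinder lattice from contours and nodule marks.

    Gland material: one sphere per resampled contour node and cylinders
    joining consecutive nodes within each ring (closing the loop); with
    ``params.link_slices``, every node additionally links to its nearest
    node on the adjacent slice's largest-overlap contour (ties broken by
    lowest node index).  Tumor material: per nodule, one circle of
    spheres+cylinders per plane the sphere intersects (planes from
    ``slice_z_mm``, the contours' slice grid, or multiples of
    ``params.nodule_plane_spacing_mm``), or a single solid sphere when
    ``params.solid_nodules``.
    """
    params = params or MeshParams()
    contours = list(contours)
    nodules = list(nodules)
    if not contours and not nodules:
        raise ValueError("build_mesh needs at least one contour or nodule")
    model = MeshModel()

    rings: list[tuple[Contour, np.ndarray]] = []
    for ct in contours:
        if ct.perimeter() <= 0:
            continue
        nodes = resample_contour(ct.points, params.node_spacing_mm)
        rings.append((ct, _to_3d(nodes, ct.z_mm)))
    for _, nodes3d in rings:
        _ring(model, nodes3d, params, "gland")

    if params.link_slices and rings:
        by_slice: dict[int, list[int]] = {}
        for ri, (ct, _) in enumerate(rings):
            by_slice.setdefault(ct.slice_index, []).append(ri)
        for si in sorted(by_slice):
            if si + 1 not in by_slice:
                continue
            for ri in by_slice[si]:
                ct_a, nodes_a = rings[ri]
                # match to the largest-overlap contour on the next slice
                best, best_area = None, -1.0
                for rj in by_slice[si + 1]:
                    area = _overlap_area(ct_a, rings[rj][0])
                    if area > best_area:
                        best, best_area = rj, area
                if best is None:
                    continue
                nodes_b = rings[best][1]
                for p in nodes_a:
                    d2 = ((nodes_b - p) ** 2).sum(axis=1)
                    j = int(np.argmin(d2))  # argmin takes the lowest index on ties
                    model.add_cylinder(p, nodes_b[j], params.cylinder_radius_mm, "gland")

    if slice_z_mm is None and contours:
        slice_z_mm = sorted({ct.z_mm for ct in contours})
    for nod in nodules:
        cz, cy, cx = nod.center_mm
        if params.solid_nodules:
            model.add_sphere((cx, cy, cz), nod.radius_mm, "tumor")
            continue
        if slice_z_mm is not None and len(slice_z_mm):
            planes = [z for z in slice_z_mm if abs(z - cz) <= nod.radius_mm]
        else:
            dz = params.nodule_plane_spacing_mm
            k0 = int(np.ceil((cz - nod.radius_mm) / dz))
            k1 = int(np.floor((cz + nod.radius_mm) / dz))
            planes = [k * dz for k in range(k0, k1 + 1)]
        if not planes:
            planes = [cz]  # thin nodule between planes: one equatorial ring
        for z in planes:
            rc = float(np.sqrt(max(nod.radius_mm**2 - (z - cz) ** 2, 0.0)))
            rc = max(rc, 0.25 * nod.radius_mm)  # keep polar rings printable
            n = max(3, int(round(2 * np.pi * rc / params.node_spacing_mm)))
            ang = 2 * np.pi * np.arange(n) / n
            ring3d = np.stack(
                [cx + rc * np.cos(ang), cy + rc * np.sin(ang), np.full(n, z)], axis=1
            )
            _ring(model, ring3d, params, "tumor")
    return model


# ---------------------------------------------------------------------------
# Tessellation and STL export
# ---------------------------------------------------------------------------


def sphere_mesh(center, radius: float, res: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed lat/long sphere: ``res`` longitudes x ``res`` latitude bands.

    Returns (vertices, faces); 2*res*(res-1) triangular facets.
    """
    center = np.asarray(center, dtype=float)
    verts = [center + [0, 0, radius]]
    for j in range(1, res):
        theta = np.pi * j / res
        for i in range(res):
            phi = 2 * np.pi * i / res
            verts.append(
                center
                + radius
                * np.array(
                    [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
                )
            )
    verts.append(center + [0, 0, -radius])
    v = np.asarray(verts)
    faces = []
    ring = lambda j, i: 1 + (j - 1) * res + (i % res)
    for i in range(res):  # top cap
        faces.append([0, ring(1, i), ring(1, i + 1)])
    for j in range(1, res - 1):  # bands
        for i in range(res):
            a, b_ = ring(j, i), ring(j, i + 1)
            c, d = ring(j + 1, i), ring(j + 1, i + 1)
            faces.append([a, c, d])
            faces.append([a, d, b_])
    last = len(v) - 1
    for i in range(res):  # bottom cap
        faces.append([last, ring(res - 1, i + 1), ring(res - 1, i)])
    return v, np.asarray(faces, dtype=np.int64)


def cylinder_mesh(a, b, radius: float, res: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed capped cylinder from ``a`` to ``b``: 4*res triangular facets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    axis = b - a
    length = np.linalg.norm(axis)
    d = axis / length if length > 0 else np.array([0.0, 0.0, 1.0])
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    w = np.cross(d, u)
    ang = 2 * np.pi * np.arange(res) / res
    rim = radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w))
    verts = np.vstack([a, b, a + rim, b + rim])
    faces = []
    for i in range(res):  # caps (fans about the end centers)
        j = (i + 1) % res
        faces.append([0, 2 + j, 2 + i])
        faces.append([1, 2 + res + i, 2 + res + j])
    for i in range(res):  # side
        j = (i + 1) % res
        faces.append([2 + i, 2 + j, 2 + res + i])
        faces.append([2 + j, 2 + res + j, 2 + res + i])
    return verts, np.asarray(faces, dtype=np.int64)


def _model_triangles(model: MeshModel, material: str, params: MeshParams) -> np.ndarray:
    """All facets of one material as an (F, 3, 3) vertex array, scaled."""
    tris = []
    res = params.resolution
    for c, r, m in model.spheres:
        if m != material:
            continue
        v, f = sphere_mesh(c, r, res)
        tris.append(v[f])
    for a, b, r, m in model.cylinders:
        if m != material:
            continue
        v, f = cylinder_mesh(a, b, r, res)
        tris.append(v[f])
    if not tris:
        return np.empty((0, 3, 3))
    return np.concatenate(tris) * params.scale


def _write_stl_binary(path: Path, tris: np.ndarray) -> None:
    n = len(tris)
    e1 = tris[:, 1] - tris[:, 0]
    e2 = tris[:, 2] - tris[:, 0]
    normals = np.cross(e1, e2)
    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.where(lens > 0, normals / np.where(lens > 0, lens, 1), 0.0)
    rec = np.zeros(n, dtype=[("n", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")])
    rec["n"] = normals
    rec["v"] = tris
    with open(path, "wb") as fh:
        fh.write(b"thyromesh binary STL (units: mm)".ljust(80, b" "))
        fh.write(struct.pack("<I", n))
        fh.write(rec.tobytes())


def _write_stl_ascii(path: Path, tris: np.ndarray, name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for t in tris:
            nvec = np.cross(t[1] - t[0], t[2] - t[0])
            ln = np.linalg.norm(nvec)
            nvec = nvec / ln if ln > 0 else nvec
            fh.write(f" facet normal {nvec[0]:.6e} {nvec[1]:.6e} {nvec[2]:.6e}\n  outer loop\n")
            for v in t:
                fh.write(f"   vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
            fh.write("  endloop\n endfacet\n")
        fh.write(f"endsolid {name}\n")


def export_stl(
    model: MeshModel,
    params: MeshParams | None = None,
    path_prefix: str | Path = "thyroid",
    ascii_format: bool = False,
) -> dict[str, Path]:
    """Write one STL per material: ``<prefix>_gland.stl`` / ``<prefix>_tumor.stl``.

    Units are mm (times ``params.scale``); a material with no primitives is
    skipped with a warning.  A ``<prefix>_summary.json`` with primitive
    counts and bounds is written alongside.  Returns material -> path.
    """
    params = params or MeshParams()
    if not model.spheres and not model.cylinders:
        raise ValueError("cannot export an empty model")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for material in ("gland", "tumor"):
        tris = _model_triangles(model, material, params)
        if len(tris) == 0:
            warnings.warn(f"material {material!r} has no primitives; STL omitted")
            continue
        path = prefix.parent / f"{prefix.name}_{material}.stl"
        if ascii_format:
            _write_stl_ascii(path, tris, material)
        else:
            _write_stl_binary(path, tris)
        written[material] = path
    summary = {"scale": params.scale, "materials": model.summary()}
    (prefix.parent / f"{prefix.name}_summary.json").write_text(json.dumps(summary, indent=1))
    return written
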