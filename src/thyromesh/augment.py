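"""Per-epoch stochastic augmentation for paired CT slices and masks.

Four operations are each applied independently with a configurable
probability (default 0.70): in-plane scaling of width and height
(independent factors in 0.70-1.30), rotation (-10..+10 degrees), shear
(-10..+10 degrees), and coarse dropout (a rectangular region covering
10-20% of the image area in which each pixel is zeroed independently with
probability 5-10%).  A horizontal flip follows with probability 0.50.

The geometric operations and the flip are applied identically to image and
mask (bilinear resampling for the image, nearest-neighbor for the mask so
it stays binary); coarse dropout touches the image only.  All transforms
are about the image center, out-of-frame regions fill with 0, and the
output shape equals the input shape.  The draw order is fixed
(scale, rotate, shear, dropout, flip) so a given RNG state reproduces a
given augmentation bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationConfig", "augment_pair", "estimate_application_rates"]


@dataclass(frozen=True)
class AugmentationConfig:
    apply_probability: float = 0.70
    scale_range: tuple[float, float] = (0.70, 1.30)
    rotation_deg_range: tuple[float, float] = (-10.0, 10.0)
    shear_deg_range: tuple[float, float] = (-10.0, 10.0)
    dropout_pixel_prob_range: tuple[float, float] = (0.05, 0.10)
    dropout_area_fraction_range: tuple[float, float] = (0.10, 0.20)
    flip_probability: float = 0.50

    def __post_init__(self):
        for p in (self.apply_probability, self.flip_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        for name in (
            "scale_range",
            "rotation_deg_range",
            "shear_deg_range",
            "dropout_pixel_prob_range",
            "dropout_area_fraction_range",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} bounds out of order: ({lo}, {hi})")

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        return cls(apply_probability=0.0, flip_probability=0.0)


def _draw_ops(config: AugmentationConfig, rng: np.random.Generator) -> dict:
    """Draw which ops apply and their parameters, in the fixed op order.

    Parameters are drawn only for ops that apply, after the apply/skip coin,
    so the draw sequence is stable and replayable.
    """
    plan: dict = {}
    if rng.random() < config.apply_probability:
        plan["scale"] = (
            float(rng.uniform(*config.scale_range)),
            float(rng.uniform(*config.scale_range)),
        )
    if rng.random() < config.apply_probability:
        plan["rotate"] = float(rng.uniform(*config.rotation_deg_range))
    if rng.random() < config.apply_probability:
        plan["shear"] = float(rng.uniform(*config.shear_deg_range))
    if rng.random() < config.apply_probability:
        plan["dropout"] = (
            float(rng.uniform(*config.dropout_area_fraction_range)),
            float(rng.uniform(*config.dropout_pixel_prob_range)),
        )
    plan["flip"] = rng.random() < config.flip_probability
    return plan


def _affine_matrix(plan: dict) -> np.ndarray | None:
    """Compose scale/rotate/shear into one 2x2 (row, col) matrix, or None."""
    mat = np.eye(2)
    applied = False
    if "scale" in plan:
        sx, sy = plan["scale"]  # width (col) then height (row) factor
        mat = np.diag([sy, sx]) @ mat
        applied = True
    if "rotate" in plan:
        th = np.deg2rad(plan["rotate"])
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        mat = rot @ mat
        applied = True
    if "shear" in plan:
        sh = np.tan(np.deg2rad(plan["shear"]))
        mat = np.array([[1.0, 0.0], [sh, 1.0]]) @ mat
        applied = True
    return mat if applied else None


def _apply_plan(
    image: np.ndarray, mask: np.ndarray, plan: dict, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    img = image.astype(np.float32, copy=True)
    msk = mask.astype(np.uint8, copy=True)
    mat = _affine_matrix(plan)
    if mat is not None:
        # ndimage.affine_transform maps output coords through `matrix` to
        # input coords, so pass the inverse; anchor at the image center
        inv = np.linalg.inv(mat)
        center = (np.asarray(img.shape) - 1) / 2.0
        offset = center - inv @ center
        img = ndimage.affine_transform(
            img, inv, offset=offset, order=1, mode="constant", cval=0.0
        )
        msk = ndimage.affine_transform(
            msk, inv, offset=offset, order=0, mode="constant", cval=0
        )
    if "dropout" in plan:
        area_frac, pix_prob = plan["dropout"]
        h, w = img.shape
        # rectangular patch with the drawn area and a drawn aspect ratio
        area = area_frac * h * w
        aspect = float(rng.uniform(0.5, 2.0))
        ph = min(h, max(1, int(round(np.sqrt(area * aspect)))))
        pw = min(w, max(1, int(round(area / ph))))
        r0 = int(rng.integers(0, h - ph + 1))
        c0 = int(rng.integers(0, w - pw + 1))
        drop = rng.random((ph, pw)) < pix_prob
        patch = img[r0 : r0 + ph, c0 : c0 + pw]
        patch[drop] = 0.0
    if plan["flip"]:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    return img, msk


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Augment one (slice, mask) pair; see the module docstring for the scheme.

    The same ``rng`` state always yields bit-identical outputs.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    plan = _draw_ops(config, rng)
    return _apply_plan(image, mask, plan, rng)


def estimate_application_rates(
    config: AugmentationConfig, n_trials: int, seed: int
) -> dict[str, float]:
    """Empirical per-op application frequencies over ``n_trials`` draws."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    counts = {op: 0 for op in ("scale", "rotate", "shear", "dropout", "flip")}
    for _ in range(n_trials):
        plan = _draw_ops(config, rng)
        for op in ("scale", "rotate", "shear", "dropout"):
            counts[op] += op in plan
        counts["flip"] += bool(plan["flip"])
    return {op: c / n_trials for op, c in counts.items()}
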