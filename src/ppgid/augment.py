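"""Training-set-only image augmentation.

Three composable operators act on rendered Gram rasters: horizontal flip,
singular-value perturbation (SVD computed, each singular value scaled by
``1 + eps`` with Gaussian ``eps``, negatives clipped), and principal-
component perturbation (row scores on the top-k PCs scaled by ``1 + eps``,
residual re-added). A bounded random rotation (bilinear, zero fill — zero
intensity means "no similarity", so reflection fill would fabricate
structure) completes the set. ``augment_dataset`` expands a train split by
a fixed number of copies per image, never touching validation/test records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from .types import GramImage, LabelledDataset, Record

__all__ = [
    "AugmentationPlan",
    "hflip",
    "sv_perturb",
    "pca_perturb",
    "rotate",
    "augment_dataset",
]


@dataclass(frozen=True)
class AugmentationPlan:
    flip_enabled: bool = True
    sv_sigma: float = 0.05  # relative singular-value perturbation scale
    pca_components: Union[int, str] = "all"
    rotation_max: float = 90.0  # degrees
    copies_per_image: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rotation_max <= 90.0):
            raise ValueError("rotation_max must lie in [0, 90] degrees")
        if self.copies_per_image < 0 or self.sv_sigma < 0:
            raise ValueError("copies_per_image and sv_sigma must be non-negative")


def _as_raster(image: Union[GramImage, np.ndarray]) -> np.ndarray:
    arr = image.G if isinstance(image, GramImage) else np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square 2-D raster")
    return arr


def hflip(image: Union[GramImage, np.ndarray]) -> np.ndarray:
    """Reverse column order; an involution."""
    return _as_raster(image)[:, ::-1].copy()


def sv_perturb(
    image: Union[GramImage, np.ndarray], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Multiply each singular value by (1 + eps), eps ~ N(0, sigma), clip at 0."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    arr = _as_raster(image)
    U, s, Vt = np.linalg.svd(arr, full_matrices=False)
    eps = rng.normal(0.0, sigma, size=s.shape) if sigma > 0 else np.zeros_like(s)
    s_new = np.clip(s * (1.0 + eps), 0.0, None)
    return (U * s_new) @ Vt


def pca_perturb(
    image: Union[GramImage, np.ndarray],
    k: int,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb row scores on the top-k principal components of the row space.

    Rows are centered, projected onto the top-k PCs, scores scaled by
    (1 + eps) with eps ~ N(0, sigma) per component, and the image is
    reconstructed with the discarded-component residual re-added, so
    sigma = 0 reproduces the input for any k.
    """
    arr = _as_raster(image)
    side = arr.shape[0]
    if not (1 <= k <= side):
        raise ValueError(f"k must lie in [1, {side}], got {k}")
    mean = arr.mean(axis=0, keepdims=True)
    X = arr - mean
    # principal axes of the row cloud
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    top = Vt[:k]  # (k, side)
    scores = X @ top.T  # (side, k)
    residual = X - scores @ top
    eps = rng.normal(0.0, sigma, size=k) if sigma > 0 else np.zeros(k)
    return mean + (scores * (1.0 + eps)) @ top + residual


def rotate(image: Union[GramImage, np.ndarray], angle: float) -> np.ndarray:
    """Rotate by |angle| <= 90 degrees about the center; bilinear, zero fill.

    Multiples of 90 degrees are exact index permutations (no interpolation).
    """
    if abs(angle) > 90.0:
        raise ValueError("|angle| must be <= 90 degrees")
    arr = _as_raster(image)
    if angle % 90 == 0:
        return np.rot90(arr, k=int(angle // 90) % 4).copy()
    return ndimage.rotate(
        arr, angle, reshape=False, order=1, mode="constant", cval=0.0
    )


def _augment_once(
    arr: np.ndarray, plan: AugmentationPlan, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[str, ...]]:
    ops: list[str] = []
    out = arr
    if plan.flip_enabled and rng.random() < 0.5:
        out = hflip(out)
        ops.append("hflip")
        out = sv_perturb(out, plan.sv_sigma, rng)
        ops.append(f"sv_perturb[sigma={plan.sv_sigma}]")
    if plan.rotation_max > 0:
        angle = rng.uniform(-plan.rotation_max, plan.rotation_max)
        out = rotate(out, angle)
        ops.append(f"rotate[{angle:.2f}]")
    return out, tuple(ops)


def augment_dataset(train: LabelledDataset, plan: AugmentationPlan) -> LabelledDataset:
    """Expand a train-split raster dataset to (1 + copies_per_image) x size.

    Every record must carry the train split tag; augmented copies inherit the
    subject label and record the operator chain that produced them.
    """
    for rec in train:
        if rec.split != "train":
            raise ValueError(
                f"augmentation is train-only; record {rec.record_id} has split={rec.split!r}"
            )
    rng = np.random.default_rng(plan.seed)
    records: list[Record] = list(train.records)
    for rec in train:
        arr = _as_raster(rec.payload)
        for c in range(plan.copies_per_image):
            out, ops = _augment_once(arr, plan, rng)
            records.append(
                Record(
                    payload=out,
                    subject_id=rec.subject_id,
                    record_id=f"{rec.record_id}_aug{c:02d}",
                    provenance=rec.provenance,
                    split="train",
                    source_id=rec.record_id,
                    ops=rec.ops + ops,
                )
            )
    manifest = dict(train.manifest)
    manifest["augmentation"] = {
        "flip_enabled": plan.flip_enabled,
        "sv_sigma": plan.sv_sigma,
        "rotation_max": plan.rotation_max,
        "copies_per_image": plan.copies_per_image,
        "seed": plan.seed,
    }
    return LabelledDataset(records, manifest=manifest)
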