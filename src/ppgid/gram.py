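"""Gram-matrix conversion of 1-D signals into 2-D classifier inputs.

Two forms are provided. The per-signal operational form is the rank-1
Gramian ``G = s s^T`` of one normalized signal with itself — an N x N image
whose (m, n) entry is the product of samples m and n; this is what the
classifier consumes, one image per signal. The literal cross-signal form is
the M x M matrix of pairwise dot products between M signals, kept for
similarity analysis.

Rendering min-max rescales intensities to [0, 1] and bilinearly resamples
the matrix to the classifier's fixed input side. A constant matrix has no
contrast and renders as all-zero intensity by convention.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .types import GramImage, PpgSignal

__all__ = ["signal_gram", "cross_gram", "render_gram"]

RENDER_SIDE_DEFAULT = 224


def signal_gram(signal: PpgSignal) -> GramImage:
    """Outer product of a normalized signal with itself (rank <= 1, PSD)."""
    s = np.asarray(signal.samples, dtype=float)
    if s.size == 0:
        raise ValueError("empty signal")
    return GramImage(G=np.outer(s, s), source_id=signal.subject_id)


def cross_gram(signals: list[PpgSignal]) -> np.ndarray:
    """M x M matrix of pairwise dot products between M equal-length signals."""
    if len(signals) == 0:
        raise ValueError("need at least one signal")
    lengths = {len(s) for s in signals}
    if len(lengths) != 1:
        raise ValueError(f"signals must share one length, got {sorted(lengths)}")
    S = np.stack([np.asarray(s.samples, dtype=float) for s in signals])
    return S @ S.T


def render_gram(
    image: GramImage | np.ndarray,
    side: int = RENDER_SIDE_DEFAULT,
    channels: int = 1,
) -> np.ndarray:
    """Rescale a Gram matrix to [0, 1] intensity and resample to side x side.

    Returns an array of shape (side, side) when channels == 1, otherwise
    (side, side, channels) with the single intensity plane replicated.
    Degenerate (constant) matrices map to all-zero intensity.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    G = image.G if isinstance(image, GramImage) else np.asarray(image, dtype=float)
    lo, hi = G.min(), G.max()
    intensity = np.zeros_like(G, dtype=float) if hi <= lo else (G - lo) / (hi - lo)
    if intensity.shape != (side, side):
        intensity = resize(
            intensity, (side, side), order=1, mode="edge", anti_aliasing=False
        )
    if channels == 1:
        return intensity
    return np.repeat(intensity[:, :, None], channels, axis=2)
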