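"""Preprocessing stage: Savitzky-Golay smoothing and min-max normalization.

The smoother fits a low-degree polynomial to each sliding window by linear
least squares and keeps the fit's value at the window center; for evenly
spaced samples this reduces to a fixed convolution. Edges use the standard
edge-preserving convention: the first/last window's polynomial is evaluated
at the edge offsets. Normalization rescales a signal affinely to [0, 1];
a constant signal is rejected rather than silently zeroed, since a fake
flat "identity" would poison the downstream Gram image.

The pipeline order is fixed: filter first (when requested), then normalize,
so the [0, 1] range guarantee holds at the stage boundary the classifier
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.signal import savgol_filter

import numpy as np

from .types import LabelledDataset, PpgSignal, Record

__all__ = [
    "SavGolParams",
    "savgol_smooth",
    "minmax_normalize",
    "preprocess_pipeline",
    "make_variant_dataset",
    "DegenerateSignalError",
]

VARIANTS = ("raw", "filtered", "mixed")


class DegenerateSignalError(ValueError):
    """Raised when a constant signal would make Eq-style min-max rescaling divide by zero."""


@dataclass(frozen=True)
class SavGolParams:
    """Sliding-window least-squares smoothing parameters.

    window_length must be odd and greater than poly_order; defaults (11, 3)
    are a common choice for pulse-wave smoothing at tens of Hz.
    """

    window_length: int = 11
    poly_order: int = 3

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")
        if not (0 <= self.poly_order < self.window_length):
            raise ValueError("require 0 <= poly_order < window_length")


def savgol_smooth(signal: PpgSignal, params: SavGolParams = SavGolParams()) -> PpgSignal:
    """Smooth a signal by sliding least-squares polynomial fits."""
    if len(signal) < params.window_length:
        raise ValueError(
            f"signal length {len(signal)} shorter than window {params.window_length}"
        )
    smoothed = savgol_filter(
        signal.samples.astype(float),
        window_length=params.window_length,
        polyorder=params.poly_order,
        mode="interp",
    )
    return signal.with_samples(smoothed, provenance="filtered")


def minmax_normalize(signal: PpgSignal) -> PpgSignal:
    """Rescale to [0, 1]: x' = (x - min x) / (max x - min x)."""
    x = signal.samples.astype(float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise DegenerateSignalError(
            f"constant signal ({signal.subject_id}): min-max normalization undefined"
        )
    return signal.with_samples((x - lo) / (hi - lo), provenance="normalized")


def preprocess_pipeline(
    signal: PpgSignal,
    variant: str = "filtered",
    savgol: SavGolParams = SavGolParams(),
) -> PpgSignal:
    """Full preprocessing for one signal.

    variant="filtered": smooth then normalize; variant="raw": normalize only.
    """
    if variant not in ("raw", "filtered"):
        raise ValueError(f"variant must be 'raw' or 'filtered', got {variant!r}")
    x = signal.samples
    if x.max() <= x.min():
        # catch this before smoothing: float round-off in the filter could
        # turn an exactly constant input into a not-quite-constant one
        raise DegenerateSignalError(
            f"constant signal ({signal.subject_id}): min-max normalization undefined"
        )
    if variant == "filtered":
        signal = savgol_smooth(signal, savgol)
    return minmax_normalize(signal)


def make_variant_dataset(
    raw: LabelledDataset,
    variant: str = "filtered",
    savgol: SavGolParams = SavGolParams(),
) -> LabelledDataset:
    """Build the raw / filtered / mixed dataset variant.

    raw -> one normalized record per source; filtered -> one smoothed +
    normalized record per source; mixed -> the union of both (each source
    signal contributes two provenance-tagged records).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    chains = {"raw": ("raw",), "filtered": ("filtered",), "mixed": ("raw", "filtered")}[variant]
    records: list[Record] = []
    for rec in raw:
        if not isinstance(rec.payload, PpgSignal):
            raise TypeError("make_variant_dataset expects PpgSignal records")
        for chain in chains:
            out = preprocess_pipeline(rec.payload, variant=chain, savgol=savgol)
            suffix = "" if variant != "mixed" else f"_{chain}"
            records.append(
                Record(
                    payload=out,
                    subject_id=rec.subject_id,
                    record_id=rec.record_id + suffix,
                    provenance=chain if chain == "raw" else "filtered",
                    split=rec.split,
                    source_id=rec.record_id,
                    ops=rec.ops + (f"preprocess[{chain}]",),
                )
            )
    manifest = dict(raw.manifest)
    manifest["variant"] = variant
    return LabelledDataset(records, manifest=manifest)
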