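"""Streaming identification loop.

The sensor is replaced by a replayable :class:`StreamSource` — either a CSV
file of ADC counts or a live synthetic generator for one subject. A session
discards a stabilization period (the sensor's warm-up), captures a fixed
window, runs the exact offline pipeline (preprocess -> Gram -> render ->
forward pass) and reports the predicted subject with per-stage timings.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .gram import render_gram, signal_gram
from .preprocess import SavGolParams, preprocess_pipeline
from .synth import GeneratorConfig, SubjectProfile, synth_signal
from .nn.core import softmax
from .nn.model import PpgNet
from .types import PpgSignal

__all__ = [
    "StreamSource",
    "IdentificationResult",
    "stabilize_and_capture",
    "identify",
    "run_session",
]


@dataclass
class StreamSource:
    """Replayable sample stream: an iterator of ADC counts plus its rate."""

    samples: Iterator[int]
    sampling_rate: float
    origin: str  # "file" | "generator"
    subject_id: str = "unknown"
    adc_bits: int = 18

    @classmethod
    def from_file(cls, path: str | Path, sampling_rate: float = 50.0) -> "StreamSource":
        values = pd.read_csv(path)["value"].astype(np.int64).tolist()
        return cls(iter(values), sampling_rate, origin="file", subject_id=Path(path).stem)

    @classmethod
    def from_generator(
        cls,
        profile: SubjectProfile,
        config: GeneratorConfig,
        rng: Optional[np.random.Generator] = None,
    ) -> "StreamSource":
        rng = rng or np.random.default_rng(config.seed)

        def gen() -> Iterator[int]:
            while True:
                sig = synth_signal(profile, config, rng)
                yield from sig.samples.tolist()

        return cls(gen(), config.sampling_rate, origin="generator", subject_id=profile.subject_id)


@dataclass
class IdentificationResult:
    label: str
    probabilities: np.ndarray
    window: PpgSignal
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def confidence(self) -> float:
        return float(self.probabilities.max())


def stabilize_and_capture(
    source: StreamSource, stabilization: float = 25.0, window: int = 300
) -> PpgSignal:
    """Discard round(stabilization * rate) samples, then capture ``window``."""
    n_discard = int(round(stabilization * source.sampling_rate))
    consumed = list(itertools.islice(source.samples, n_discard + window))
    if len(consumed) < n_discard + window:
        raise ValueError(
            f"stream exhausted: needed {n_discard + window} samples, got {len(consumed)}"
        )
    captured = np.asarray(consumed[n_discard:], dtype=np.int64)
    return PpgSignal(
        samples=captured,
        sampling_rate=source.sampling_rate,
        subject_id=source.subject_id,
        adc_bits=source.adc_bits,
        provenance="raw",
    )


def identify(
    window: PpgSignal,
    model: PpgNet,
    variant: str = "filtered",
    savgol: SavGolParams = SavGolParams(),
) -> IdentificationResult:
    """Preprocess -> Gram -> render -> forward pass on one captured window."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    prepped = preprocess_pipeline(window, variant=variant, savgol=savgol)
    timings["preprocess_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    raster = render_gram(signal_gram(prepped), side=model.config.input_side)
    timings["gram_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    probs = softmax(model.forward_logits(raster[None, :, :], train=False))[0]
    timings["predict_s"] = time.perf_counter() - t0

    idx = int(probs.argmax())
    classes = model.classes or [f"class_{i}" for i in range(len(probs))]
    return IdentificationResult(
        label=classes[idx], probabilities=probs, window=window, timings=timings
    )


def run_session(
    source: StreamSource,
    model: PpgNet,
    n_windows: int = 1,
    stabilization: float = 25.0,
    window: int = 300,
    variant: str = "filtered",
    log_path: Optional[str | Path] = None,
    echo=print,
) -> pd.DataFrame:
    """Loop capture -> identify; each iteration restarts from the current
    stream position (the restart-button analogue). Returns the session log.
    """
    rows = []
    for i in range(n_windows):
        # only the first capture pays the stabilization discard; restarts
        # resume from the live position
        stab = stabilization if i == 0 else 0.0
        win = stabilize_and_capture(source, stabilization=stab, window=window)
        result = identify(win, model, variant=variant)
        echo(f"[window {i + 1}] predicted {result.label} (confidence {result.confidence:.3f})")
        row = {
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "window_index": i,
            "label": result.label,
            "confidence": result.confidence,
            **result.timings,
        }
        rows.append(row)
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return log
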