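"""Core domain types shared across the pipeline.

A :class:`PpgSignal` is a labelled 1-D sample series; a :class:`GramImage`
is the square similarity matrix derived from one signal; a
:class:`LabelledDataset` is an ordered collection of records carrying either,
each tagged with its subject label, split and provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np

ADC_BITS_DEFAULT = 18

Provenance = str  # "raw" | "filtered" | "normalized"


@dataclass(frozen=True)
class PpgSignal:
    """A single PPG recording: samples, sampling rate, subject label.

    Raw-provenance signals hold integer ADC counts in
    ``[0, 2**adc_bits - 1]``; filtered/normalized signals hold floats.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str
    adc_bits: int = ADC_BITS_DEFAULT
    provenance: Provenance = "raw"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.provenance == "raw":
            hi = 2**self.adc_bits - 1
            if not np.issubdtype(samples.dtype, np.integer):
                raise ValueError("raw signals must hold integer counts")
            if samples.min() < 0 or samples.max() > hi:
                raise ValueError(f"raw samples must lie in [0, {hi}]")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1

    def with_samples(self, samples: np.ndarray, provenance: Provenance) -> "PpgSignal":
        return PpgSignal(
            samples=np.asarray(samples),
            sampling_rate=self.sampling_rate,
            subject_id=self.subject_id,
            adc_bits=self.adc_bits,
            provenance=provenance,
        )


@dataclass(frozen=True)
class GramImage:
    """Square similarity matrix derived from one signal.

    The per-signal operational form is the rank-1 outer product ``s s^T``
    of a [0, 1]-normalized signal with itself, so the matrix is symmetric,
    positive semidefinite and has non-negative entries.
    """

    G: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        G = np.asarray(self.G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1] or G.shape[0] == 0:
            raise ValueError("G must be a non-empty square matrix")
        object.__setattr__(self, "G", G)

    @property
    def side(self) -> int:
        return int(self.G.shape[0])

    @property
    def value_range(self) -> tuple[float, float]:
        return float(self.G.min()), float(self.G.max())


Payload = Union[PpgSignal, GramImage, np.ndarray]


@dataclass
class Record:
    """One labelled item: a signal, Gram image or rendered raster."""

    payload: Payload
    subject_id: str
    record_id: str
    provenance: Provenance = "raw"
    split: Optional[str] = None  # None | "train" | "test"
    source_id: Optional[str] = None  # for derived/augmented records
    ops: tuple[str, ...] = ()  # operator chain that produced this record


class LabelledDataset:
    """Ordered collection of labelled records with split/provenance tags."""

    def __init__(self, records: Iterable[Record], manifest: Optional[dict] = None):
        self.records: list[Record] = list(records)
        self.manifest: dict = dict(manifest or {})

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __getitem__(self, i: int) -> Record:
        return self.records[i]

    @property
    def labels(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def subject_ids(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def subset(self, indices: Sequence[int], split: Optional[str] = None) -> "LabelledDataset":
        recs = []
        for i in indices:
            r = self.records[i]
            recs.append(replace_split(r, split) if split is not None else r)
        return LabelledDataset(recs, manifest=dict(self.manifest))

    def filter_split(self, split: str) -> "LabelledDataset":
        return LabelledDataset(
            [r for r in self.records if r.split == split], manifest=dict(self.manifest)
        )


def replace_split(r: Record, split: str) -> Record:
    return Record(
        payload=r.payload,
        subject_id=r.subject_id,
        record_id=r.record_id,
        provenance=r.provenance,
        split=split,
        source_id=r.source_id,
        ops=r.ops,
    )
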