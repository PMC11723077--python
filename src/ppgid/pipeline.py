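"""End-to-end glue: signals -> preprocessed rasters -> trained classifier.

``rasters_from_signals`` runs preprocessing (raw/filtered/mixed variant),
per-signal Gram conversion and rendering for a whole dataset.
``parameter_recovery_run`` is the package's standing end-to-end check: a
small low-noise synthetic cohort, an 80/20 stratified split, the tiny model
preset trained with the Adam-based preset, and the resulting test accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .gram import render_gram, signal_gram
from .preprocess import SavGolParams, make_variant_dataset
from .synth import GeneratorConfig, build_dataset
from .train_eval import SETTINGS, EvalReport, TrainHistory, evaluate, split_dataset, train
from .nn.model import PpgNet, tiny_config, build_model
from .types import LabelledDataset, PpgSignal, Record

__all__ = ["rasters_from_signals", "parameter_recovery_run", "RecoveryResult"]


def rasters_from_signals(
    data: LabelledDataset,
    variant: str = "filtered",
    side: int = 32,
    savgol: SavGolParams = SavGolParams(),
) -> LabelledDataset:
    """Preprocess every signal and render its Gram matrix at ``side`` pixels."""
    prepped = make_variant_dataset(data, variant=variant, savgol=savgol)
    records = []
    for rec in prepped:
        assert isinstance(rec.payload, PpgSignal)
        raster = render_gram(signal_gram(rec.payload), side=side)
        records.append(
            Record(
                payload=raster,
                subject_id=rec.subject_id,
                record_id=rec.record_id,
                provenance=rec.provenance,
                split=rec.split,
                source_id=rec.source_id,
                ops=rec.ops + (f"signal_gram+render[{side}]",),
            )
        )
    manifest = dict(prepped.manifest)
    manifest["raster_side"] = side
    return LabelledDataset(records, manifest=manifest)


@dataclass
class RecoveryResult:
    report: EvalReport
    history: TrainHistory
    model: PpgNet
    classes: list[str]


# Study conditions of the standing end-to-end check: a small cohort with
# sensor noise low enough that identity dominates, at desk-scale image side.
RECOVERY_CONFIG = GeneratorConfig(
    n_subjects=8, signals_per_subject=40, signal_length=300, noise_sd=300.0
)
RECOVERY_SIDE = 32


def parameter_recovery_run(
    seed: int = 0,
    config: Optional[GeneratorConfig] = None,
    variant: str = "filtered",
    epochs: int = 25,
    patience: int = 10,
) -> RecoveryResult:
    """Generate, split, train the tiny preset, and evaluate on held-out data."""
    config = replace(config or RECOVERY_CONFIG, seed=seed)
    raw = build_dataset(config)
    rasters = rasters_from_signals(raw, variant=variant, side=RECOVERY_SIDE)
    rng = np.random.default_rng(seed)
    train_ds, test_ds = split_dataset(rasters, 0.8, rng)
    classes = sorted(set(rasters.labels))
    model = build_model(
        config=tiny_config(n_classes=len(classes), input_side=RECOVERY_SIDE), seed=seed
    )
    model.classes = classes
    history = train(
        model,
        train_ds,
        setting=SETTINGS[2],
        epochs=epochs,
        patience=patience,
        rng=rng,
        classes=classes,
    )
    report = evaluate(model, test_ds, classes=classes)
    return RecoveryResult(report=report, history=history, model=model, classes=classes)
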