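"""Dataset persistence: one CSV per signal plus a manifest.

Mirrors a spreadsheet-per-recording acquisition workflow in an open format:
each signal is a single-column CSV of integer counts, and ``manifest.csv``
maps filenames to subject labels and provenance. A long-format loader
(signal_id, sample_index, value, subject_id) is provided for datasets
exported as one flat table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import LabelledDataset, PpgSignal, Record

__all__ = ["save_dataset", "load_dataset", "load_long_csv", "save_long_csv"]

MANIFEST_NAME = "manifest.csv"
CONFIG_NAME = "manifest.json"


def save_dataset(data: LabelledDataset, out_dir: str | Path) -> Path:
    """Write one CSV per signal and the manifest; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in data:
        if not isinstance(rec.payload, PpgSignal):
            raise TypeError("save_dataset stores PpgSignal records only")
        fname = f"{rec.record_id}.csv"
        pd.DataFrame({"value": rec.payload.samples}).to_csv(out / fname, index=False)
        rows.append(
            {
                "filename": fname,
                "subject_id": rec.subject_id,
                "provenance": rec.provenance,
                "sampling_rate": rec.payload.sampling_rate,
                "adc_bits": rec.payload.adc_bits,
                "split": rec.split or "",
            }
        )
    pd.DataFrame(rows).to_csv(out / MANIFEST_NAME, index=False)
    (out / CONFIG_NAME).write_text(json.dumps(data.manifest.get("config", {}), indent=1))
    return out


def load_dataset(in_dir: str | Path) -> LabelledDataset:
    """Read a dataset written by :func:`save_dataset`."""
    src = Path(in_dir)
    manifest = pd.read_csv(src / MANIFEST_NAME, keep_default_na=False)
    records = []
    for row in manifest.itertuples(index=False):
        values = pd.read_csv(src / row.filename)["value"].to_numpy()
        if row.provenance == "raw":
            values = values.astype(np.int64)
        sig = PpgSignal(
            samples=values,
            sampling_rate=float(row.sampling_rate),
            subject_id=str(row.subject_id),
            adc_bits=int(row.adc_bits),
            provenance=str(row.provenance),
        )
        records.append(
            Record(
                payload=sig,
                subject_id=str(row.subject_id),
                record_id=Path(row.filename).stem,
                provenance=str(row.provenance),
                split=str(row.split) or None,
            )
        )
    meta = {}
    cfg_path = src / CONFIG_NAME
    if cfg_path.exists():
        meta["config"] = json.loads(cfg_path.read_text())
    return LabelledDataset(records, manifest=meta)


def save_long_csv(data: LabelledDataset, path: str | Path) -> Path:
    frames = []
    for rec in data:
        if not isinstance(rec.payload, PpgSignal):
            raise TypeError("save_long_csv stores PpgSignal records only")
        frames.append(
            pd.DataFrame(
                {
                    "signal_id": rec.record_id,
                    "sample_index": np.arange(len(rec.payload)),
                    "value": rec.payload.samples,
                    "subject_id": rec.subject_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def load_long_csv(
    path: str | Path, sampling_rate: float = 50.0, provenance: str = "raw"
) -> LabelledDataset:
    """Load a long-format table (signal_id, sample_index, value, subject_id)."""
    df = pd.read_csv(path)
    required = {"signal_id", "sample_index", "value", "subject_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"long CSV must have columns {sorted(required)}")
    records = []
    for sig_id, group in df.groupby("signal_id", sort=False):
        group = group.sort_values("sample_index")
        values = group["value"].to_numpy()
        if provenance == "raw":
            values = values.astype(np.int64)
        subject = str(group["subject_id"].iloc[0])
        records.append(
            Record(
                payload=PpgSignal(
                    samples=values,
                    sampling_rate=sampling_rate,
                    subject_id=subject,
                    provenance=provenance,
                ),
                subject_id=subject,
                record_id=str(sig_id),
                provenance=provenance,
            )
        )
    return LabelledDataset(records)
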