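"""Record I/O and run configuration.

Records travel as wide CSV (one row per sample: ``time`` plus the 12 standard
lead columns, mV) with a per-dataset metadata sidecar CSV holding the
clinical fields and the split assignment.  Run configurations are YAML and
round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import FEATURE_ORDER, MetadataRaw
from .synth import EcgRecord, LEAD_NAMES, ParameterError

SIDECAR_COLUMNS = ("record_id", "RAxis", "TAxis", "VentricularRate",
                   "QRSCount", "QRSDuration", "split")


class EcgIoError(IOError):
    """Unreadable or malformed ECG input."""


def write_ecg(record: EcgRecord, path: str | Path) -> Path:
    """Write one record as wide CSV (time + 12 lead columns, mV)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame({"time": t})
    for name in LEAD_NAMES:
        df[name] = record.leads[name]
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_ecg(path: str | Path, fs: float | None = None,
             metadata: MetadataRaw | None = None) -> EcgRecord:
    """Read a wide-CSV record; fs is inferred from the time column if absent."""
    path = Path(path)
    if not path.exists():
        raise EcgIoError(f"no such record file: {path}")
    df = pd.read_csv(path)
    missing = [name for name in LEAD_NAMES if name not in df.columns]
    if missing:
        raise EcgIoError(f"record {path.name} is missing lead(s): {missing}")
    if fs is None:
        if "time" not in df.columns or len(df) < 2:
            raise EcgIoError(f"record {path.name}: cannot infer sampling rate")
        dt = float(df["time"].iloc[1] - df["time"].iloc[0])
        if dt <= 0:
            raise EcgIoError(f"record {path.name}: non-increasing time column")
        fs = round(1.0 / dt)
    leads = {name: df[name].to_numpy(dtype=float) for name in LEAD_NAMES}
    return EcgRecord(record_id=path.stem, leads=leads, fs=float(fs),
                     metadata=metadata)


def write_dataset(records: list[EcgRecord], split: dict[str, str],
                  out_dir: str | Path) -> Path:
    """Write records as CSVs plus the metadata/split sidecar ``metadata.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        write_ecg(rec, out_dir / f"{rec.record_id}.csv")
        md = rec.metadata
        rows.append({
            "record_id": rec.record_id,
            "RAxis": md.r_axis if md else "",
            "TAxis": md.t_axis if md else "",
            "VentricularRate": md.ventricular_rate if md else "",
            "QRSCount": md.qrs_count if md else "",
            "QRSDuration": md.qrs_duration if md else "",
            "split": split.get(rec.record_id, ""),
        })
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(
        out_dir / "metadata.csv", index=False)
    return out_dir


def read_dataset(in_dir: str | Path) -> tuple[list[EcgRecord], dict[str, str]]:
    """Read a dataset directory written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    sidecar = in_dir / "metadata.csv"
    if not sidecar.exists():
        raise EcgIoError(f"missing metadata sidecar: {sidecar}")
    meta = pd.read_csv(sidecar)
    records, split = [], {}
    for _, row in meta.iterrows():
        rid = str(row["record_id"])
        md = MetadataRaw(
            r_axis=float(row["RAxis"]) if pd.notna(row["RAxis"]) else None,
            t_axis=float(row["TAxis"]) if pd.notna(row["TAxis"]) else None,
            ventricular_rate=float(row["VentricularRate"]),
            qrs_count=float(row["QRSCount"]),
            qrs_duration=float(row["QRSDuration"]),
        )
        records.append(read_ecg(in_dir / f"{rid}.csv", metadata=md))
        split[rid] = str(row["split"])
    return records, split


@dataclass
class RunConfig:
    """Configuration of a full experiment run (YAML round-trippable)."""

    out_dir: str = "runs/experiment"
    n_records: int = 200
    stratified: bool = False
    features: tuple[str, ...] = FEATURE_ORDER
    conditions: tuple[str, ...] = ("none", "all")  # metadata conditions
    arch: str = "dual"
    bilstm_units: int = 64
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 0.001
    mc_passes: int = 100
    epsilon: float = 1e-3
    alpha: float = 0.05
    data_seed: int = 0
    model_seed: int = 0
    mc_seed: int = 0

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.conditions = tuple(self.conditions)
        unknown = set(self.features) - set(FEATURE_ORDER)
        if unknown:
            raise ParameterError(f"unknown features: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = asdict(self)
        d["features"] = list(self.features)
        d["conditions"] = list(self.conditions)
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
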