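"""Reading and writing per-cell fluorescence data and analysis records.

On-disk layout: one plain one-column CSV/TSV file per replicate (a single
fluorescence value per event, optional header) plus a tab-separated sample
sheet with columns ``strain, replicate, day, condition, path`` describing
every replicate.  Inputs are assumed pre-gated single-channel data; no
compensation or gating is performed here.

Result records (divergences, test results, fits) are written as TSV with
full float precision and can be read back losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FlowSample",
    "SampleSheet",
    "read_sample_table",
    "read_intensity_file",
    "write_sample",
    "write_sample_table",
    "write_records",
    "read_records",
    "load_config",
]

CONDITIONS = ("uninduced", "induced")
SHEET_COLUMNS = ("strain", "replicate", "day", "condition", "path")

#: replicates smaller than this are rejected (configurable per call)
DEFAULT_MIN_EVENTS = 100


@dataclass(frozen=True)
class FlowSample:
    """One replicate's per-cell fluorescence vector plus metadata."""

    strain: str
    replicate: str
    experiment_day: str
    condition: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intensities must be a 1-D vector")
        if arr.size == 0:
            raise ValueError("no events in FlowSample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities contain non-finite values")
        object.__setattr__(self, "intensities", arr)

    @property
    def n_events(self) -> int:
        return int(self.intensities.size)

    @property
    def key(self) -> tuple:
        return (self.strain, self.replicate, self.experiment_day, self.condition)


@dataclass(frozen=True)
class SampleSheet:
    """Rows of (strain, replicate, day, condition, path); keys unique."""

    rows: tuple

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SampleSheet":
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        rows = tuple(
            tuple(str(v) for v in rec)
            for rec in df[list(SHEET_COLUMNS)].itertuples(index=False)
        )
        keys = [r[:4] for r in rows]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate sample-sheet keys: {sorted(dupes)}")
        return cls(rows=rows)


def read_intensity_file(path, *, min_events: int = DEFAULT_MIN_EVENTS) -> np.ndarray:
    """Read a one-column numeric CSV/TSV of per-event intensities.

    A single non-numeric first line is treated as a header.  Values are
    returned unmodified in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"intensity file not found: {path}")
    text = path.read_text().strip().splitlines()
    if text and text[0].strip():
        try:
            float(text[0].split(",")[0].split("\t")[0])
        except ValueError:
            text = text[1:]  # header line
    if not text:
        raise ValueError(f"no events in {path}")
    try:
        vals = np.array([float(line.strip().split(",")[0].split("\t")[0]) for line in text if line.strip()])
    except ValueError as e:
        raise ValueError(f"non-numeric value in {path}: {e}") from None
    if vals.size == 0:
        raise ValueError(f"no events in {path}")
    if vals.size < min_events:
        raise ValueError(
            f"{path} has {vals.size} events, below the floor of {min_events}"
        )
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"non-finite value in {path}")
    return vals


def read_sample_table(
    sheet_path, data_root=None, *, min_events: int = DEFAULT_MIN_EVENTS
) -> list:
    """Load every replicate referenced by a sample sheet.

    Parameters
    ----------
    sheet_path
        TSV file with columns strain, replicate, day, condition, path.
    data_root
        Directory that relative data paths are resolved against (defaults
        to the sheet's directory).

    Returns one ``FlowSample`` per sheet row, in sheet order.  Any missing
    file, duplicate key, non-numeric or empty data raises a parse error
    naming the offending row.
    """
    sheet_path = Path(sheet_path)
    if not sheet_path.exists():
        raise FileNotFoundError(f"sample sheet not found: {sheet_path}")
    root = Path(data_root) if data_root is not None else sheet_path.parent
    df = pd.read_csv(sheet_path, sep="\t", dtype=str)
    sheet = SampleSheet.from_dataframe(df)
    samples = []
    for strain, replicate, day, condition, rel in sheet.rows:
        p = Path(rel)
        if not p.is_absolute():
            p = root / p
        try:
            vals = read_intensity_file(p, min_events=min_events)
            samples.append(
                FlowSample(
                    strain=strain,
                    replicate=replicate,
                    experiment_day=day,
                    condition=condition,
                    intensities=vals,
                )
            )
        except (ValueError, FileNotFoundError) as e:
            raise ValueError(
                f"sample sheet row ({strain}, {replicate}, {day}, {condition}): {e}"
            ) from None
    return samples


def write_sample(sample: FlowSample, path) -> None:
    """Write one replicate as a one-column CSV with header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("intensity\n")
        for v in sample.intensities:
            fh.write(repr(float(v)) + "\n")


def write_sample_table(samples, out_dir) -> Path:
    """Write per-replicate CSVs plus a sample sheet; returns the sheet path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        fname = f"{s.strain}_{s.replicate}_{s.experiment_day}_{s.condition}.csv"
        write_sample(s, out_dir / fname)
        rows.append(
            {
                "strain": s.strain,
                "replicate": s.replicate,
                "day": s.experiment_day,
                "condition": s.condition,
                "path": fname,
            }
        )
    sheet = out_dir / "samples.tsv"
    pd.DataFrame(rows, columns=list(SHEET_COLUMNS)).to_csv(sheet, sep="\t", index=False)
    return sheet


def _record_to_dict(rec) -> dict:
    if dataclasses.is_dataclass(rec):
        d = {}
        for f in dataclasses.fields(rec):
            v = getattr(rec, f.name)
            if isinstance(v, np.ndarray):
                v = ";".join(repr(float(x)) for x in v)
            elif dataclasses.is_dataclass(v):
                continue  # nested parameter snapshots are not tabular
            d[f.name] = v
        return d
    if isinstance(rec, dict):
        return rec
    raise TypeError(f"cannot serialize record of type {type(rec)!r}")


def write_records(records, out_path) -> Path:
    """Write a collection of result records as a TSV (full float precision).

    Records may be any dataclass (DivergenceRecord, TestResult, FitResult,
    ...) or plain dicts; an empty collection yields a header-only file when
    a ``columns`` hint is present on the collection, else an empty file
    with a single placeholder header.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    records = list(records)
    if not records:
        cols = getattr(records, "columns", None) or ["empty"]
        pd.DataFrame(columns=cols).to_csv(out_path, sep="\t", index=False)
        return out_path
    df = pd.DataFrame([_record_to_dict(r) for r in records])
    df.to_csv(out_path, sep="\t", index=False, float_format="%.17g")
    return out_path


def read_records(path, record_type=None) -> list:
    """Read a record TSV back; returns dataclass instances when
    ``record_type`` is given, else dicts.  Round-trips ``write_records``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if record_type is None:
        return df.to_dict("records")
    fields = {f.name: f for f in dataclasses.fields(record_type)}
    out = []
    for rec in df.to_dict("records"):
        kwargs = {k: v for k, v in rec.items() if k in fields}
        out.append(record_type(**kwargs))
    return out


def load_config(path) -> dict:
    """Load a YAML run configuration (model parameters, calibration,
    grid and test settings)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
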