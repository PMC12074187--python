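"""CSV interchange for pipeline tables.

Dialect: comma separator, UTF-8, ISO-8601 timestamps, empty cell for
missing, and one comment header line prefixed ``#`` naming the generating
stage, config hash and seed. Write/read/write round trips are
byte-stable.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_minute_csv",
    "read_minute_csv",
]

TIMESTAMP_COL = "timestamp"
TIME_FORMAT = "%Y-%m-%dT%H:%M:%S"


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable config mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_line(stage: str, chash: str, seed) -> str:
    return f"# stage={stage} config_hash={chash} seed={seed}\n"


def write_table(df: pd.DataFrame, path, stage: str, chash: str = "-",
                seed="-", index: bool = False) -> Path:
    """Write a plain table with the standard comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(_header_line(stage, chash, seed))
    df.to_csv(buf, index=index, na_rep="")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def write_minute_csv(table: pd.DataFrame, path, stage: str = "derive",
                     chash: str = "-", seed="-",
                     time_format: str = TIME_FORMAT) -> Path:
    """Write a timestamp-indexed signal table in the pipeline dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    out.insert(0, TIMESTAMP_COL, out.index.strftime(time_format))
    buf = _io.StringIO()
    buf.write(_header_line(stage, chash, seed))
    out.to_csv(buf, index=False, na_rep="")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


def read_minute_csv(path, time_format: str = TIME_FORMAT) -> pd.DataFrame:
    """Read a timestamp-indexed signal table.

    Empty cells become NaN; unknown columns are preserved. Missing or
    unsorted timestamp columns are rejected.
    """
    # round_trip parsing keeps write -> read -> write byte-stable
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if TIMESTAMP_COL not in df.columns:
        raise ValueError(f"{path}: no '{TIMESTAMP_COL}' column")
    ts = pd.to_datetime(df.pop(TIMESTAMP_COL), format=time_format)
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError(f"{path}: timestamps must be sorted and unique")
    df.index = pd.DatetimeIndex(ts, name=None)
    return df.astype(float, errors="ignore")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


WAVEFORM_TIME_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"


def write_waveform_csv(record, path, chash: str = "-", seed="-") -> Path:
    """Persist a waveform record (timestamp + channel columns)."""
    df = pd.DataFrame(record.channels, index=record.times())
    return write_minute_csv(df, path, stage="simulate", chash=chash,
                            seed=seed, time_format=WAVEFORM_TIME_FORMAT)


def nan_to_none(x):
    return None if (isinstance(x, float) and np.isnan(x)) else x
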