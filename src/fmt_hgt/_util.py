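"""Small shared helpers: percentages, hashing, deterministic TSV output."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded to `decimals` places.

    Raises ZeroDivisionError when the denominator is zero; callers that can
    legitimately hit an empty denominator must guard for it themselves.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for a zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def config_hash(obj: Any) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: Path, meta: Mapping[str, Any] | None = None) -> None:
    """Write a TSV with optional ``# key=value`` metadata header lines.

    Column order is preserved as given; rows are written as-is (callers sort
    before writing when determinism matters).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            for key, value in meta.items():
                fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: Path, dtypes: Mapping[str, type] | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping ``#`` header lines."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if dtypes:
        for col, typ in dtypes.items():
            if col not in df.columns:
                continue
            if typ is bool:
                df[col] = df[col].str.lower().map({"true": True, "false": False})
            elif typ is not str:
                df[col] = df[col].astype(typ)
    return df
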