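"""TSV round-tripping with '#'-prefixed metadata headers.

All pipeline artifacts are tab-separated text with a small metadata block
(seed, config hash, stage) in comment lines, so runs diff cleanly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import pandas as pd

__all__ = ["read_tsv", "write_tsv"]


def write_tsv(df: pd.DataFrame, path: str | Path, meta: Mapping[str, Any] | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
    df.attrs["meta"] = meta
    return df
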