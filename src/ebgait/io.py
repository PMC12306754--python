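"""Cohort readers/writers and configuration loading.

Interchange dialect is fixed: UTF-8 comma-separated values with a header
row; an empty cell means missing.  Treatment indicator columns must be
strictly {0,1}.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .cohort import TREATMENT_NAMES


class SchemaError(ValueError):
    pass


class ParseError(ValueError):
    pass


REQUIRED_COLUMNS = ("limb_id",)


def write_cohort(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = out.index.name or "limb_id"
    out.to_csv(path, index=True, na_rep="")


def read_cohort(path, *, treatments=TREATMENT_NAMES,
                require_treatments: bool = True) -> pd.DataFrame:
    """Read and schema-validate a cohort table.

    Unknown columns are preserved; treatment columns are coerced to
    {0,1} with cell-level validation.
    """
    df = pd.read_csv(path, encoding="utf-8")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if df["limb_id"].duplicated().any():
        dup = df["limb_id"][df["limb_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate limb_id {dup!r}")
    df = df.set_index("limb_id")
    present = [t for t in treatments if t in df.columns]
    if require_treatments and len(present) < len(treatments):
        missing = sorted(set(treatments) - set(present))
        raise SchemaError(f"missing treatment column(s): {missing}")
    for t in present:
        col = pd.to_numeric(df[t], errors="coerce")
        bad = col.isna() | ~col.isin([0, 1])
        if bad.any():
            row = df.index[bad][0]
            raise ParseError(
                f"non-binary value in treatment column {t!r} at row {row!r}")
        df[t] = col.astype(int)
    delta_cols = [c for c in df.columns if c.startswith("delta_")]
    for c in delta_cols:
        if df[c].isna().all():
            raise SchemaError(f"outcome column {c!r} is entirely missing")
    return df


def load_config(path) -> dict:
    """YAML or JSON configuration mirroring the generator config."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
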