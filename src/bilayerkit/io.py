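"""Delimited-table I/O with unit-bearing headers.

Tables are plain CSV with an optional block of ``# key: value`` comment
lines before the header row; the ``# params:`` line carries the
generating or analysis parameters as JSON so every file is replayable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError


def write_table(path, df: pd.DataFrame, params: dict | None = None,
                meta: dict | None = None) -> None:
    """Write a CSV with JSON parameter/metadata comment headers."""
    path = Path(path)
    with open(path, "w") as fh:
        if params is not None:
            fh.write(f"# params: {json.dumps(params, default=str)}\n")
        if meta:
            for key, value in meta.items():
                fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_table(path, required_columns=()) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by write_table; returns (frame, header metadata).

    Raises SchemaError naming the offending column if a required column
    is missing or fails to parse as numeric (e.g. locale decimal commas
    are reported, never silently mangled).
    """
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key == "params":
                    try:
                        meta[key] = json.loads(value)
                    except json.JSONDecodeError:
                        meta[key] = value
                else:
                    meta[key] = value
    import warnings

    try:
        with warnings.catch_warnings():
            # a field-count mismatch (e.g. decimal commas splitting values)
            # must be a hard error, never silent truncation
            warnings.simplefilter("error", pd.errors.ParserWarning)
            df = pd.read_csv(path, comment="#", index_col=False)
    except (pd.errors.ParserError, pd.errors.ParserWarning) as err:
        raise SchemaError(f"column: cannot parse {path.name}: {err}") from err
    for col in required_columns:
        if col not in df.columns:
            raise SchemaError(f"column: missing required column {col!r} in {path.name}")
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(
                f"column: {col!r} in {path.name} is not numeric "
                "(check for locale decimal commas or stray text)"
            )
    return df, meta
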