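"""CSV readers/writers for phenotype tables, marker matrices and kernels.

Dialect: comma-separated UTF-8, "." decimal, configurable missing token
(default "NA").  Every file written by the package starts with comment
lines (``# key: value``) recording the package version, the config
hash and the seed, so outputs are traceable; readers skip ``#`` lines.
Entry/line identifiers are opaque strings joined exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import __version__
from .errors import ParseError
from .markers import Kernel, MarkerMatrix

__all__ = [
    "REQUIRED_PHENOTYPE_COLUMNS",
    "read_phenotypes",
    "write_phenotypes",
    "read_markers",
    "write_markers",
    "read_kernel",
    "write_kernel",
    "read_table",
    "write_table",
]

REQUIRED_PHENOTYPE_COLUMNS = ("location", "replicate", "block", "entry", "tester")

#: Default mapping from deposited-file style column names.
DEFAULT_COLUMN_MAP = {
    "Location": "location",
    "Rep": "replicate",
    "Block": "block",
    "Entry": "entry",
    "Tester": "tester",
}


def _header_lines(meta: dict | None) -> str:
    meta = {"package": f"strigagp {__version__}", **(meta or {})}
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                index: bool = False, na_rep: str = "NA"):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, index=index, na_rep=na_rep)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", na_values=["NA"],
                       keep_default_na=True, **kwargs)


def read_phenotypes(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a plot-level phenotype CSV.

    Requires the design columns location/replicate/block/entry/tester
    (after applying ``column_map``); the rest are treated as trait
    columns.  Duplicated design keys raise with the offending rows.
    """
    df = read_table(path, dtype=str)
    mapping = dict(DEFAULT_COLUMN_MAP)
    mapping.update(column_map or {})
    df = df.rename(columns=mapping)
    missing = set(REQUIRED_PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(
            f"{path}: missing required columns {sorted(missing)}; expected "
            f"{list(REQUIRED_PHENOTYPE_COLUMNS)} plus trait columns"
        )
    key = list(REQUIRED_PHENOTYPE_COLUMNS)
    dup = df.duplicated(subset=key)
    if dup.any():
        rows = (np.nonzero(dup.to_numpy())[0] + 2).tolist()
        raise ParseError(f"{path}: duplicated design keys at data rows {rows[:10]}")
    trait_cols = [c for c in df.columns if c not in key]
    for c in trait_cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in trait column {c!r}: {exc}")
    for c in key:
        df[c] = df[c].astype(str)
    return df


def write_phenotypes(df: pd.DataFrame, path, meta: dict | None = None):
    write_table(df, path, meta=meta, index=False)


def read_markers(path, missing_tokens=("NA", "", "nan")) -> MarkerMatrix:
    """Read a marker CSV: first column line ID, remaining columns 0/1
    calls; declared missing tokens surface as missing (NaN)."""
    raw = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected a line-ID column plus marker columns")
    line_ids = raw.iloc[:, 0].astype(str).tolist()
    if len(set(line_ids)) != len(line_ids):
        seen, dups = set(), []
        for x in line_ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ParseError(f"{path}: duplicated line identifiers {sorted(set(dups))[:5]}")
    marker_ids = [str(c) for c in raw.columns[1:]]
    values = np.empty((len(line_ids), len(marker_ids)))
    tokens = {t.strip().lower() for t in missing_tokens}
    for j, col in enumerate(raw.columns[1:]):
        for i, cell in enumerate(raw[col]):
            s = str(cell).strip()
            if s.lower() in tokens:
                values[i, j] = np.nan
            elif s in ("0", "1"):
                values[i, j] = float(s)
            else:
                try:
                    v = float(s)
                except ValueError:
                    v = None
                if v in (0.0, 1.0):
                    values[i, j] = v
                else:
                    raise ParseError(
                        f"{path}: invalid marker call {s!r} at data row "
                        f"{i + 2}, column {col!r} (expected 0, 1 or missing)"
                    )
    return MarkerMatrix(values, line_ids, marker_ids)


def write_markers(m: MarkerMatrix, path, meta: dict | None = None):
    df = m.to_dataframe()
    out = df.copy()
    # keep integer look for clean round-trips
    for c in out.columns:
        col = out[c]
        out[c] = col.map(lambda v: "" if pd.isna(v) else str(int(v)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(meta))
        out.index.name = "line_id"
        out.to_csv(fh, na_rep="NA")


def write_kernel(k: Kernel, path, meta: dict | None = None):
    df = pd.DataFrame(k.values, index=k.ids, columns=k.ids)
    df.index.name = "line_id"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, float_format="%.10g")


def read_kernel(path) -> Kernel:
    df = pd.read_csv(path, comment="#", index_col=0)
    return Kernel(df.to_numpy(dtype=float), [str(x) for x in df.index])
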