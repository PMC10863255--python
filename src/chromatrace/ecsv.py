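"""Enhanced Character-Separated Values (ECSV 1.0) table I/O.

ECSV is a plain CSV file preceded by a YAML schema header in comment
lines (``# %ECSV 1.0`` / ``# ---`` / ``# datatype: ...``).  The header
carries column names, datatypes, units and free-form table metadata, so
a round trip through disk preserves the full schema — which is what the
pipeline relies on to keep localization and trace tables auditable.

Tables are represented in memory as :class:`pandas.DataFrame` with two
attrs keys: ``units`` (column name -> unit string) and ``meta`` (table
level metadata dict).
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["read_ecsv", "write_ecsv"]

_DTYPE_TO_ECSV = {
    "bool": "bool",
    "int8": "int8",
    "int16": "int16",
    "int32": "int32",
    "int64": "int64",
    "uint8": "uint8",
    "uint16": "uint16",
    "uint32": "uint32",
    "uint64": "uint64",
    "float32": "float32",
    "float64": "float64",
    "object": "string",
    "str": "string",
}

_ECSV_TO_PANDAS = {
    "bool": "bool",
    "int8": "int8",
    "int16": "int16",
    "int32": "int32",
    "int64": "int64",
    "uint8": "uint8",
    "uint16": "uint16",
    "uint32": "uint32",
    "uint64": "uint64",
    "float32": "float32",
    "float64": "float64",
    "string": "object",
}


class ECSVError(ValueError):
    """Malformed ECSV header or schema/data mismatch."""


def _column_datatype(series: pd.Series) -> str:
    name = series.dtype.name
    if name not in _DTYPE_TO_ECSV:
        raise ECSVError(f"column {series.name!r} has unsupported dtype {name}")
    return _DTYPE_TO_ECSV[name]


def write_ecsv(table: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write *table* to *path* with a YAML schema comment header.

    Column units are taken from ``table.attrs["units"]`` and table-level
    metadata from ``table.attrs["meta"]``; both are optional.
    """
    path = Path(path)
    units = table.attrs.get("units", {})
    meta = table.attrs.get("meta", {})

    datatype = []
    for col in table.columns:
        entry: dict = {"name": str(col), "datatype": _column_datatype(table[col])}
        if col in units and units[col]:
            entry["unit"] = str(units[col])
        datatype.append(entry)

    header: dict = {"delimiter": delimiter, "datatype": datatype}
    if meta:
        header["meta"] = meta

    yaml_text = yaml.safe_dump(header, sort_keys=False, default_flow_style=None)
    lines = ["# %ECSV 1.0", "# ---"]
    lines += [f"# {line}" for line in yaml_text.rstrip("\n").split("\n")]
    lines.append(delimiter.join(str(c) for c in table.columns))

    buf = io.StringIO()
    table.to_csv(buf, sep=delimiter, index=False, header=False, lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_ecsv(path: str | Path) -> pd.DataFrame:
    """Read an ECSV file, restoring dtypes, units and metadata.

    Columns present in the file but absent from any expected schema are
    preserved untouched; this function never drops columns.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.split("\n")
    if not lines or not lines[0].startswith("# %ECSV"):
        raise ECSVError(f"{path}: missing '# %ECSV' signature line")

    header_lines = []
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            # strip exactly "# " to preserve YAML indentation
            header_lines.append(line[2:] if line.startswith("# ") else line[1:])
        else:
            data_start = i
            break
    # drop the signature and '---' document marker before YAML parsing
    yaml_body = "\n".join(l for l in header_lines[1:] if l.strip() != "---")
    try:
        header = yaml.safe_load(yaml_body) or {}
    except yaml.YAMLError as exc:  # pragma: no cover - defensive
        raise ECSVError(f"{path}: bad YAML header: {exc}") from exc

    datatype = header.get("datatype")
    if not datatype:
        raise ECSVError(f"{path}: header lacks 'datatype' block")
    delimiter = header.get("delimiter", " ")

    names = [d["name"] for d in datatype]
    dtypes = {}
    for d in datatype:
        ecsv_type = d.get("datatype", "string")
        if ecsv_type not in _ECSV_TO_PANDAS:
            raise ECSVError(f"{path}: unsupported datatype {ecsv_type!r}")
        dtypes[d["name"]] = _ECSV_TO_PANDAS[ecsv_type]

    body = "\n".join(lines[data_start:])
    # string columns must not pass through numeric inference ("001" != 1)
    read_dtypes = {n: "object" for n, t in dtypes.items() if t == "object"}
    table = pd.read_csv(io.StringIO(body), sep=delimiter, skipinitialspace=True,
                        dtype=read_dtypes)
    if list(table.columns) != names:
        raise ECSVError(
            f"{path}: CSV column row {list(table.columns)} does not match "
            f"schema names {names}"
        )
    for name, dt in dtypes.items():
        if dt == "object":
            table[name] = table[name].astype(str)
        else:
            try:
                table[name] = table[name].astype(dt)
            except (TypeError, ValueError) as exc:
                raise ECSVError(f"{path}: column {name!r} not castable to {dt}") from exc

    table.attrs["units"] = {
        d["name"]: d["unit"] for d in datatype if "unit" in d
    }
    table.attrs["meta"] = header.get("meta", {})
    return table


def empty_like_schema(columns: dict[str, str], units: dict[str, str] | None = None,
                      meta: dict | None = None) -> pd.DataFrame:
    """Empty table with the given ``{name: pandas dtype}`` schema."""
    table = pd.DataFrame({c: pd.Series(dtype=t) for c, t in columns.items()})
    table.attrs["units"] = dict(units or {})
    table.attrs["meta"] = dict(meta or {})
    return table
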