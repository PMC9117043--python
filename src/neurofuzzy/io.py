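"""Readers and writers for CSV and ARFF tables.

CSV files need a header row; "?" and the empty string mark missing values.
The ARFF support targets the UCI dialect: ``@relation``, ``@attribute name
type`` (numeric/real/integer or a {nominal} value set) and ``@data`` with
comma-separated rows, "?" for missing.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import NeuroFuzzyError
from .preprocessing import Dataset, encode_categoricals

MISSING_TOKENS = ["?", ""]


def read_csv_table(path, delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, delimiter=delimiter, na_values=MISSING_TOKENS,
                       skipinitialspace=True)


def _strip_quotes(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    return token


def read_arff_table(path) -> pd.DataFrame:
    """Parse a UCI-dialect ARFF file into a DataFrame.

    Nominal attributes come back as string columns, numeric ones as floats;
    "?" entries become NaN.
    """
    names, kinds = [], []
    data_lines = []
    in_data = False
    text = Path(path).read_text()
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if in_data:
            data_lines.append(line)
        elif low.startswith("@attribute"):
            rest = line[len("@attribute"):].strip()
            if rest.startswith(("'", '"')):
                quote = rest[0]
                end = rest.index(quote, 1)
                name, kind = rest[1:end], rest[end + 1:].strip()
            else:
                parts = rest.split(None, 1)
                if len(parts) != 2:
                    raise NeuroFuzzyError(f"malformed @attribute line: {raw!r}")
                name, kind = parts
            names.append(name)
            kinds.append(kind.strip())
        elif low.startswith("@data"):
            in_data = True
        elif low.startswith("@relation"):
            continue
        else:
            raise NeuroFuzzyError(f"unrecognised ARFF header line: {raw!r}")
    if not names:
        raise NeuroFuzzyError("ARFF file declares no attributes")
    frame = pd.read_csv(_io.StringIO("\n".join(data_lines)), header=None,
                        names=names, na_values=MISSING_TOKENS,
                        skipinitialspace=True, quotechar="'")
    for name, kind in zip(names, kinds):
        k = kind.lower()
        if k in ("numeric", "real", "integer") or k.startswith(("numeric", "real", "integer")):
            frame[name] = pd.to_numeric(frame[name], errors="raise")
        else:
            frame[name] = frame[name].map(
                lambda v: v if pd.isna(v) else _strip_quotes(str(v)))
    return frame


def load_table(path, fmt: str | None = None, delimiter: str = ",") -> pd.DataFrame:
    """Read a table, inferring the format from the suffix when not given."""
    path = Path(path)
    if fmt is None:
        fmt = "arff" if path.suffix.lower() == ".arff" else "csv"
    if fmt == "csv":
        return read_csv_table(path, delimiter)
    if fmt == "arff":
        return read_arff_table(path)
    raise NeuroFuzzyError(f"unknown format {fmt!r}")


def load_dataset(path, fmt=None, class_column=None, encoding="ordinal",
                 delimiter=","):
    """Read a table and encode it into a :class:`Dataset`."""
    frame = load_table(path, fmt, delimiter)
    return encode_categoricals(frame, class_column=class_column, encoding=encoding)


def dataset_to_frame(data: Dataset, class_column: str = "class") -> pd.DataFrame:
    frame = pd.DataFrame(data.X, columns=data.feature_names)
    frame[class_column] = [data.class_names[c] for c in data.y]
    return frame


def write_csv(data: Dataset, path, class_column: str = "class"):
    frame = dataset_to_frame(data, class_column)
    frame.to_csv(path, index=False, na_rep="?")


def write_arff(data: Dataset, path, relation: str = "synthetic",
               class_column: str = "class"):
    lines = [f"@relation {relation}", ""]
    for name in data.feature_names:
        quoted = f"'{name}'" if any(ch in name for ch in " ,{}") else name
        lines.append(f"@attribute {quoted} numeric")
    classes = ",".join(data.class_names)
    lines.append(f"@attribute {class_column} {{{classes}}}")
    lines.extend(["", "@data"])
    for i in range(data.n_samples):
        cells = ["?" if np.isnan(v) else repr(float(v)) for v in data.X[i]]
        cells.append(data.class_names[data.y[i]])
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")
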