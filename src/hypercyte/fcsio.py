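"""Minimal FCS 3.1 list-mode export/import for per-cell tables.

Mirrors the common cytometry workflow of converting per-well CSV feature
tables into FCS files for gating software.  Only what that needs is
implemented: float32 list mode ($DATATYPE F, $MODE L), little-endian,
one event per nucleus, one parameter per numeric column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class FCSError(ValueError):
    pass


def write_fcs(path, table: pd.DataFrame) -> None:
    """Write a numeric per-cell table as an FCS 3.1 file (one event/row).

    Non-numeric columns are rejected by name; values are stored as float32,
    so a round-trip read recovers them to float32 precision.
    """
    bad = [c for c in table.columns if not pd.api.types.is_numeric_dtype(table[c])]
    if bad:
        raise FCSError(f"non-numeric columns cannot be exported: {bad}")
    if len(table.columns) == 0:
        raise FCSError("table has no columns")

    data = np.ascontiguousarray(table.to_numpy(dtype="<f4"))
    n_events, n_par = data.shape

    delim = "/"
    kv = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "0" * 8,   # fixed-width placeholders, patched below
        "$ENDDATA": "0" * 8,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_events),
    }
    for i, col in enumerate(table.columns, start=1):
        name = str(col)
        if delim in name:
            raise FCSError(f"column name {name!r} contains the delimiter {delim!r}")
        colmax = float(np.nanmax(data[:, i - 1])) if n_events else 1.0
        kv[f"$P{i}N"] = name
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(max(colmax, 1.0)) + 1)

    text = delim + delim.join(f"{k}{delim}{v}" for k, v in kv.items()) + delim
    header_len = 58
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1
    if data_end > 99_999_999:
        raise FCSError("table too large for 8-digit FCS header offsets")

    text = text.replace(
        f"$BEGINDATA{delim}{'0' * 8}", f"$BEGINDATA{delim}{data_start:08d}"
    ).replace(f"$ENDDATA{delim}{'0' * 8}", f"$ENDDATA{delim}{data_end:08d}")

    header = (
        b"FCS3.1    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_start:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == header_len

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("ascii"))
        fh.write(data.tobytes())


def read_fcs(path) -> pd.DataFrame:
    """Read back an FCS file written by :func:`write_fcs` (float32 list mode)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"FCS3"):
        raise FCSError("not an FCS 3.x file")
    text_start = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_start : text_end + 1].decode("ascii")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    kv = dict(zip(parts[0::2], parts[1::2]))

    if kv.get("$DATATYPE") != "F" or kv.get("$MODE") != "L":
        raise FCSError("only float32 list-mode FCS is supported")
    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    data_start = int(kv["$BEGINDATA"])
    data_end = int(kv["$ENDDATA"])
    dtype = "<f4" if kv.get("$BYTEORD", "1,2,3,4") == "1,2,3,4" else ">f4"
    data = np.frombuffer(raw[data_start : data_end + 1], dtype=dtype)
    data = data.reshape(n_tot, n_par)
    names = [kv.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return pd.DataFrame(data, columns=names)
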