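"""Reading and writing FCS 3.1 list-mode files.

Only the modern subset needed for cytometer data exchange is supported:
FCS 3.1, single dataset, float32 list-mode data ($DATATYPE/F, $MODE/L),
little-endian byte order, with $PnN channel names, optional $PnS marker
names and the optional $SPILLOVER keyword. Log-amplifier scaling of the
FCS 2.0 era ($PnE other than 0,0) and multi-dataset files are out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import RAW_SCALE_TOP, EventTable, SpilloverMatrix

DELIM = "/"
HEADER_LEN = 58  # "FCS3.1    " + 6 x 8-char offsets


class FcsFormatError(ValueError):
    """The file violates the FCS layout; the message names the offending part."""


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _escape(value: str) -> str:
    return value.replace(DELIM, DELIM + DELIM)


def _text_segment(keywords: dict[str, str]) -> bytes:
    parts = [DELIM]
    for key, value in keywords.items():
        parts.append(_escape(key) + DELIM + _escape(str(value)) + DELIM)
    return "".join(parts).encode("utf-8")


def _spillover_keyword(spill: SpilloverMatrix) -> str:
    n = len(spill.channels)
    cells = [str(n), *spill.channels]
    cells += [repr(float(v)) for v in spill.matrix.ravel()]
    return ",".join(cells)


def write_fcs(table: EventTable, path: str | Path) -> Path:
    """Write an :class:`EventTable` as an FCS 3.1 list-mode file.

    Data are stored as little-endian float32; hidden simulator labels are
    intentionally not serialized.
    """
    path = Path(path)
    columns = list(table.data.columns)
    n_par = len(columns)
    n_tot = len(table)
    data = np.ascontiguousarray(table.data.to_numpy(dtype="<f4"))

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, col in enumerate(columns, start=1):
        keywords[f"$P{i}N"] = col
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = str(int(RAW_SCALE_TOP))
        marker = table.channel_map.get(col)
        if marker:
            keywords[f"$P{i}S"] = marker
    if table.panel_id:
        keywords["$PROJ"] = table.panel_id
    if table.sample_id:
        keywords["$SMNO"] = table.sample_id
    keywords["$TIMESTEP"] = "1"
    keywords["HEMOFLOW_DURATION"] = repr(float(table.duration))
    keywords["HEMOFLOW_VOLUME_UL"] = repr(float(table.volume_ul))
    if table.spillover is not None:
        keywords["$SPILLOVER"] = _spillover_keyword(table.spillover)

    # two-pass: sizes of BEGIN/END data offsets depend on the text length,
    # so fix the text length with zero-padded placeholder offsets first.
    placeholder = {"$BEGINDATA": "0" * 12, "$ENDDATA": "0" * 12, **keywords}
    text_len = len(_text_segment(placeholder))
    text_start = HEADER_LEN + 4  # small spacer after header
    text_end = text_start + text_len - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1 if data.nbytes else 0

    final = {
        "$BEGINDATA": str(data_start).zfill(12),
        "$ENDDATA": str(max(data_end, 0)).zfill(12),
        **keywords,
    }
    text = _text_segment(final)
    assert len(text) == text_len

    def offs(v: int) -> bytes:
        s = str(v)
        return (s if len(s) <= 8 else "0" * 8).rjust(8).encode("ascii")

    header = b"FCS3.1    " + offs(text_start) + offs(text_end)
    header += offs(data_start if data_start <= 99_999_999 else 0)
    header += offs(data_end if data_end <= 99_999_999 else 0)
    header += offs(0) + offs(0)
    assert len(header) == HEADER_LEN

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b" " * (text_start - HEADER_LEN))
        fh.write(text)
        fh.write(data.tobytes())
    return path


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_text(raw: bytes) -> dict[str, str]:
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise FcsFormatError(f"TEXT segment is not valid UTF-8: {exc}") from exc
    if not text:
        raise FcsFormatError("TEXT segment is empty")
    delim = text[0]
    body = text[1:]
    if body.endswith(delim):
        body = body[:-1]
    # split on single delimiters; doubled delimiters are escapes
    tokens = body.replace(delim + delim, "\x00").split(delim)
    tokens = [t.replace("\x00", delim) for t in tokens]
    if len(tokens) % 2 != 0:
        raise FcsFormatError("TEXT segment has an unpaired keyword")
    out: dict[str, str] = {}
    for key, value in zip(tokens[::2], tokens[1::2]):
        out[key.strip().upper() if key.startswith("$") else key.strip()] = value
    return out


def _parse_spillover(value: str) -> SpilloverMatrix:
    cells = value.split(",")
    try:
        n = int(cells[0])
    except ValueError as exc:
        raise FcsFormatError(f"$SPILLOVER does not start with a channel count: {value[:40]}") from exc
    names = cells[1 : 1 + n]
    vals = np.array([float(v) for v in cells[1 + n :]], dtype=float)
    if vals.size != n * n:
        raise FcsFormatError("$SPILLOVER matrix size does not match its channel count")
    return SpilloverMatrix(names, vals.reshape(n, n))


def read_fcs(path: str | Path) -> EventTable:
    """Read an FCS 3.1 file written by :func:`write_fcs` (or compatible).

    A truncated DATA segment raises :class:`FcsFormatError` rather than
    silently returning fewer events.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < HEADER_LEN:
        raise FcsFormatError("file shorter than an FCS header")
    if not blob[:6].startswith(b"FCS3"):
        raise FcsFormatError(f"not an FCS 3.x file (magic {blob[:6]!r})")

    def header_int(a: int, b: int, what: str) -> int:
        try:
            return int(blob[a:b].decode("ascii").strip() or "0")
        except ValueError as exc:
            raise FcsFormatError(f"malformed header offset for {what}") from exc

    text_start = header_int(10, 18, "TEXT start")
    text_end = header_int(18, 26, "TEXT end")
    if text_start <= 0 or text_end < text_start or text_end >= len(blob):
        raise FcsFormatError("TEXT segment offsets out of range")
    kw = _parse_text(blob[text_start : text_end + 1])

    for required in ("$PAR", "$TOT", "$DATATYPE", "$BYTEORD", "$MODE"):
        if required not in kw:
            raise FcsFormatError(f"missing required keyword {required}")
    if kw["$DATATYPE"] != "F":
        raise FcsFormatError(f"unsupported $DATATYPE {kw['$DATATYPE']!r} (only F)")
    if kw["$MODE"] != "L":
        raise FcsFormatError(f"unsupported $MODE {kw['$MODE']!r} (only list mode)")
    byteord = kw["$BYTEORD"]
    if byteord not in ("1,2,3,4", "4,3,2,1"):
        raise FcsFormatError(f"unsupported $BYTEORD {byteord!r}")
    dtype = "<f4" if byteord == "1,2,3,4" else ">f4"

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    data_start = int(kw.get("$BEGINDATA", "0"))
    data_end = int(kw.get("$ENDDATA", "0"))
    if data_start == 0:
        data_start = header_int(26, 34, "DATA start")
        data_end = header_int(34, 42, "DATA end")

    expected = n_par * n_tot * 4
    if n_tot:
        available = len(blob) - data_start
        span = data_end - data_start + 1
        if span < expected or available < expected:
            raise FcsFormatError(
                f"DATA segment truncated: need {expected} bytes for "
                f"$TOT={n_tot} x $PAR={n_par}, have {min(span, available)}"
            )
        data = np.frombuffer(blob[data_start : data_start + expected], dtype=dtype)
        data = data.reshape(n_tot, n_par).astype(np.float64)
    else:
        data = np.empty((0, n_par))

    names, markers = [], {}
    for i in range(1, n_par + 1):
        if f"$P{i}N" not in kw:
            raise FcsFormatError(f"missing channel name keyword $P{i}N")
        name = kw[f"$P{i}N"]
        names.append(name)
        if f"$P{i}S" in kw:
            markers[name] = kw[f"$P{i}S"]

    spill = None
    if "$SPILLOVER" in kw:
        spill = _parse_spillover(kw["$SPILLOVER"])

    return EventTable(
        data=pd.DataFrame(data, columns=names),
        panel_id=kw.get("$PROJ", ""),
        sample_id=kw.get("$SMNO", ""),
        channel_map=markers,
        duration=float(kw.get("HEMOFLOW_DURATION", 60.0)),
        volume_ul=float(kw.get("HEMOFLOW_VOLUME_UL", 100.0)),
        spillover=spill,
    )


# ---------------------------------------------------------------------------
# plain-text spillover matrices
# ---------------------------------------------------------------------------

def read_spillover_csv(path: str | Path) -> SpilloverMatrix:
    """Load a channel-labelled square spillover matrix from CSV."""
    frame = pd.read_csv(path, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise FcsFormatError("spillover CSV row and column labels differ")
    return SpilloverMatrix(list(frame.columns), frame.to_numpy(dtype=float))


def write_spillover_csv(spill: SpilloverMatrix, path: str | Path) -> Path:
    path = Path(path)
    spill.to_frame().to_csv(path)
    return path
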