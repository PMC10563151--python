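"""Minimal FCS 3.0/3.1 reader and fixture writer.

Supports list-mode ($MODE L) datasets with float ($DATATYPE F/D) or
fixed-width integer ($DATATYPE I) events, little- or big-endian $BYTEORD.
Spillover/compensation, analysis segments and multi-dataset files are out of
scope; clinical exports are assumed compensated upstream.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np


class FCSFormatError(ValueError):
    """Raised when a file cannot be parsed as FCS 3.0/3.1."""


def _parse_text_segment(raw: bytes) -> Dict[str, str]:
    if not raw:
        raise FCSFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Escaped delimiters (doubled) are not produced by our writer and are
    # rare in clinical exports; split plainly and reject odd token counts.
    parts = body.split(delim)
    if len(parts) % 2 != 0:
        raise FCSFormatError("TEXT segment has an odd number of tokens")
    out: Dict[str, str] = {}
    for k, v in zip(parts[0::2], parts[1::2]):
        out[k.decode("utf-8", "replace").strip().upper()] = v.decode("utf-8", "replace").strip()
    return out


def read_fcs_file(path) -> Tuple[np.ndarray, List[str], Dict[str, str]]:
    """Read an FCS file.

    Returns (events, channel_names, text_keywords).  Channel names prefer the
    stain name $PnS and fall back to the short name $PnN.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 58:
        raise FCSFormatError(f"{path}: file too short to be FCS")
    version = data[0:6].decode("ascii", "replace")
    if not version.startswith("FCS3"):
        raise FCSFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo: int, hi: int) -> int:
        field = data[lo:hi].decode("ascii", "replace").strip()
        if not field:
            return 0
        try:
            return int(field)
        except ValueError as e:
            raise FCSFormatError(f"{path}: bad header offset {field!r}") from e

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    if text_end <= text_start:
        raise FCSFormatError(f"{path}: invalid TEXT segment offsets")
    text = _parse_text_segment(data[text_start:text_end + 1])

    if data_start == 0 and data_end == 0:
        data_start = int(text.get("$BEGINDATA", "0"))
        data_end = int(text.get("$ENDDATA", "0"))
    if data_end <= data_start:
        raise FCSFormatError(f"{path}: invalid DATA segment offsets")

    mode = text.get("$MODE", "L").upper()
    if mode != "L":
        raise FCSFormatError(f"{path}: only list mode ($MODE L) is supported, got {mode!r}")
    try:
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
    except KeyError as e:
        raise FCSFormatError(f"{path}: missing required keyword {e}") from e

    byteord = text.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    endian = "<" if little else ">"
    dtype_code = text.get("$DATATYPE", "F").upper()

    names: List[str] = []
    for p in range(1, n_par + 1):
        name = text.get(f"$P{p}S") or text.get(f"$P{p}N") or f"P{p}"
        names.append(name)

    raw = data[data_start:data_end + 1]
    if dtype_code == "F":
        dt = np.dtype(endian + "f4")
        itemsize = 4
    elif dtype_code == "D":
        dt = np.dtype(endian + "f8")
        itemsize = 8
    elif dtype_code == "I":
        bits = {int(text.get(f"$P{p}B", "16")) for p in range(1, n_par + 1)}
        if len(bits) != 1:
            raise FCSFormatError(f"{path}: mixed integer widths are not supported")
        nbits = bits.pop()
        if nbits not in (8, 16, 32):
            raise FCSFormatError(f"{path}: unsupported integer width {nbits}")
        dt = np.dtype(endian + f"u{nbits // 8}")
        itemsize = nbits // 8
    else:
        raise FCSFormatError(f"{path}: unsupported $DATATYPE {dtype_code!r}")

    needed = n_tot * n_par * itemsize
    if len(raw) < needed:
        raise FCSFormatError(
            f"{path}: DATA segment holds {len(raw)} bytes, need {needed} for "
            f"$TOT={n_tot} x $PAR={n_par}"
        )
    events = np.frombuffer(raw[:needed], dtype=dt).reshape(n_tot, n_par).astype(float)
    return events, names, text


def write_fcs_file(path, events: np.ndarray, names: List[str]) -> None:
    """Write a minimal FCS 3.0 file (float32, little-endian).

    Intended for test fixtures and round-trip checks, not clinical export.
    """
    events = np.asarray(events, dtype=np.float32)
    if events.ndim != 2:
        raise ValueError("events must be a 2-D array")
    n_tot, n_par = events.shape
    if n_par != len(names):
        raise ValueError("one channel name per column required")

    payload = events.astype("<f4").tobytes()
    keywords = [
        ("$MODE", "L"),
        ("$DATATYPE", "F"),
        ("$BYTEORD", "1,2,3,4"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
        ("$NEXTDATA", "0"),
    ]
    for p, name in enumerate(names, start=1):
        keywords.append((f"$P{p}N", name))
        keywords.append((f"$P{p}S", name))
        keywords.append((f"$P{p}B", "32"))
        keywords.append((f"$P{p}E", "0,0"))
        keywords.append((f"$P{p}R", str(int(max(1, np.ceil(np.abs(events[:, p - 1]).max() + 1))))))

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in keywords) + delim
    text_bytes = text.encode("ascii")

    header_len = 58
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1

    header = (
        b"FCS3.0    "
        + f"{text_start:8d}".encode()
        + f"{text_end:8d}".encode()
        + f"{data_start:8d}".encode()
        + f"{data_end:8d}".encode()
        + f"{0:8d}".encode()
        + f"{0:8d}".encode()
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text_bytes + payload)
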