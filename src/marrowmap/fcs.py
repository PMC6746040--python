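"""Reading and writing Flow Cytometry Standard (FCS) list-mode files.

Supports the subset of the standard that routine clinical instruments
emit: FCS 3.0 / 3.1, list mode (``$MODE L``), ``$DATATYPE`` ``F``
(float32) or ``I`` (16/32-bit unsigned integers).  Everything else —
ASCII/double datatypes, correlated mode, FCS 2.0 — is rejected with an
:class:`~marrowmap.exceptions.UnsupportedDialectError` rather than
guessed at.  Files are written as FCS 3.1, float32, little-endian.

The ANALYSIS segment and non-essential keywords are ignored on read and
not round-tripped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventMatrix
from .exceptions import CorruptFileError, UnsupportedDialectError, ValidationError

HEADER_LEN = 58
_DELIM = "/"
#: Non-standard keyword carrying the simulator's population-of-origin labels.
TRUTH_KEYWORD = "MMAPTRUTH"

_BYTE_ORDERS = {"1,2,3,4": "<", "4,3,2,1": ">"}


@dataclass
class FcsMetadata:
    """Parsed TEXT-segment metadata of one FCS file."""

    version: str
    keyword_map: dict[str, str] = field(default_factory=dict)
    byte_order: str = "<"
    datatype: str = "float32"

    @property
    def n_events(self) -> int:
        return int(self.keyword_map["$TOT"])

    @property
    def n_channels(self) -> int:
        return int(self.keyword_map["$PAR"])


# ----------------------------------------------------------------------
# reading

def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise CorruptFileError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw[1:].decode("latin-1")
    # Trailing delimiter terminates the segment.
    if body.endswith(delim):
        body = body[:-1]
    parts = body.split(delim)
    if len(parts) % 2:
        raise CorruptFileError("TEXT segment has an odd number of delimited fields")
    kw = {}
    for key, value in zip(parts[::2], parts[1::2]):
        kw[key.strip().upper() if key.startswith("$") else key.strip()] = value
    return kw


def read_fcs(path) -> tuple[EventMatrix, FcsMetadata]:
    """Read an FCS 3.0/3.1 list-mode file.

    Returns the events (``state="raw"``) with channel names from ``$PnN``
    and marker names from ``$PnS`` where present, plus the parsed metadata.

    Raises
    ------
    UnsupportedDialectError
        For versions other than FCS 3.0/3.1, non-list mode, or datatypes
        other than F/I.
    CorruptFileError
        If the declared segments do not fit in the file.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < HEADER_LEN:
        raise CorruptFileError(f"{path}: file shorter than an FCS header")
    version = blob[:6].decode("latin-1")
    if version not in ("FCS3.0", "FCS3.1"):
        raise UnsupportedDialectError(f"{path}: unsupported version {version!r}")

    def _offset(a: int, b: int) -> int:
        text = blob[a:b].decode("latin-1").strip()
        return int(text) if text else 0

    text_start, text_end = _offset(10, 18), _offset(18, 26)
    data_start, data_end = _offset(26, 34), _offset(34, 42)
    if text_end >= len(blob) or text_start >= text_end:
        raise CorruptFileError(f"{path}: TEXT segment offsets out of range")
    kw = _parse_text_segment(blob[text_start : text_end + 1])
    for required in ("$TOT", "$PAR", "$DATATYPE", "$MODE", "$BYTEORD"):
        if required not in kw:
            raise CorruptFileError(f"{path}: missing required keyword {required}")
    if kw["$MODE"].upper() != "L":
        raise UnsupportedDialectError(f"{path}: only list mode supported, got $MODE={kw['$MODE']}")
    datatype = kw["$DATATYPE"].upper()
    if datatype not in ("F", "I"):
        raise UnsupportedDialectError(f"{path}: unsupported $DATATYPE={datatype}")
    if kw["$BYTEORD"] not in _BYTE_ORDERS:
        raise UnsupportedDialectError(f"{path}: unsupported $BYTEORD={kw['$BYTEORD']}")
    endian = _BYTE_ORDERS[kw["$BYTEORD"]]

    # FCS 3.0 files with large data may zero the header offsets and use
    # $BEGINDATA/$ENDDATA instead.
    if data_start == 0 and "$BEGINDATA" in kw:
        data_start, data_end = int(kw["$BEGINDATA"]), int(kw["$ENDDATA"])

    n_events, n_channels = int(kw["$TOT"]), int(kw["$PAR"])
    channel_names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_channels + 1)]
    marker_names = [kw.get(f"$P{i}S", "") for i in range(1, n_channels + 1)]

    if datatype == "F":
        dtype = np.dtype(endian + "f4")
        bits = [32] * n_channels
    else:
        bits = [int(kw.get(f"$P{i}B", "32")) for i in range(1, n_channels + 1)]
        if any(b not in (16, 32) for b in bits):
            raise UnsupportedDialectError(
                f"{path}: integer data with $PnB outside 16/32 bits"
            )
        if len(set(bits)) > 1:
            raise UnsupportedDialectError(f"{path}: mixed integer widths not supported")
        dtype = np.dtype(endian + ("u2" if bits[0] == 16 else "u4"))

    expected = n_events * n_channels * dtype.itemsize
    payload = blob[data_start : data_start + expected]
    if len(payload) < expected:
        raise CorruptFileError(
            f"{path}: DATA segment truncated ({len(payload)} of {expected} bytes)"
        )
    values = (
        np.frombuffer(payload, dtype=dtype)
        .reshape(n_events, n_channels)
        .astype(float)
    )
    truth = None
    if TRUTH_KEYWORD in kw and kw[TRUTH_KEYWORD]:
        labels = kw[TRUTH_KEYWORD].split(",")
        if len(labels) == n_events:
            truth = np.array(labels, dtype=object)
    sample_id = kw.get("$FIL", "") or "sample0"
    meta = FcsMetadata(
        version=version,
        keyword_map=kw,
        byte_order=endian,
        datatype="float32" if datatype == "F" else "int",
    )
    events = EventMatrix(
        values=values,
        channel_names=channel_names,
        marker_names=marker_names,
        sample_ids=np.array([sample_id] * n_events, dtype=object),
        state="raw",
        truth=truth,
    )
    return events, meta


# ----------------------------------------------------------------------
# writing

def write_fcs(events: EventMatrix, path, include_truth: bool = False) -> None:
    """Write events as an FCS 3.1 list-mode file (float32, little-endian).

    ``read_fcs(write_fcs(E))`` reproduces values to float32 precision and
    names exactly.  With ``include_truth`` the simulator's hidden
    population labels are stored under a non-standard keyword
    (:data:`TRUTH_KEYWORD`), never as a measurement channel.
    """
    if events.n_channels < 1:
        raise ValidationError("cannot write an FCS file with zero channels")
    if events.values.size and not np.isfinite(events.values).all():
        raise ValidationError("values contain non-finite entries")
    n, p = events.values.shape
    payload = events.values.astype("<f4").tobytes()

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        # fixed-width so the TEXT length is independent of the actual offsets
        "$BEGINDATA": "%10d" % 0,
        "$ENDDATA": "%10d" % 0,
        "$NEXTDATA": "0",
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$TOT": str(n),
        "$PAR": str(p),
    }
    sample_ids = set(events.sample_ids.tolist())
    if len(sample_ids) == 1:
        kw["$FIL"] = str(next(iter(sample_ids)))
    for i in range(p):
        kw[f"$P{i + 1}N"] = events.channel_names[i]
        if events.marker_names[i]:
            kw[f"$P{i + 1}S"] = events.marker_names[i]
        kw[f"$P{i + 1}B"] = "32"
        kw[f"$P{i + 1}E"] = "0,0"
        col_max = float(events.values[:, i].max()) if n else 0.0
        kw[f"$P{i + 1}R"] = str(int(max(col_max, 1.0)) + 1)
    if include_truth and events.truth is not None:
        kw[TRUTH_KEYWORD] = ",".join(str(t) for t in events.truth)

    def _render(kwmap: dict[str, str]) -> bytes:
        out = [_DELIM]
        for k, v in kwmap.items():
            out.append(f"{k}{_DELIM}{v}{_DELIM}")
        return "".join(out).encode("latin-1")

    text = _render(kw)
    text_start = HEADER_LEN
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + len(payload) - 1 if payload else 0
    kw["$BEGINDATA"] = "%10d" % data_start
    kw["$ENDDATA"] = "%10d" % data_end
    text = _render(kw)
    assert text_start + len(text) - 1 == text_end  # fixed-width offsets

    def _fmt(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        _fmt(x)
        for x in (
            text_start,
            text_end,
            data_start if len(str(data_start)) <= 8 else 0,
            data_end if len(str(data_end)) <= 8 else 0,
            0,
            0,
        )
    )
    assert len(header) == HEADER_LEN
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(payload)


# ----------------------------------------------------------------------
# merging

def merge_events(samples, panel) -> EventMatrix:
    """Row-concatenate samples, reordering columns to the panel's order.

    Channels are matched per sample by marker name (``$PnS``) first,
    falling back to channel name (``$PnN``), case-insensitively — the
    same stain may sit on a different detector across donors.  All
    samples must be in the same processing state and contain every panel
    channel; a missing channel raises a
    :class:`~marrowmap.exceptions.ChannelMismatchError` naming the sample
    and the channel.
    """
    from .preprocess import _panel_column  # late import avoids a cycle

    if not samples:
        raise ValidationError("no samples to merge")
    states = {s.state for s in samples}
    if len(states) > 1:
        raise ValidationError(f"samples are in mixed states: {sorted(states)}")
    blocks, ids, truths = [], [], []
    any_truth = any(s.truth is not None for s in samples)
    for s in samples:
        cols = [_panel_column(s, ch) for ch in panel.channels]
        blocks.append(s.values[:, cols])
        ids.append(s.sample_ids)
        if any_truth:
            truths.append(
                s.truth if s.truth is not None
                else np.array(["?"] * s.n_events, dtype=object)
            )
    return EventMatrix(
        values=np.vstack(blocks),
        channel_names=[c.name for c in panel.channels],
        marker_names=[c.marker for c in panel.channels],
        sample_ids=np.concatenate(ids),
        state=samples[0].state,
        truth=np.concatenate(truths) if any_truth else None,
    )
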