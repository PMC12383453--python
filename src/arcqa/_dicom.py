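"""Minimal DICOM codec (explicit VR little endian) for the RTPLAN subset.

Supports exactly what :mod:`arcqa.plan_model` needs to persist dynamic-arc
plans: flat data elements of the common string/numeric VRs plus nested
sequences (SQ) with defined or undefined lengths.  This is not a general
DICOM implementation; files written here are standard-conformant and can be
opened by pydicom or a TPS, but reading is restricted to the explicit VR
little endian transfer syntax.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Union

Tag = tuple[int, int]

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"
SOP_CLASS_RTPLAN = "1.2.840.10008.5.1.4.1.1.481.5"
IMPLEMENTATION_UID = "1.2.826.0.1.3680043.10.1462.1"

_ITEM = (0xFFFE, 0xE000)
_ITEM_DELIM = (0xFFFE, 0xE00D)
_SEQ_DELIM = (0xFFFE, 0xE0DD)

# VRs using the 12-byte header (2 reserved bytes + 4-byte length).
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UN", "UT"}
_STRING_VRS = {"UI", "SH", "LO", "CS", "DA", "TM", "IS", "DS", "ST", "PN", "LT", "AE"}

Value = Union[str, list[str], bytes, int, list["Dataset"]]


class DicomError(ValueError):
    """Raised on malformed or unsupported DICOM input."""


@dataclass
class Dataset:
    """An ordered mapping of tag -> (vr, value)."""

    elements: dict[Tag, tuple[str, Value]] = field(default_factory=dict)

    def set(self, tag: Tag, vr: str, value: Value) -> None:
        self.elements[tag] = (vr, value)

    def __contains__(self, tag: Tag) -> bool:
        return tag in self.elements

    def get(self, tag: Tag, default=None):
        if tag in self.elements:
            return self.elements[tag][1]
        return default

    def __getitem__(self, tag: Tag) -> Value:
        try:
            return self.elements[tag][1]
        except KeyError:
            raise KeyError(f"missing tag ({tag[0]:04X},{tag[1]:04X})") from None

    # -- typed accessors -------------------------------------------------
    def get_str(self, tag: Tag, default: str | None = None) -> str | None:
        v = self.get(tag, default)
        if isinstance(v, list):
            v = v[0] if v else default
        return v if v is None else str(v).strip()

    def get_floats(self, tag: Tag) -> list[float]:
        v = self[tag]
        if isinstance(v, str):
            v = v.split("\\")
        return [float(x) for x in v]

    def get_float(self, tag: Tag, default: float | None = None) -> float | None:
        if tag not in self:
            return default
        return self.get_floats(tag)[0]

    def get_int(self, tag: Tag, default: int | None = None) -> int | None:
        if tag not in self:
            return default
        v = self[tag]
        if isinstance(v, list):
            v = v[0]
        return int(str(v).strip())


def _encode_value(vr: str, value: Value) -> bytes:
    if vr == "SQ":
        out = b""
        for item in value:  # type: ignore[union-attr]
            body = _encode_dataset(item)
            out += struct.pack("<HHI", *_ITEM, len(body)) + body
        return out
    if vr == "UL":
        return struct.pack("<I", int(value))  # type: ignore[arg-type]
    if vr == "US":
        return struct.pack("<H", int(value))  # type: ignore[arg-type]
    if vr == "OB":
        data = bytes(value)  # type: ignore[arg-type]
        return data + (b"\x00" if len(data) % 2 else b"")
    if vr in _STRING_VRS:
        if isinstance(value, list):
            value = "\\".join(str(v) for v in value)
        data = str(value).encode("ascii")
        if len(data) % 2:
            data += b"\x00" if vr == "UI" else b" "
        return data
    raise DicomError(f"unsupported VR for encoding: {vr}")


def _encode_element(tag: Tag, vr: str, value: Value) -> bytes:
    body = _encode_value(vr, value)
    head = struct.pack("<HH", *tag) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(body)) + body
    if len(body) > 0xFFFF:
        raise DicomError(f"value too long for short-form VR {vr}")
    return head + struct.pack("<H", len(body)) + body


def _encode_dataset(ds: Dataset) -> bytes:
    return b"".join(
        _encode_element(tag, vr, value)
        for tag, (vr, value) in sorted(ds.elements.items())
    )


def write_file(path, ds: Dataset, sop_instance_uid: str) -> None:
    """Write *ds* as a Part-10 file with explicit VR LE transfer syntax."""
    meta = Dataset()
    meta.set((0x0002, 0x0001), "OB", b"\x00\x01")
    meta.set((0x0002, 0x0002), "UI", SOP_CLASS_RTPLAN)
    meta.set((0x0002, 0x0003), "UI", sop_instance_uid)
    meta.set((0x0002, 0x0010), "UI", TRANSFER_SYNTAX_EXPLICIT_LE)
    meta.set((0x0002, 0x0012), "UI", IMPLEMENTATION_UID)
    meta_body = _encode_dataset(meta)
    group_len = _encode_element((0x0002, 0x0000), "UL", len(meta_body))
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(group_len)
        fh.write(meta_body)
        fh.write(_encode_dataset(ds))


def _parse_elements(buf: bytes, pos: int, end: int) -> tuple[Dataset, int]:
    ds = Dataset()
    while pos < end:
        if end - pos < 8:
            raise DicomError("truncated data element header")
        group, elem = struct.unpack_from("<HH", buf, pos)
        tag = (group, elem)
        if tag == _ITEM_DELIM or tag == _SEQ_DELIM:
            return ds, pos
        vr = buf[pos + 4 : pos + 6].decode("ascii", errors="replace")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            pos += 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            pos += 8
        if vr == "SQ":
            items, pos = _parse_sequence(buf, pos, length)
            ds.set(tag, vr, items)
            continue
        if length == 0xFFFFFFFF:
            raise DicomError("undefined length outside SQ is not supported")
        raw = buf[pos : pos + length]
        pos += length
        if vr == "UL":
            ds.set(tag, vr, struct.unpack("<I", raw)[0])
        elif vr == "US":
            ds.set(tag, vr, struct.unpack("<H", raw)[0])
        elif vr == "OB":
            ds.set(tag, vr, raw)
        elif vr in _STRING_VRS:
            text = raw.decode("ascii", errors="replace").rstrip("\x00 ")
            ds.set(tag, vr, text.split("\\") if "\\" in text else text)
        else:
            # Unknown short VR: keep raw bytes so round-trips do not crash.
            ds.set(tag, "UN", raw)
    return ds, pos


def _parse_sequence(buf: bytes, pos: int, length: int) -> tuple[list[Dataset], int]:
    items: list[Dataset] = []
    end = len(buf) if length == 0xFFFFFFFF else pos + length
    while pos < end:
        group, elem = struct.unpack_from("<HH", buf, pos)
        (item_len,) = struct.unpack_from("<I", buf, pos + 4)
        pos += 8
        if (group, elem) == _SEQ_DELIM:
            return items, pos
        if (group, elem) != _ITEM:
            raise DicomError("expected sequence item tag")
        if item_len == 0xFFFFFFFF:
            item, pos = _parse_elements(buf, pos, end)
            # consume the item delimiter
            pos += 8
        else:
            item, _ = _parse_elements(buf, pos, pos + item_len)
            pos += item_len
        items.append(item)
    return items, pos


def read_file(path) -> Dataset:
    """Parse a Part-10 explicit VR LE file into a :class:`Dataset`."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomError(f"{path}: not a DICOM Part-10 file")
    meta, pos = _parse_meta(buf)
    ts = meta.get_str((0x0002, 0x0010))
    if ts != TRANSFER_SYNTAX_EXPLICIT_LE:
        raise DicomError(f"unsupported transfer syntax {ts!r}")
    ds, _ = _parse_elements(buf, pos, len(buf))
    return ds


def _parse_meta(buf: bytes) -> tuple[Dataset, int]:
    pos = 132
    group, elem = struct.unpack_from("<HH", buf, pos)
    if (group, elem) != (0x0002, 0x0000):
        raise DicomError("file meta group length missing")
    (glen,) = struct.unpack_from("<H", buf, pos + 6)
    if glen != 4:
        raise DicomError("bad file meta group length element")
    (meta_len,) = struct.unpack_from("<I", buf, pos + 8)
    pos += 12
    meta, _ = _parse_elements(buf, pos, pos + meta_len)
    return meta, pos + meta_len
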