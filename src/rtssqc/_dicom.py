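"""Minimal DICOM Part-10 reader/writer (explicit VR little endian).

Implements just enough of the encoding rules for RT Structure Set files:
the 128-byte preamble + "DICM" marker, the file meta group, string/number
VRs, and nested sequences with defined or undefined lengths.  Not a
general DICOM implementation.
"""
from __future__ import annotations

import struct
import uuid
from dataclasses import dataclass, field

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"

# VRs using the 4-byte length layout (2-byte VR + 2 reserved + 4-byte length)
_LONG_VRS = {"OB", "OD", "OF", "OL", "OW", "SQ", "UC", "UN", "UR", "UT"}
# text VRs padded with a trailing space; UI pads with NUL
_SPACE_PADDED = {
    "AE", "AS", "CS", "DA", "DS", "DT", "IS", "LO", "LT", "PN", "SH", "ST", "TM", "UC", "UR", "UT",
}

_ITEM = (0xFFFE, 0xE000)
_ITEM_DELIM = (0xFFFE, 0xE00D)
_SEQ_DELIM = (0xFFFE, 0xE0DD)
_UNDEFINED = 0xFFFFFFFF


class DicomFormatError(Exception):
    pass


@dataclass
class Element:
    tag: tuple[int, int]
    vr: str
    value: bytes | list["Dataset"]


@dataclass
class Dataset:
    """Ordered collection of data elements keyed by (group, element)."""

    elements: dict[tuple[int, int], Element] = field(default_factory=dict)

    def __contains__(self, tag: tuple[int, int]) -> bool:
        return tag in self.elements

    def get(self, tag: tuple[int, int]) -> Element | None:
        return self.elements.get(tag)

    def text(self, tag: tuple[int, int], default: str | None = None) -> str | None:
        el = self.elements.get(tag)
        if el is None or isinstance(el.value, list):
            return default
        return el.value.decode("ascii", errors="replace").rstrip(" \x00")

    def texts(self, tag: tuple[int, int]) -> list[str]:
        t = self.text(tag)
        return [] if t is None or t == "" else t.split("\\")

    def sequence(self, tag: tuple[int, int]) -> list["Dataset"] | None:
        el = self.elements.get(tag)
        if el is None:
            return None
        if not isinstance(el.value, list):
            raise DicomFormatError(f"element {tag} is not a sequence")
        return el.value

    def put_text(self, tag: tuple[int, int], vr: str, value: str) -> None:
        data = value.encode("ascii")
        if len(data) % 2:
            data += b"\x00" if vr == "UI" else b" "
        self.elements[tag] = Element(tag, vr, data)

    def put_sequence(self, tag: tuple[int, int], items: list["Dataset"]) -> None:
        self.elements[tag] = Element(tag, "SQ", items)


def new_uid() -> str:
    """UUID-derived UID under the 2.25 root."""
    return f"2.25.{uuid.uuid4().int}"


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_element(buf: bytes, pos: int) -> tuple[Element | None, int]:
    """One explicit-VR element; returns (element, next position).

    Item/sequence delimitation tags return ``None`` with the position
    advanced past the delimiter.
    """
    if pos + 8 > len(buf):
        raise DicomFormatError("truncated data element")
    group, elem = struct.unpack_from("<HH", buf, pos)
    tag = (group, elem)
    if group == 0xFFFE:  # delimitation items carry no VR
        (length,) = struct.unpack_from("<I", buf, pos + 4)
        if tag in (_ITEM_DELIM, _SEQ_DELIM):
            return None, pos + 8
        raise DicomFormatError(f"unexpected item tag at offset {pos}")
    vr = buf[pos + 4 : pos + 6].decode("ascii", errors="replace")
    if vr in _LONG_VRS:
        (length,) = struct.unpack_from("<I", buf, pos + 8)
        pos += 12
    else:
        (length,) = struct.unpack_from("<H", buf, pos + 6)
        pos += 8
    if vr == "SQ":
        items, pos = _read_sequence(buf, pos, length)
        return Element(tag, vr, items), pos
    if length == _UNDEFINED:
        raise DicomFormatError(f"undefined length on non-SQ element {tag}")
    if pos + length > len(buf):
        raise DicomFormatError(f"element {tag} overruns the file")
    return Element(tag, vr, buf[pos : pos + length]), pos + length


def _read_sequence(buf: bytes, pos: int, length: int) -> tuple[list[Dataset], int]:
    items: list[Dataset] = []
    end = None if length == _UNDEFINED else pos + length
    while True:
        if end is not None and pos >= end:
            break
        if pos + 8 > len(buf):
            raise DicomFormatError("truncated sequence")
        tag = struct.unpack_from("<HH", buf, pos)
        (item_len,) = struct.unpack_from("<I", buf, pos + 4)
        pos += 8
        if tag == _SEQ_DELIM:
            break
        if tag != _ITEM:
            raise DicomFormatError(f"expected sequence item, got {tag}")
        item_end = None if item_len == _UNDEFINED else pos + item_len
        ds = Dataset()
        while True:
            if item_end is not None and pos >= item_end:
                break
            el, pos = _read_element(buf, pos)
            if el is None:  # item delimiter
                break
            ds.elements[el.tag] = el
        items.append(ds)
    return items, pos


def read_file(path) -> Dataset:
    """Parse a Part-10 file (explicit VR little endian only)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomFormatError("not a DICOM Part-10 file (missing DICM marker)")
    pos = 132
    meta = Dataset()
    while pos < len(buf):
        group = struct.unpack_from("<H", buf, pos)[0]
        if group != 0x0002:
            break
        el, pos = _read_element(buf, pos)
        if el is not None:
            meta.elements[el.tag] = el
    ts = meta.text((0x0002, 0x0010))
    if ts is not None and ts != EXPLICIT_VR_LE:
        raise DicomFormatError(f"unsupported transfer syntax {ts!r}")
    ds = Dataset()
    while pos < len(buf):
        el, pos = _read_element(buf, pos)
        if el is not None:
            ds.elements[el.tag] = el
    return ds


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _encode_element(el: Element) -> bytes:
    group, elem = el.tag
    if el.vr == "SQ":
        body = b"".join(_encode_item(item) for item in el.value)
        body += struct.pack("<HHI", *_SEQ_DELIM, 0)
        head = struct.pack("<HH", group, elem) + b"SQ\x00\x00" + struct.pack("<I", _UNDEFINED)
        return head + body
    value = el.value
    assert isinstance(value, bytes)
    if len(value) % 2:
        value += b"\x00" if el.vr == "UI" else b" "
    if el.vr in _LONG_VRS:
        head = (
            struct.pack("<HH", group, elem)
            + el.vr.encode("ascii")
            + b"\x00\x00"
            + struct.pack("<I", len(value))
        )
    else:
        head = (
            struct.pack("<HH", group, elem)
            + el.vr.encode("ascii")
            + struct.pack("<H", len(value))
        )
    return head + value


def _encode_item(ds: Dataset) -> bytes:
    body = _encode_dataset(ds)
    return struct.pack("<HHI", *_ITEM, len(body)) + body


def _encode_dataset(ds: Dataset) -> bytes:
    return b"".join(_encode_element(ds.elements[tag]) for tag in sorted(ds.elements))


def write_file(path, ds: Dataset, sop_class_uid: str, sop_instance_uid: str) -> None:
    """Write ``ds`` as explicit-VR-LE Part 10 with a standard meta header."""
    meta = Dataset()
    meta.elements[(0x0002, 0x0001)] = Element((0x0002, 0x0001), "OB", b"\x00\x01")
    meta.put_text((0x0002, 0x0002), "UI", sop_class_uid)
    meta.put_text((0x0002, 0x0003), "UI", sop_instance_uid)
    meta.put_text((0x0002, 0x0010), "UI", EXPLICIT_VR_LE)
    meta.put_text((0x0002, 0x0012), "UI", "2.25.313710640736939829807636504941979115")
    meta_bytes = _encode_dataset(meta)
    group_len = Element((0x0002, 0x0000), "UL", struct.pack("<I", len(meta_bytes)))
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(_encode_element(group_len))
        fh.write(meta_bytes)
        fh.write(_encode_dataset(ds))
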