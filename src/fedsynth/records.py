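"""Record-file serialization for processed images.

Two containers behind one read/write contract:

* ``.tfrecord`` — TFRecord framing (little-endian length, masked CRC32C of the
  length, payload, masked CRC32C of the payload) around a small protobuf
  wire-format message:

  ===== ========== ======================================
  field wire type  content
  ===== ========== ======================================
  1     bytes      pixel buffer, float32 little-endian
  2     bytes      shape, packed varints
  3     varint     severity label (omitted when unlabeled)
  4     bytes      source_id, UTF-8
  ===== ========== ======================================

* ``.npz`` — a numpy archive holding the same fields.

The container is chosen from the file suffix; round-trips are lossless for
float32 pixels, labels, and record order.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .pipeline import ProcessedImage

__all__ = ["write_records", "read_records", "RecordParseError"]


class RecordParseError(ValueError):
    """Corrupt record file; carries the byte offset of the failure."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


# ---------------------------------------------------------------- crc32c ----

_CRC_TABLE = np.zeros(256, dtype=np.uint32)
for _i in range(256):
    _c = _i
    for _ in range(8):
        _c = (_c >> 1) ^ (0x82F63B78 if _c & 1 else 0)
    _CRC_TABLE[_i] = _c


def _crc32c(data: bytes) -> int:
    crc = np.uint32(0xFFFFFFFF)
    table = _CRC_TABLE
    for b in np.frombuffer(data, dtype=np.uint8):
        crc = table[(crc ^ b) & np.uint32(0xFF)] ^ (crc >> np.uint32(8))
    return int(crc ^ np.uint32(0xFFFFFFFF))


def _masked_crc(data: bytes) -> int:
    crc = _crc32c(data)
    return ((((crc >> 15) | (crc << 17)) + 0xA282EAD8) & 0xFFFFFFFF)


# ------------------------------------------------------- protobuf wiring ----


def _varint(n: int) -> bytes:
    out = bytearray()
    while True:
        b = n & 0x7F
        n >>= 7
        if n:
            out.append(b | 0x80)
        else:
            out.append(b)
            return bytes(out)


def _read_varint(buf: bytes, pos: int) -> tuple[int, int]:
    result = shift = 0
    while True:
        if pos >= len(buf):
            raise RecordParseError("truncated varint", pos)
        b = buf[pos]
        pos += 1
        result |= (b & 0x7F) << shift
        if not b & 0x80:
            return result, pos
        shift += 7


def _encode_payload(img: ProcessedImage) -> bytes:
    pix = np.ascontiguousarray(img.pixels, dtype="<f4").tobytes()
    shape = b"".join(_varint(s) for s in img.pixels.shape)
    sid = img.source_id.encode()
    out = bytearray()
    out += _varint((1 << 3) | 2) + _varint(len(pix)) + pix
    out += _varint((2 << 3) | 2) + _varint(len(shape)) + shape
    if img.label is not None:
        out += _varint((3 << 3) | 0) + _varint(int(img.label))
    out += _varint((4 << 3) | 2) + _varint(len(sid)) + sid
    return bytes(out)


def _decode_payload(buf: bytes, base_offset: int) -> ProcessedImage:
    pix = shape = None
    label = None
    sid = ""
    pos = 0
    while pos < len(buf):
        tag, pos = _read_varint(buf, pos)
        field, wire = tag >> 3, tag & 7
        if wire == 2:
            length, pos = _read_varint(buf, pos)
            if pos + length > len(buf):
                raise RecordParseError("truncated field", base_offset + pos)
            chunk = buf[pos : pos + length]
            pos += length
            if field == 1:
                pix = chunk
            elif field == 2:
                shape, p = [], 0
                while p < len(chunk):
                    s, p = _read_varint(chunk, p)
                    shape.append(s)
            elif field == 4:
                sid = chunk.decode()
        elif wire == 0:
            val, pos = _read_varint(buf, pos)
            if field == 3:
                label = int(val)
        else:
            raise RecordParseError(f"unsupported wire type {wire}", base_offset + pos)
    if pix is None or shape is None:
        raise RecordParseError("record missing pixel or shape field", base_offset)
    arr = np.frombuffer(pix, dtype="<f4").astype(np.float32)
    if arr.size != int(np.prod(shape)):
        raise RecordParseError("pixel buffer does not match shape", base_offset)
    return ProcessedImage(arr.reshape(shape), label=label, source_id=sid)


# ------------------------------------------------------------- public API ---


def write_records(path: str | os.PathLike, images: list[ProcessedImage]) -> int:
    """Serialize ``images``; returns the record count written."""
    path = Path(path)
    if path.suffix == ".npz":
        arrays: dict[str, np.ndarray] = {"n": np.array(len(images))}
        for i, img in enumerate(images):
            arrays[f"pix{i}"] = img.pixels.astype(np.float32)
            arrays[f"label{i}"] = np.array(-1 if img.label is None else int(img.label))
            arrays[f"sid{i}"] = np.array(img.source_id)
        np.savez(path, **arrays)
        return len(images)
    with open(path, "wb") as fh:
        for img in images:
            payload = _encode_payload(img)
            length = len(payload).to_bytes(8, "little")
            fh.write(length)
            fh.write(_masked_crc(length).to_bytes(4, "little"))
            fh.write(payload)
            fh.write(_masked_crc(payload).to_bytes(4, "little"))
    return len(images)


def read_records(path: str | os.PathLike) -> list[ProcessedImage]:
    """Read a record file written by :func:`write_records` (order preserved)."""
    path = Path(path)
    if path.suffix == ".npz":
        out = []
        with np.load(path) as z:
            for i in range(int(z["n"])):
                label = int(z[f"label{i}"])
                out.append(ProcessedImage(z[f"pix{i}"].astype(np.float32),
                                          label=None if label < 0 else label,
                                          source_id=str(z[f"sid{i}"])))
        return out
    data = path.read_bytes()
    out = []
    pos = 0
    while pos < len(data):
        if pos + 12 > len(data):
            raise RecordParseError("truncated record header", pos)
        length = int.from_bytes(data[pos : pos + 8], "little")
        if _masked_crc(data[pos : pos + 8]) != int.from_bytes(data[pos + 8 : pos + 12], "little"):
            raise RecordParseError("length CRC mismatch", pos)
        start = pos + 12
        if start + length + 4 > len(data):
            raise RecordParseError("truncated record payload", start)
        payload = data[start : start + length]
        if _masked_crc(payload) != int.from_bytes(data[start + length : start + length + 4], "little"):
            raise RecordParseError("payload CRC mismatch", start)
        out.append(_decode_payload(payload, start))
        pos = start + length + 4
    return out
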