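"""Minimal single-frame monochrome DICOM reader/writer.

Supports exactly what this pipeline needs: uncompressed Explicit/Implicit VR
Little Endian, one frame, MONOCHROME1/2, 8- or 16-bit unsigned or signed
integers, with rescale slope/intercept applied on read.  Sequences,
compressed transfer syntaxes and multi-frame objects are out of scope and
rejected with :class:`DicomFormatError`.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
IMPLICIT_VR_LE = "1.2.840.10008.1.2"
SECONDARY_CAPTURE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"

# VRs whose explicit encoding carries a 2-byte reserved field + 4-byte length
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

_TAG_TRANSFER_SYNTAX = (0x0002, 0x0010)
_TAG_ROWS = (0x0028, 0x0010)
_TAG_COLS = (0x0028, 0x0011)
_TAG_BITS_ALLOCATED = (0x0028, 0x0100)
_TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
_TAG_PHOTOMETRIC = (0x0028, 0x0004)
_TAG_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
_TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
_TAG_RESCALE_SLOPE = (0x0028, 0x1053)
_TAG_PIXEL_DATA = (0x7FE0, 0x0010)


class DicomFormatError(ValueError):
    pass


def _parse_elements(buf: bytes, offset: int, explicit: bool) -> dict[tuple[int, int], bytes]:
    elements: dict[tuple[int, int], bytes] = {}
    n = len(buf)
    while offset + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, offset)
        offset += 4
        if explicit or group == 0x0002:  # file meta is always explicit
            vr = buf[offset : offset + 2]
            if vr in _LONG_VRS:
                (length,) = struct.unpack_from("<I", buf, offset + 4)
                offset += 8
            else:
                (length,) = struct.unpack_from("<H", buf, offset + 2)
                offset += 4
            if vr == b"SQ":
                raise DicomFormatError("sequences are not supported")
        else:
            (length,) = struct.unpack_from("<I", buf, offset)
            offset += 4
        if length == 0xFFFFFFFF:
            raise DicomFormatError("undefined-length elements are not supported")
        if offset + length > n:
            raise DicomFormatError("truncated element")
        elements[(group, elem)] = buf[offset : offset + length]
        offset += length
    return elements


def _ascii(value: bytes) -> str:
    return value.decode("ascii").strip().rstrip("\x00")


def _us(value: bytes) -> int:
    return struct.unpack("<H", value[:2])[0]


def read_dicom(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a single-frame monochrome DICOM; return (pixels, header dict).

    Pixels are float64 with rescale slope/intercept applied.
    """
    buf = Path(path).read_bytes()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise DicomFormatError(f"{path}: missing DICM magic")
    # file meta group: always explicit VR LE; parse it alone first
    offset = 132
    meta_end = offset
    n = len(buf)
    while meta_end + 8 <= n:
        group = struct.unpack_from("<H", buf, meta_end)[0]
        if group != 0x0002:
            break
        vr = buf[meta_end + 6 : meta_end + 8]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, meta_end + 8)
            meta_end += 12 + length
        else:
            (length,) = struct.unpack_from("<H", buf, meta_end + 6)
            meta_end += 8 + length
    meta = _parse_elements(buf[offset:meta_end], 0, explicit=True)
    syntax = _ascii(meta.get(_TAG_TRANSFER_SYNTAX, EXPLICIT_VR_LE.encode()))
    if syntax == EXPLICIT_VR_LE:
        explicit = True
    elif syntax == IMPLICIT_VR_LE:
        explicit = False
    else:
        raise DicomFormatError(f"unsupported transfer syntax {syntax!r}")
    ds = _parse_elements(buf, meta_end, explicit=explicit)

    photometric = _ascii(ds.get(_TAG_PHOTOMETRIC, b"MONOCHROME2"))
    if photometric not in ("MONOCHROME1", "MONOCHROME2"):
        raise DicomFormatError(f"unsupported photometric interpretation {photometric!r}")
    samples = _us(ds.get(_TAG_SAMPLES_PER_PIXEL, b"\x01\x00"))
    if samples != 1:
        raise DicomFormatError(f"expected 1 sample per pixel, got {samples}")
    rows = _us(ds[_TAG_ROWS])
    cols = _us(ds[_TAG_COLS])
    bits = _us(ds.get(_TAG_BITS_ALLOCATED, b"\x08\x00"))
    signed = _us(ds.get(_TAG_PIXEL_REPRESENTATION, b"\x00\x00")) == 1
    if bits == 8:
        dtype = np.int8 if signed else np.uint8
    elif bits == 16:
        dtype = np.int16 if signed else np.uint16
    else:
        raise DicomFormatError(f"unsupported bits allocated: {bits}")
    raw = np.frombuffer(ds[_TAG_PIXEL_DATA], dtype=dtype, count=rows * cols)
    pixels = raw.reshape(rows, cols).astype(np.float64)
    slope = float(_ascii(ds.get(_TAG_RESCALE_SLOPE, b"1"))) if _TAG_RESCALE_SLOPE in ds else 1.0
    intercept = (
        float(_ascii(ds.get(_TAG_RESCALE_INTERCEPT, b"0"))) if _TAG_RESCALE_INTERCEPT in ds else 0.0
    )
    pixels = pixels * slope + intercept
    header = {
        "rows": rows,
        "columns": cols,
        "bits_allocated": bits,
        "photometric": photometric,
        "rescale_slope": slope,
        "rescale_intercept": intercept,
        "transfer_syntax": syntax,
    }
    return pixels, header


def read_dicom_image(path: str | Path) -> np.ndarray:
    pixels, _ = read_dicom(path)
    return pixels


def _encode_element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr in _LONG_VRS or vr in (b"US", b"UL") else b" "
    head = struct.pack("<HH", group, elem)
    if vr in _LONG_VRS:
        return head + vr + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + vr + struct.pack("<H", len(value)) + value


def write_dicom(
    path: str | Path,
    pixels: np.ndarray,
    rescale_slope: float = 1.0,
    rescale_intercept: float = 0.0,
    sop_instance_uid: str = "1.2.826.0.1.3680043.9999.1",
) -> None:
    """Write an 8-bit MONOCHROME2 secondary-capture style DICOM file."""
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError("pixels must be 2-D")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("pixels must fit in 8 bits for DICOM export")
        arr = arr.astype(np.uint8)
    rows, cols = arr.shape

    def ui(s: str) -> bytes:
        return s.encode("ascii")

    meta_body = _encode_element(0x0002, 0x0002, b"UI", ui(SECONDARY_CAPTURE_SOP_CLASS))
    meta_body += _encode_element(0x0002, 0x0003, b"UI", ui(sop_instance_uid))
    meta_body += _encode_element(0x0002, 0x0010, b"UI", ui(EXPLICIT_VR_LE))
    meta = _encode_element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta_body))) + meta_body

    ds = b""
    ds += _encode_element(0x0008, 0x0016, b"UI", ui(SECONDARY_CAPTURE_SOP_CLASS))
    ds += _encode_element(0x0008, 0x0018, b"UI", ui(sop_instance_uid))
    ds += _encode_element(0x0028, 0x0002, b"US", struct.pack("<H", 1))
    ds += _encode_element(0x0028, 0x0004, b"CS", b"MONOCHROME2")
    ds += _encode_element(0x0028, 0x0010, b"US", struct.pack("<H", rows))
    ds += _encode_element(0x0028, 0x0011, b"US", struct.pack("<H", cols))
    ds += _encode_element(0x0028, 0x0100, b"US", struct.pack("<H", 8))
    ds += _encode_element(0x0028, 0x0101, b"US", struct.pack("<H", 8))
    ds += _encode_element(0x0028, 0x0102, b"US", struct.pack("<H", 7))
    ds += _encode_element(0x0028, 0x0103, b"US", struct.pack("<H", 0))
    if rescale_slope != 1.0 or rescale_intercept != 0.0:
        ds += _encode_element(0x0028, 0x1052, b"DS", f"{rescale_intercept:g}".encode())
        ds += _encode_element(0x0028, 0x1053, b"DS", f"{rescale_slope:g}".encode())
    ds += _encode_element(0x7FE0, 0x0010, b"OB", arr.tobytes())

    Path(path).write_bytes(b"\x00" * 128 + b"DICM" + meta + ds)
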