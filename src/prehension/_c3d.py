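"""Minimal C3D point-data codec (Intel byte order, floating-point storage).

Covers the subset of the C3D standard needed for fingertip-marker trials:
the 512-byte header, the parameter section (only ``POINT`` group parameters
are interpreted: ``LABELS``, ``RATE``, ``USED``), and floating-point 3-D
point frames with a per-sample residual word (negative residual = sample
not tracked).  Analog channels and integer-scaled point storage are not
supported and raise a format error.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

BLOCK = 512
PROC_INTEL = 84


class C3DFormatError(ValueError):
    pass


@dataclass
class PointData:
    labels: list[str]
    points: np.ndarray  # (n_markers, n_frames, 3) mm
    residuals: np.ndarray  # (n_markers, n_frames)
    rate: float


def read_c3d(path: Path) -> PointData:
    raw = Path(path).read_bytes()
    if len(raw) < 2 * BLOCK:
        raise C3DFormatError("file too short for a C3D")
    param_block = raw[0]
    if raw[1] != 0x50:
        raise C3DFormatError("missing C3D magic byte 0x50")
    n_points, analog_per_frame, first_frame, last_frame = struct.unpack_from(
        "<4H", raw, 2
    )
    (scale,) = struct.unpack_from("<f", raw, 12)
    (data_block,) = struct.unpack_from("<H", raw, 16)
    (rate,) = struct.unpack_from("<f", raw, 20)
    if scale >= 0:
        raise C3DFormatError("integer-scaled C3D point data is not supported")
    if analog_per_frame:
        raise C3DFormatError("analog channels are not supported")
    n_frames = last_frame - first_frame + 1

    labels = _read_labels(raw, param_block, n_points)

    offset = (data_block - 1) * BLOCK
    words = n_points * 4 * n_frames
    vals = np.frombuffer(raw, dtype="<f4", count=words, offset=offset)
    frames = vals.reshape(n_frames, n_points, 4)
    points = np.transpose(frames[:, :, :3], (1, 0, 2)).astype(float)
    residuals = frames[:, :, 3].T.astype(float)
    return PointData(labels=labels, points=points, residuals=residuals, rate=float(rate))


def _read_labels(raw: bytes, param_block: int, n_points: int) -> list[str]:
    start = (param_block - 1) * BLOCK
    proc = raw[start + 3]
    if proc not in (0, PROC_INTEL):
        raise C3DFormatError(f"unsupported processor type {proc}")
    pos = start + 4
    group_ids: dict[int, str] = {}
    params: dict[tuple[int, str], tuple[int, list[int], bytes]] = {}
    while pos < len(raw):
        n_name = struct.unpack_from("<b", raw, pos)[0]
        if n_name == 0:
            break
        gid = struct.unpack_from("<b", raw, pos + 1)[0]
        name = raw[pos + 2 : pos + 2 + abs(n_name)].decode("ascii", "replace")
        p = pos + 2 + abs(n_name)
        (offset,) = struct.unpack_from("<h", raw, p)
        next_pos = p + offset
        p += 2
        if gid < 0:
            group_ids[-gid] = name.upper()
        else:
            etype = struct.unpack_from("<b", raw, p)[0]
            ndim = struct.unpack_from("<B", raw, p + 1)[0]
            dims = [raw[p + 2 + k] for k in range(ndim)]
            dstart = p + 2 + ndim
            count = int(np.prod(dims)) if dims else 1
            nbytes = count * abs(etype)
            params[(gid, name.upper())] = (etype, dims, raw[dstart : dstart + nbytes])
        if offset == 0:
            break
        pos = next_pos
    point_gid = next((g for g, nm in group_ids.items() if nm == "POINT"), None)
    if point_gid is None or (point_gid, "LABELS") not in params:
        # fall back to generic names
        return [f"M{i + 1}" for i in range(n_points)]
    etype, dims, data = params[(point_gid, "LABELS")]
    if etype != -1 or len(dims) != 2:
        raise C3DFormatError("POINT:LABELS must be a 2-D char array")
    w, n = dims
    labels = [
        data[i * w : (i + 1) * w].decode("ascii", "replace").strip()
        for i in range(min(n, n_points))
    ]
    while len(labels) < n_points:
        labels.append(f"M{len(labels) + 1}")
    return labels


# ---------------------------------------------------------------------------
# Writer (used to synthesize fixtures and round-trip tests)
# ---------------------------------------------------------------------------

def _param_record(name: bytes, gid: int, body: bytes, last: bool) -> bytes:
    head = struct.pack("<bb", len(name), gid) + name
    offset = 0 if last else 2 + len(body)
    return head + struct.pack("<h", offset) + body


def write_c3d(
    path: Path,
    labels: list[str],
    points: np.ndarray,
    residuals: np.ndarray,
    rate: float,
) -> None:
    """Write floating-point C3D point data (no analog channels)."""
    points = np.asarray(points, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    n_markers, n_frames, _ = points.shape
    if residuals.shape != (n_markers, n_frames):
        raise ValueError("residuals shape mismatch")

    # parameter section: one POINT group with USED, RATE, FRAMES, LABELS
    width = max(4, max(len(s) for s in labels))
    label_blob = b"".join(s.ljust(width).encode("ascii") for s in labels)
    records = [
        _param_record(b"POINT", -1, struct.pack("<B", 0), last=False),
        _param_record(
            b"USED", 1, struct.pack("<bB", 2, 0) + struct.pack("<h", n_markers), last=False
        ),
        _param_record(
            b"RATE", 1, struct.pack("<bB", 4, 0) + struct.pack("<f", rate), last=False
        ),
        _param_record(
            b"FRAMES", 1, struct.pack("<bB", 2, 0) + struct.pack("<h", min(n_frames, 32767)),
            last=False,
        ),
        _param_record(
            b"LABELS",
            1,
            struct.pack("<bBBB", -1, 2, width, len(labels)) + label_blob,
            last=True,
        ),
    ]
    param = b"\x01\x50\x00" + bytes([PROC_INTEL]) + b"".join(records)
    n_param_blocks = -(-len(param) // BLOCK)
    param = param[:2] + bytes([n_param_blocks]) + param[3:]
    param = param.ljust(n_param_blocks * BLOCK, b"\x00")

    data_block = 2 + n_param_blocks  # header=1, params next, data after
    header = bytearray(BLOCK)
    header[0] = 2  # parameter section starts at block 2
    header[1] = 0x50
    struct.pack_into("<4H", header, 2, n_markers, 0, 1, n_frames)
    struct.pack_into("<f", header, 12, -1.0)  # negative scale -> float data
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<f", header, 20, rate)

    frames = np.empty((n_frames, n_markers, 4), dtype="<f4")
    frames[:, :, :3] = np.transpose(points, (1, 0, 2))
    frames[:, :, 3] = residuals.T
    blob = frames.tobytes()
    blob = blob.ljust(-(-len(blob) // BLOCK) * BLOCK, b"\x00")
    Path(path).write_bytes(bytes(header) + param + blob)
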