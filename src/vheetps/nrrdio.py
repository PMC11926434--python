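"""Minimal NRRD (NRRD0004) reader/writer for 3-D raw little-endian volumes.

Supports exactly the subset this package writes: detached-header-free files
with `type` in {uint8, int16, float32, float64}, `encoding: raw`,
`endian: little`, diagonal `space directions` and a `space origin`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple, Union

import numpy as np

_TYPE_MAP = {
    "uint8": np.uint8,
    "int16": np.int16,
    "float32": np.float32,
    "float64": np.float64,
}
_INV_TYPE_MAP = {np.dtype(v): k for k, v in _TYPE_MAP.items()}


class NrrdError(IOError):
    pass


def write_nrrd(
    path: Union[str, Path],
    array: np.ndarray,
    spacing_mm: Tuple[float, float, float],
    origin_mm: Tuple[float, float, float],
) -> None:
    array = np.ascontiguousarray(array)
    if array.ndim != 3:
        raise NrrdError("only 3-D volumes are supported")
    if array.dtype not in _INV_TYPE_MAP:
        raise NrrdError(f"unsupported dtype {array.dtype}")
    sx, sy, sz = (float(s) for s in spacing_mm)
    ox, oy, oz = (float(o) for o in origin_mm)
    header = (
        "NRRD0004\n"
        f"type: {_INV_TYPE_MAP[array.dtype]}\n"
        "dimension: 3\n"
        "space: left-posterior-superior\n"
        f"sizes: {array.shape[0]} {array.shape[1]} {array.shape[2]}\n"
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})\n"
        f"space origin: ({ox},{oy},{oz})\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        # NRRD raw payload is fastest-axis-first; write Fortran order so the
        # first `sizes` axis varies fastest.
        fh.write(np.asfortranarray(array).tobytes(order="F"))


def _parse_vector(text: str) -> Tuple[float, ...]:
    return tuple(float(x) for x in text.strip().lstrip("(").rstrip(")").split(","))


def read_nrrd(path: Union[str, Path]):
    """Read a volume; returns (array, spacing_mm, origin_mm)."""
    path = Path(path)
    raw = path.read_bytes()
    end = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or end < 0:
        raise NrrdError(f"{path}: not a NRRD file")
    fields = {}
    for line in raw[:end].decode("ascii").splitlines()[1:]:
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()

    for key in ("type", "sizes", "encoding"):
        if key not in fields:
            raise NrrdError(f"{path}: missing header field {key!r}")
    if fields["encoding"] != "raw":
        raise NrrdError(f"{path}: unsupported encoding {fields['encoding']!r}")
    if fields.get("endian", "little") != "little":
        raise NrrdError(f"{path}: unsupported endian {fields['endian']!r}")
    if fields["type"] not in _TYPE_MAP:
        raise NrrdError(f"{path}: unsupported type {fields['type']!r}")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    if len(sizes) != 3:
        raise NrrdError(f"{path}: expected 3-D sizes, got {fields['sizes']!r}")

    spacing = (1.0, 1.0, 1.0)
    if "space directions" in fields:
        vecs = [_parse_vector(v) for v in fields["space directions"].split(") (")]
        spacing = tuple(vecs[i][i] for i in range(3))
    origin = (0.0, 0.0, 0.0)
    if "space origin" in fields:
        origin = _parse_vector(fields["space origin"])

    dtype = np.dtype(_TYPE_MAP[fields["type"]])
    payload = raw[end + 2 :]
    expected = int(np.prod(sizes)) * dtype.itemsize
    if len(payload) != expected:
        raise NrrdError(f"{path}: payload size {len(payload)} != expected {expected}")
    array = np.frombuffer(payload, dtype=dtype).reshape(sizes, order="F").copy()
    return array, spacing, origin
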