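"""PLY vertex I/O for intraoral-scan point clouds.

Reads and writes the Polygon File Format restricted to what the pipeline
needs: a ``vertex`` element with float ``x, y, z`` and optional
``nx, ny, nz`` properties, in the ``ascii`` or ``binary_little_endian``
dialects (the dialects produced by iTero-style scanner exports and by this
package itself).  Faces, colours and any other elements or properties are
skipped; big-endian files are rejected with a clear error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .cloud import PointCloud, normalize_rows

__all__ = ["read_ply", "write_ply", "PlyParseError"]

log = logging.getLogger(__name__)

_PLY_TO_NUMPY = {
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
}


class PlyParseError(ValueError):
    """Raised for a malformed PLY header or body."""


def _parse_header(fh) -> tuple[str, list[tuple[str, int, list[tuple[str, str]]]]]:
    """Returns (format, [(element_name, count, [(prop_name, dtype), ...]), ...])."""
    magic = fh.readline().strip()
    if magic != b"ply":
        raise PlyParseError("not a PLY file: missing 'ply' magic")
    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    while True:
        line = fh.readline()
        if not line:
            raise PlyParseError("unexpected end of file in header")
        tokens = line.decode("ascii", errors="replace").split()
        if not tokens or tokens[0] == "comment":
            continue
        if tokens[0] == "format":
            if tokens[1] == "binary_big_endian":
                raise PlyParseError("binary_big_endian PLY is not supported")
            if tokens[1] not in ("ascii", "binary_little_endian"):
                raise PlyParseError(f"unknown PLY format {tokens[1]!r}")
            fmt = tokens[1]
        elif tokens[0] == "element":
            elements.append((tokens[1], int(tokens[2]), []))
        elif tokens[0] == "property":
            if not elements:
                raise PlyParseError("property before any element")
            if tokens[1] == "list":
                # list property (e.g. face indices); record a marker
                elements[-1][2].append((tokens[-1], f"list:{tokens[2]}:{tokens[3]}"))
            else:
                if tokens[1] not in _PLY_TO_NUMPY:
                    raise PlyParseError(f"unknown property type {tokens[1]!r}")
                elements[-1][2].append((tokens[2], _PLY_TO_NUMPY[tokens[1]]))
        elif tokens[0] == "end_header":
            break
        else:
            raise PlyParseError(f"unrecognized header line: {' '.join(tokens)!r}")
    if fmt is None:
        raise PlyParseError("header has no 'format' line")
    return fmt, elements


def _read_element_ascii(fh, count: int, props: list[tuple[str, str]]) -> np.ndarray:
    rows = []
    for i in range(count):
        line = fh.readline()
        if not line:
            raise PlyParseError(f"vertex element truncated at row {i}")
        parts = line.split()
        if len(parts) < len(props):
            raise PlyParseError(f"vertex row {i} has {len(parts)} values, expected {len(props)}")
        rows.append(parts[: len(props)])
    dtype = np.dtype([(name, "f8") for name, _ in props])
    try:
        arr = np.array([[float(x) for x in row] for row in rows], dtype=np.float64)
    except ValueError as exc:
        raise PlyParseError(f"non-numeric value in vertex element: {exc}") from exc
    out = np.empty(count, dtype=dtype)
    for j, (name, _) in enumerate(props):
        out[name] = arr[:, j]
    return out


def _skip_element_ascii(fh, count: int) -> None:
    for _ in range(count):
        fh.readline()


def read_ply(path: str | Path) -> PointCloud:
    """Read a PLY file into a :class:`PointCloud`.

    Vertices are returned in file order.  Normals are populated iff the
    vertex element carries ``nx, ny, nz`` properties; they are re-normalized
    to unit length on load.  All other elements (faces, edges) and vertex
    properties (colour, quality, ...) are ignored.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        fmt, elements = _parse_header(fh)
        vertex_data = None
        for name, count, props in elements:
            is_vertex = name == "vertex"
            if is_vertex and any(dt.startswith("list:") for _, dt in props):
                raise PlyParseError("list property on vertex element is not supported")
            if fmt == "ascii":
                if is_vertex:
                    vertex_data = _read_element_ascii(fh, count, props)
                else:
                    _skip_element_ascii(fh, count)
            else:
                if any(dt.startswith("list:") for _, dt in props):
                    if is_vertex:  # pragma: no cover - guarded above
                        raise PlyParseError("list property on vertex element")
                    # cannot compute a fixed stride past a list element; stop if
                    # the vertex element was already read, else fail
                    if vertex_data is not None:
                        break
                    raise PlyParseError(
                        f"element {name!r} with list properties precedes vertex element"
                    )
                dtype = np.dtype([(pname, "<" + dt) for pname, dt in props])
                buf = fh.read(dtype.itemsize * count)
                if len(buf) != dtype.itemsize * count:
                    raise PlyParseError(f"element {name!r} truncated")
                if is_vertex:
                    vertex_data = np.frombuffer(buf, dtype=dtype)
    if vertex_data is None:
        raise PlyParseError("no vertex element in file")
    names = vertex_data.dtype.names
    for c in ("x", "y", "z"):
        if c not in names:
            raise PlyParseError(f"vertex element lacks required property {c!r}")
    skipped = [n for n in names if n not in ("x", "y", "z", "nx", "ny", "nz")]
    if skipped:
        log.debug("skipping vertex properties %s in %s", skipped, path)
    pts = np.column_stack([vertex_data[c].astype(np.float64) for c in ("x", "y", "z")])
    if not np.all(np.isfinite(pts)):
        raise PlyParseError("vertex element contains non-finite coordinates")
    normals = None
    if all(c in names for c in ("nx", "ny", "nz")):
        normals = np.column_stack(
            [vertex_data[c].astype(np.float64) for c in ("nx", "ny", "nz")]
        )
        norms = np.linalg.norm(normals, axis=1)
        if np.any(norms == 0):
            raise PlyParseError("vertex element contains a zero-length normal")
        # renormalize only when needed so unit normals round-trip bit-for-bit
        off = np.abs(norms - 1.0) > 1e-9
        normals[off] /= norms[off, None]
    return PointCloud(pts, normals, label=path.stem)


def write_ply(cloud: PointCloud, path: str | Path, binary: bool = True) -> None:
    """Write ``cloud`` to ``path`` as PLY.

    Binary little-endian (default) round-trips coordinates bit-for-bit;
    ascii mode prints 17 significant digits (lossless for float64 in
    practice).  Normals are written iff present.
    """
    path = Path(path)
    n = len(cloud)
    props = ["x", "y", "z"] + (["nx", "ny", "nz"] if cloud.has_normals else [])
    header = ["ply"]
    header.append("format binary_little_endian 1.0" if binary else "format ascii 1.0")
    header.append(f"element vertex {n}")
    header.extend(f"property double {p}" for p in props)
    header.append("end_header")
    data = (
        np.hstack([cloud.points, cloud.normals])
        if cloud.has_normals
        else cloud.points
    )
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(np.ascontiguousarray(data, dtype="<f8").tobytes())
        else:
            np.savetxt(fh, data, fmt="%.17g")
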