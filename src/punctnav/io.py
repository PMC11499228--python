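"""Readers and writers for the formats the pipeline exchanges.

Point clouds travel as PLY (ASCII or binary little-endian; the per-vertex
``quality`` property carries scalar values such as drift distances) or as
whitespace-delimited XYZ text. Meshes travel as STL or PLY (via trimesh);
the heat-map export writes PLY with per-vertex quality and an 8-bit colour
ramp. Volumes are NIfTI (.nii / .nii.gz) via nibabel.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .geometry import GeometryError, PointCloud, TriMesh, Volume

__all__ = [
    "read_ply",
    "read_point_cloud",
    "write_point_cloud",
    "read_xyz",
    "write_xyz",
    "read_mesh",
    "write_mesh",
    "write_mesh_ply",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
]

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "int8": "i1", "uint8": "u1",
    "short": "i2", "ushort": "u2", "int16": "i2", "uint16": "u2",
    "int": "i4", "uint": "u4", "int32": "i4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def read_ply(path):
    """Parse a PLY file into per-element dictionaries of property arrays.

    Supports ascii and binary_little_endian, scalar properties, and a
    single uniform list property per element (e.g. ``vertex_indices``).
    Returns ``{element_name: {property_name: ndarray}}``.
    """
    raw = Path(path).read_bytes()
    header_end = raw.find(b"end_header")
    if header_end < 0:
        raise GeometryError(f"{path}: not a PLY file (no end_header)")
    header_end = raw.index(b"\n", header_end) + 1
    header = raw[:header_end].decode("ascii").splitlines()
    body = raw[header_end:]

    if header[0].strip() != "ply":
        raise GeometryError(f"{path}: not a PLY file")
    fmt = None
    elements = []  # (name, count, [(prop_name, dtype | ("list", cdt, idt))])
    for line in header[1:]:
        tok = line.split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if tok[1] == "list":
                elements[-1][2].append((tok[4], ("list", _PLY_TYPES[tok[2]], _PLY_TYPES[tok[3]])))
            else:
                elements[-1][2].append((tok[2], _PLY_TYPES[tok[1]]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise GeometryError(f"{path}: unsupported PLY format {fmt!r}")

    out = {}
    if fmt == "ascii":
        text = body.decode("ascii").split("\n")
        row = 0
        for name, count, props in elements:
            cols = {p: [] for p, _ in props}
            for _ in range(count):
                tok = text[row].split()
                row += 1
                i = 0
                for pname, pdt in props:
                    if isinstance(pdt, tuple):
                        n = int(tok[i]); i += 1
                        cols[pname].append([float(x) for x in tok[i:i + n]])
                        i += n
                    else:
                        cols[pname].append(float(tok[i])); i += 1
            out[name] = {
                p: np.array(v) for p, v in cols.items()
            }
    else:
        offset = 0
        for name, count, props in elements:
            has_list = any(isinstance(dt, tuple) for _, dt in props)
            if not has_list:
                dt = np.dtype([(p, "<" + d) for p, d in props])
                arr = np.frombuffer(body, dtype=dt, count=count, offset=offset)
                offset += dt.itemsize * count
                out[name] = {p: np.ascontiguousarray(arr[p]) for p, _ in props}
            else:
                if len(props) != 1:
                    raise GeometryError(f"{path}: mixed list/scalar element unsupported")
                pname, (_, cdt, idt) = props[0]
                cdt = np.dtype("<" + cdt)
                idt = np.dtype("<" + idt)
                rows = []
                for _ in range(count):
                    n = int(np.frombuffer(body, cdt, 1, offset)[0])
                    offset += cdt.itemsize
                    rows.append(np.frombuffer(body, idt, n, offset))
                    offset += idt.itemsize * n
                out[name] = {pname: np.array(rows)}
    return out


def read_point_cloud(path) -> PointCloud:
    """Load a point cloud from PLY or XYZ (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".xyz", ".txt", ".asc"):
        return read_xyz(path)
    data = read_ply(path)
    if "vertex" not in data:
        raise GeometryError(f"{path}: PLY has no vertex element")
    v = data["vertex"]
    pts = np.column_stack([v["x"], v["y"], v["z"]]).astype(float)
    normals = None
    if all(k in v for k in ("nx", "ny", "nz")):
        normals = np.column_stack([v["nx"], v["ny"], v["nz"]]).astype(float)
        # re-normalise: float32 storage degrades unit length
        norms = np.linalg.norm(normals, axis=1)
        normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    scalars = np.asarray(v["quality"], dtype=float) if "quality" in v else None
    return PointCloud(pts, normals, scalars)


def write_point_cloud(cloud: PointCloud, path, binary: bool = True) -> None:
    """Write a point cloud as PLY; scalars go to the ``quality`` property."""
    props = [("x", "f8"), ("y", "f8"), ("z", "f8")]
    cols = [cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]]
    if cloud.normals is not None:
        props += [("nx", "f8"), ("ny", "f8"), ("nz", "f8")]
        cols += [cloud.normals[:, 0], cloud.normals[:, 1], cloud.normals[:, 2]]
    if cloud.scalars is not None:
        props += [("quality", "f8")]
        cols += [cloud.scalars]
    _write_ply_vertices(path, props, cols, faces=None, binary=binary)


_PLY_NAMES = {"f8": "double", "f4": "float", "u1": "uchar", "i4": "int"}


def _write_ply_vertices(path, props, cols, faces=None, binary=True):
    n = len(cols[0])
    buf = _io.BytesIO()
    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0", f"element vertex {n}"]
    header += [f"property {_PLY_NAMES[d]} {p}" for p, d in props]
    if faces is not None:
        header += [f"element face {len(faces)}", "property list uchar int vertex_indices"]
    header += ["end_header"]
    buf.write(("\n".join(header) + "\n").encode("ascii"))
    vdt = np.dtype([(p, "<" + d) for p, d in props])
    varr = np.empty(n, dtype=vdt)
    for (p, _), c in zip(props, cols):
        varr[p] = c
    if binary:
        buf.write(varr.tobytes())
        if faces is not None:
            fdt = np.dtype([("n", "u1"), ("idx", "<i4", (3,))])
            farr = np.empty(len(faces), dtype=fdt)
            farr["n"] = 3
            farr["idx"] = faces
            buf.write(farr.tobytes())
    else:
        for row in varr:
            buf.write((" ".join(_fmt_ascii(row[p], d) for p, d in props) + "\n").encode())
        if faces is not None:
            for f in faces:
                buf.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode())
    Path(path).write_bytes(buf.getvalue())


def _fmt_ascii(v, dtype):
    if dtype in ("u1", "i4"):
        return str(int(v))
    return repr(float(v))


def read_xyz(path) -> PointCloud:
    """Whitespace-delimited x y z (extra columns ignored)."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] < 3:
        raise GeometryError(f"{path}: need at least 3 columns")
    return PointCloud(arr[:, :3])


def write_xyz(cloud: PointCloud, path) -> None:
    np.savetxt(path, cloud.points, fmt="%.9g")


def read_mesh(path) -> TriMesh:
    """Load an STL or PLY mesh."""
    import trimesh

    tm = trimesh.load(str(path), force="mesh", process=False)
    return TriMesh.from_trimesh(tm)


def write_mesh(mesh: TriMesh, path, file_type: str | None = None) -> None:
    """Write STL (binary) or PLY, chosen by extension unless overridden."""
    tm = mesh.to_trimesh()
    tm.export(str(path), file_type=file_type)


def write_mesh_ply(mesh: TriMesh, path, quality=None, colors=None, binary=True) -> None:
    """PLY mesh writer supporting per-vertex quality and uchar RGB colours."""
    props = [("x", "f8"), ("y", "f8"), ("z", "f8")]
    cols = [mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.vertices[:, 2]]
    if quality is not None:
        quality = np.asarray(quality, dtype=float).ravel()
        if len(quality) != len(mesh.vertices):
            raise GeometryError("quality count must equal vertex count")
        props.append(("quality", "f8"))
        cols.append(quality)
    if colors is not None:
        colors = np.asarray(colors, dtype=np.uint8)
        if colors.shape != (len(mesh.vertices), 3):
            raise GeometryError("colors must be (n_vertices, 3) uint8")
        props += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
        cols += [colors[:, 0], colors[:, 1], colors[:, 2]]
    _write_ply_vertices(path, props, cols, faces=mesh.faces, binary=binary)


def read_volume(path) -> Volume:
    """Load a NIfTI volume; spacing/origin from the affine (axis-aligned)."""
    import nibabel as nib

    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    affine = img.affine
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    origin = affine[:3, 3]
    return Volume(values, spacing, origin)


def write_volume(vol: Volume, path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))


def read_landmarks(path):
    """Correspondence file: one ``x y z  x y z`` pair per line (CT then SLI).

    Returns ``(ct_points, sli_points)`` arrays.
    """
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise GeometryError(f"{path}: expected 6 columns (CT xyz, SLI xyz)")
    return arr[:, :3].copy(), arr[:, 3:].copy()


def write_landmarks(ct_points, sli_points, path) -> None:
    ct = np.asarray(ct_points, dtype=float)
    sli = np.asarray(sli_points, dtype=float)
    np.savetxt(path, np.hstack([ct, sli]), fmt="%.9g")
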