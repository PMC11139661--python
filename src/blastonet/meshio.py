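"""Readers and writers for mesh and network files.

Supported mesh formats: Wavefront OBJ (ASCII) and PLY (ASCII and
binary_little_endian on read; ASCII on write).  Polygon faces are
fan-triangulated on read.  An embryo on disk is a directory of per-cell
mesh files; networks are exported as GraphML and two-column CSV edge lists.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import InvalidMeshError
from .meshes import BlastomereMesh, ContactNetwork, Embryo

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_obj",
    "write_obj",
    "read_ply",
    "write_ply",
    "read_embryo_dir",
    "write_embryo_dir",
    "write_network_graphml",
    "write_network_edge_csv",
]

MESH_SUFFIXES = (".obj", ".ply")


def _fan_triangulate(polygons: list[list[int]]) -> np.ndarray:
    faces = []
    for poly in polygons:
        if len(poly) < 3:
            raise InvalidMeshError(f"face with {len(poly)} vertices")
        for k in range(1, len(poly) - 1):
            faces.append((poly[0], poly[k], poly[k + 1]))
    return np.asarray(faces, dtype=np.int64)


# -- OBJ --------------------------------------------------------------------


def read_obj(path: str | Path, cell_id: str | None = None) -> BlastomereMesh:
    path = Path(path)
    vertices: list[list[float]] = []
    polygons: list[list[int]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "v":
            vertices.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = []
            for tok in parts[1:]:
                i = int(tok.split("/")[0])
                idx.append(i - 1 if i > 0 else len(vertices) + i)
            polygons.append(idx)
    if not vertices:
        raise InvalidMeshError(f"{path}: no vertices")
    return BlastomereMesh(
        cell_id=cell_id or path.stem,
        vertices=np.asarray(vertices, dtype=np.float64),
        faces=_fan_triangulate(polygons),
    )


def write_obj(mesh: BlastomereMesh, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# {mesh.cell_id}"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
    for f in mesh.faces:
        lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    path.write_text("\n".join(lines) + "\n")


# -- PLY --------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def read_ply(path: str | Path, cell_id: str | None = None) -> BlastomereMesh:
    path = Path(path)
    data = path.read_bytes()
    end = data.find(b"end_header")
    if not data.startswith(b"ply") or end < 0:
        raise InvalidMeshError(f"{path}: not a PLY file")
    header = data[:end].decode("ascii", errors="replace").splitlines()
    body = data[data.find(b"\n", end) + 1 :]

    fmt = None
    elements: list[tuple[str, int, list]] = []  # (name, count, properties)
    for line in header:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            elements.append((parts[1], int(parts[2]), []))
        elif parts[0] == "property" and elements:
            if parts[1] == "list":
                elements[-1][2].append(("list", parts[2], parts[3], parts[4]))
            else:
                elements[-1][2].append(("scalar", parts[1], parts[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise InvalidMeshError(f"{path}: unsupported PLY format {fmt!r}")

    vertices: np.ndarray | None = None
    polygons: list[list[int]] = []

    if fmt == "ascii":
        tokens = body.decode("ascii").split("\n")
        rows = [t.split() for t in tokens if t.strip()]
        pos = 0
        for name, count, props in elements:
            chunk = rows[pos : pos + count]
            pos += count
            if name == "vertex":
                names = [p[2] for p in props if p[0] == "scalar"]
                cols = [names.index(axis) for axis in ("x", "y", "z")]
                vertices = np.asarray(
                    [[float(r[c]) for c in cols] for r in chunk], dtype=np.float64
                )
            elif name == "face":
                for r in chunk:
                    n = int(r[0])
                    polygons.append([int(tok) for tok in r[1 : 1 + n]])
    else:
        offset = 0
        for name, count, props in elements:
            if name == "vertex":
                scalar = [p for p in props if p[0] == "scalar"]
                if len(scalar) != len(props):
                    raise InvalidMeshError(f"{path}: list property in vertex element")
                dt = np.dtype([(p[2], "<" + _PLY_DTYPES[p[1]]) for p in scalar])
                arr = np.frombuffer(body, dtype=dt, count=count, offset=offset)
                offset += dt.itemsize * count
                vertices = np.stack(
                    [arr["x"], arr["y"], arr["z"]], axis=1
                ).astype(np.float64)
            elif name == "face":
                lp = next(p for p in props if p[0] == "list")
                cdt = "<" + _PLY_DTYPES[lp[1]]
                idt = "<" + _PLY_DTYPES[lp[2]]
                csize = np.dtype(cdt).itemsize
                isize = np.dtype(idt).itemsize
                for _ in range(count):
                    n = int(np.frombuffer(body, dtype=cdt, count=1, offset=offset)[0])
                    offset += csize
                    idx = np.frombuffer(body, dtype=idt, count=n, offset=offset)
                    offset += isize * n
                    polygons.append([int(i) for i in idx])
            else:
                # skip unknown fixed-size elements
                dt = np.dtype(
                    [(f"p{i}", "<" + _PLY_DTYPES[p[1]]) for i, p in enumerate(props)]
                )
                offset += dt.itemsize * count

    if vertices is None:
        raise InvalidMeshError(f"{path}: no vertex element")
    return BlastomereMesh(
        cell_id=cell_id or path.stem,
        vertices=vertices,
        faces=_fan_triangulate(polygons),
    )


def write_ply(mesh: BlastomereMesh, path: str | Path) -> None:
    path = Path(path)
    lines = [
        "ply",
        "format ascii 1.0",
        f"comment cell {mesh.cell_id}",
        f"element vertex {len(mesh.vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(mesh.faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")


def read_mesh(path: str | Path, cell_id: str | None = None) -> BlastomereMesh:
    path = Path(path)
    if path.suffix.lower() == ".obj":
        return read_obj(path, cell_id)
    if path.suffix.lower() == ".ply":
        return read_ply(path, cell_id)
    raise InvalidMeshError(f"unsupported mesh format: {path.suffix}")


def write_mesh(mesh: BlastomereMesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".obj":
        write_obj(mesh, path)
    elif path.suffix.lower() == ".ply":
        write_ply(mesh, path)
    else:
        raise InvalidMeshError(f"unsupported mesh format: {path.suffix}")


# -- embryo directories -----------------------------------------------------


def read_embryo_dir(path: str | Path, metadata=None) -> Embryo:
    """Read a directory of per-cell mesh files as one embryo."""
    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in MESH_SUFFIXES
    )
    if not files:
        raise InvalidMeshError(f"{path}: no mesh files found")
    meshes = tuple(read_mesh(p) for p in files)
    return Embryo(embryo_id=path.name, blastomeres=meshes, metadata=metadata)


def write_embryo_dir(embryo: Embryo, path: str | Path, fmt: str = "ply") -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for mesh in embryo.blastomeres:
        write_mesh(mesh, path / f"{mesh.cell_id}.{fmt}")


# -- network export ---------------------------------------------------------


def write_network_graphml(net: ContactNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(net.to_networkx(), str(path))


def write_network_edge_csv(net: ContactNetwork, path: str | Path) -> None:
    lines = ["source,target"]
    for i, j in sorted(net.edges):
        lines.append(f"{i},{j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network_edge_csv(path: str | Path, n_nodes: int) -> ContactNetwork:
    edges = set()
    for line in Path(path).read_text().splitlines()[1:]:
        if line.strip():
            i, j = line.split(",")
            edges.add((int(i), int(j)))
    return ContactNetwork(n_nodes=n_nodes, edges=frozenset(edges))
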