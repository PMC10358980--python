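"""File formats: meshes, electrode tables, electrograms and predictions.

All coordinates are centimetres and all times milliseconds.  Supported
formats:

* legacy ASCII VTK unstructured grids (lines, triangles, tetrahedra);
* a plain-text mesh dialect: a node table (``id,x,y,z`` with header) and an
  element table (``n1,n2,...`` node ids per row with header);
* electrode tables ``label,x,y,z``;
* surface-point tables ``id,x,y,z`` (node id on the mapped surface);
* electrogram sets as HDF5 (``time_ms`` dataset plus one dataset per
  electrode under ``signals/``) or delimited text
  (``time_ms,<label>,...``);
* prediction tables: activation times ``site_id,act_ms`` (repeated rows
  per site) and patterns ``type,beat,site_id,time_ms``.

Electrogram exports intentionally carry only the time base, signals and
declared noise levels — no simulation ground truth and no noise seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .electrograms import ElectrogramSet
from .geometry import ElectrodeArray, TissueGeometry
from .patterns import PatternDetection

__all__ = [
    "write_vtk",
    "read_vtk",
    "write_mesh_tables",
    "read_mesh_tables",
    "geometry_from_mesh",
    "write_electrode_table",
    "read_electrode_table",
    "write_surface_points",
    "read_surface_points",
    "write_electrograms_h5",
    "read_electrograms_h5",
    "write_electrograms_text",
    "read_electrograms_text",
    "write_act_table",
    "read_act_table",
    "write_pattern_table",
    "read_pattern_table",
]

_VTK_CELL_TYPES = {2: 3, 3: 5, 4: 10}           # arity -> VTK cell type
_VTK_ARITY = {v: k for k, v in _VTK_CELL_TYPES.items()}


def write_vtk(geom: TissueGeometry, path) -> None:
    """Write the mesh as a legacy ASCII VTK unstructured grid."""
    elements = geom.elements
    k = elements.shape[1]
    if k not in _VTK_CELL_TYPES:
        raise ValueError(f"unsupported element arity {k}")
    ne = len(elements)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("tissue geometry (cm)\n")
        f.write("ASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {geom.n_nodes} double\n")
        for p in geom.nodes:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write(f"CELLS {ne} {ne * (k + 1)}\n")
        for el in elements:
            f.write(f"{k} " + " ".join(str(int(i)) for i in el) + "\n")
        f.write(f"CELL_TYPES {ne}\n")
        for _ in range(ne):
            f.write(f"{_VTK_CELL_TYPES[k]}\n")


def read_vtk(path) -> TissueGeometry:
    """Read a legacy ASCII VTK unstructured grid of uniform simplices."""
    with open(path) as f:
        tokens = []
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens.extend(line.split())
    it = iter(range(len(tokens)))

    def find(keyword: str, start: int = 0) -> int:
        for i in range(start, len(tokens)):
            if tokens[i].upper() == keyword:
                return i
        raise ValueError(f"malformed VTK file: missing {keyword}")

    ip = find("POINTS")
    npts = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3: ip + 3 + 3 * npts], dtype=float).reshape(npts, 3)
    ic = find("CELLS", ip)
    ncells = int(tokens[ic + 1])
    total = int(tokens[ic + 2])
    flat = np.array(tokens[ic + 3: ic + 3 + total], dtype=np.int64)
    it = find("CELL_TYPES", ic)
    ctypes = np.array(tokens[it + 2: it + 2 + ncells], dtype=int)
    if len(set(ctypes.tolist())) != 1:
        raise ValueError("mixed cell types are not supported")
    k = _VTK_ARITY.get(int(ctypes[0]))
    if k is None:
        raise ValueError(f"unsupported VTK cell type {int(ctypes[0])}")
    cells = flat.reshape(ncells, k + 1)
    if np.any(cells[:, 0] != k):
        raise ValueError("inconsistent cell arity in CELLS block")
    return geometry_from_mesh(coords, cells[:, 1:])


def geometry_from_mesh(nodes: np.ndarray, elements: np.ndarray) -> TissueGeometry:
    """Build a TissueGeometry, inferring the mapped surface from the mesh.

    Triangle meshes: every node is a surface node and the (oriented) faces
    are taken as given; vertex normals are area-weighted face normals.
    Tetrahedral meshes: the boundary (faces used by exactly one tet) is the
    surface, oriented outward.  Line meshes (cables) have no meaningful
    surface; all nodes are marked surface with a conventional +z normal.
    """
    nodes = np.asarray(nodes, dtype=float)
    elements = np.asarray(elements, dtype=np.int64)
    k = elements.shape[1]
    if k == 2:
        n = len(nodes)
        return TissueGeometry(
            nodes, elements, np.arange(n), np.tile([0.0, 0.0, 1.0], (n, 1)),
            np.empty((0, 3), dtype=np.int64),
        )
    if k == 3:
        faces = elements
    elif k == 4:
        # boundary faces, oriented so normals point away from the 4th vertex
        face_count: dict[tuple, list] = {}
        local = [(1, 2, 3, 0), (0, 3, 2, 1), (0, 1, 3, 2), (0, 2, 1, 3)]
        for tet in elements:
            for a, b, c, d in local:
                tri = (int(tet[a]), int(tet[b]), int(tet[c]))
                key = tuple(sorted(tri))
                face_count.setdefault(key, []).append((tri, int(tet[d])))
        faces = []
        for key, occ in face_count.items():
            if len(occ) != 1:
                continue
            (i, j, l), opp = occ[0]
            nvec = np.cross(nodes[j] - nodes[i], nodes[l] - nodes[i])
            if np.dot(nvec, nodes[opp] - nodes[i]) > 0:
                i, j, l = i, l, j
            faces.append((i, j, l))
        faces = np.array(faces, dtype=np.int64)
    else:
        raise ValueError(f"unsupported element arity {k}")

    surface_nodes = np.unique(faces)
    vn = np.zeros((len(nodes), 3))
    fn = np.cross(nodes[faces[:, 1]] - nodes[faces[:, 0]],
                  nodes[faces[:, 2]] - nodes[faces[:, 0]])
    for col in range(3):
        np.add.at(vn, faces[:, col], fn)
    normals = vn[surface_nodes]
    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    lens[lens < 1e-30] = 1.0
    normals = normals / lens
    return TissueGeometry(nodes, elements, surface_nodes, normals, faces)


def write_mesh_tables(geom: TissueGeometry, nodes_path, elements_path) -> None:
    """Write the plain-text mesh dialect: node and element tables."""
    nd = pd.DataFrame(geom.nodes, columns=["x", "y", "z"])
    nd.insert(0, "id", np.arange(len(nd)))
    nd.to_csv(nodes_path, index=False)
    cols = [f"n{i + 1}" for i in range(geom.elements.shape[1])]
    pd.DataFrame(geom.elements, columns=cols).to_csv(elements_path, index=False)


def read_mesh_tables(nodes_path, elements_path) -> TissueGeometry:
    nd = pd.read_csv(nodes_path)
    el = pd.read_csv(elements_path)
    order = np.argsort(nd["id"].to_numpy())
    nodes = nd[["x", "y", "z"]].to_numpy(dtype=float)[order]
    return geometry_from_mesh(nodes, el.to_numpy(dtype=np.int64))


def write_electrode_table(labels, positions, path) -> None:
    """Electrode exchange table ``label,x,y,z`` (cm)."""
    positions = np.asarray(positions, dtype=float)
    df = pd.DataFrame({
        "label": list(labels),
        "x": positions[:, 0], "y": positions[:, 1], "z": positions[:, 2],
    })
    df.to_csv(path, index=False)


def read_electrode_table(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    for col in ("label", "x", "y", "z"):
        if col not in df.columns:
            raise ValueError(f"electrode table missing column {col!r}")
    labels = [str(v) for v in df["label"]]
    if len(set(labels)) != len(labels):
        raise ValueError("electrode labels must be unique")
    return labels, df[["x", "y", "z"]].to_numpy(dtype=float)


def write_surface_points(geom: TissueGeometry, path) -> None:
    """Surface-point table ``id,x,y,z``: coordinates only, no signals."""
    pts = geom.nodes[geom.surface_nodes]
    df = pd.DataFrame({
        "id": geom.surface_nodes,
        "x": pts[:, 0], "y": pts[:, 1], "z": pts[:, 2],
    })
    df.to_csv(path, index=False)


def read_surface_points(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["id"].to_numpy(dtype=np.int64), df[["x", "y", "z"]].to_numpy(dtype=float)


def write_electrograms_h5(egms: ElectrogramSet, path) -> None:
    """Hierarchical export: ``time_ms`` plus ``signals/<label>`` datasets.

    Deliberately blinded: no ground truth and no noise seed; declared noise
    levels are stored per electrode (the user supplied them).
    """
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=np.asarray(egms.times, dtype=float))
        g = f.create_group("signals")
        for i, lab in enumerate(egms.labels):
            g.create_dataset(lab, data=np.asarray(egms.phi_e[i], dtype=float))
        if egms.noise_levels is not None:
            f.create_dataset("noise_level_mv_per_ms", data=egms.noise_levels)
            f["noise_level_mv_per_ms"].attrs["labels"] = [
                s.encode() for s in egms.labels
            ]


def read_electrograms_h5(path) -> ElectrogramSet:
    import h5py

    with h5py.File(path, "r") as f:
        times = f["time_ms"][...]
        labels = sorted(f["signals"].keys())
        phi = np.vstack([f["signals"][lab][...] for lab in labels])
        levels = (f["noise_level_mv_per_ms"][...]
                  if "noise_level_mv_per_ms" in f else None)
    return ElectrogramSet(labels=labels, times=times, phi_e=phi, noise_levels=levels)


def write_electrograms_text(egms: ElectrogramSet, path) -> None:
    """Delimited dialect: header ``time_ms,<label>,...`` then one row/sample."""
    df = pd.DataFrame({"time_ms": egms.times})
    for i, lab in enumerate(egms.labels):
        df[lab] = egms.phi_e[i]
    df.to_csv(path, index=False)


def read_electrograms_text(path) -> ElectrogramSet:
    df = pd.read_csv(path)
    if df.columns[0] != "time_ms":
        raise ValueError("electrogram text file must start with a time_ms column")
    labels = [str(c) for c in df.columns[1:]]
    phi = df[df.columns[1:]].to_numpy(dtype=float).T
    return ElectrogramSet(labels=labels, times=df["time_ms"].to_numpy(dtype=float),
                          phi_e=phi)


def write_act_table(acts: dict, path) -> None:
    """AcT prediction/report table: repeated rows ``site_id,act_ms``."""
    rows = []
    for site in sorted(acts, key=str):
        for t in np.sort(np.asarray(acts[site], dtype=float)):
            rows.append({"site_id": site, "act_ms": float(t)})
    pd.DataFrame(rows, columns=["site_id", "act_ms"]).to_csv(path, index=False)


def read_act_table(path) -> dict:
    df = pd.read_csv(path)
    for col in ("site_id", "act_ms"):
        if col not in df.columns:
            raise ValueError(f"AcT table missing column {col!r}")
    out: dict = {}
    for site, grp in df.groupby("site_id", sort=True):
        out[str(site)] = np.sort(grp["act_ms"].to_numpy(dtype=float))
    return out


def write_pattern_table(detections: list[PatternDetection], path) -> None:
    """Pattern prediction table: rows ``type,beat,site_id,time_ms``."""
    rows = [{"type": d.type, "beat": d.beat, "site_id": d.electrode,
             "time_ms": d.time} for d in detections]
    pd.DataFrame(rows, columns=["type", "beat", "site_id", "time_ms"]).to_csv(
        path, index=False)


def read_pattern_table(path) -> list[PatternDetection]:
    df = pd.read_csv(path)
    for col in ("type", "beat", "site_id", "time_ms"):
        if col not in df.columns:
            raise ValueError(f"pattern table missing column {col!r}")
    out = []
    for _, r in df.iterrows():
        typ = str(r["type"])
        if typ not in ("F", "R+", "R-"):
            raise ValueError(f"unknown pattern type {typ!r}")
        out.append(PatternDetection(typ, str(r["site_id"]), float(r["time_ms"]),
                                    int(r["beat"])))
    return out
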