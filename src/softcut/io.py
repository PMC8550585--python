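"""Plain-text file formats: volume models, OBJ surfaces, CSV logs.

The volume format (``SOFTCUT-VOL 1``) is a versioned, whitespace-separated
text file with 0-based indexing:

    SOFTCUT-VOL 1
    <grid_spacing>
    <n_nodes>
    x y z                 (one line per node)
    <n_elems>
    cx cy cz vol          (one line per element)

Surfaces are read and written as Wavefront OBJ with ``v``/``f`` records
only; OBJ's 1-based face indices are converted to 0-based in memory.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .errors import SoftcutError
from .model import SurfaceMesh, VolumeModel

VOLUME_MAGIC = "SOFTCUT-VOL 1"


def write_volume(model: VolumeModel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{VOLUME_MAGIC}\n")
        fh.write(f"{float(model.grid_spacing)!r}\n")
        fh.write(f"{model.n_nodes}\n")
        for p in model.node_positions:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        fh.write(f"{model.n_elements}\n")
        for c, v in zip(model.element_centers, model.element_volumes):
            fh.write(f"{float(c[0])!r} {float(c[1])!r} {float(c[2])!r} {float(v)!r}\n")


def read_volume(path) -> VolumeModel:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != VOLUME_MAGIC:
        raise SoftcutError(f"{path}: not a {VOLUME_MAGIC} file")
    try:
        h = float(lines[1])
        n_nodes = int(lines[2])
        at = 3
        nodes = np.array(
            [[float(t) for t in lines[at + i].split()] for i in range(n_nodes)]
        )
        at += n_nodes
        n_elems = int(lines[at])
        at += 1
        rows = np.array(
            [[float(t) for t in lines[at + i].split()] for i in range(n_elems)]
        )
    except (ValueError, IndexError) as err:
        raise SoftcutError(f"{path}: malformed volume file ({err})") from err
    return VolumeModel(
        node_positions=nodes,
        element_centers=rows[:, :3],
        element_volumes=rows[:, 3],
        grid_spacing=h,
    )


def write_obj(surface: SurfaceMesh, path) -> None:
    """Write v/f records; indices converted to OBJ's 1-based convention."""
    path = Path(path)
    with path.open("w") as fh:
        for p in surface.vertex_rest_positions:
            fh.write(f"v {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        for t in surface.triangles:
            fh.write(f"f {int(t[0]) + 1} {int(t[1]) + 1} {int(t[2]) + 1}\n")


def write_obj_positions(positions: np.ndarray, triangles: np.ndarray, path) -> None:
    """Write an OBJ from explicit (deformed) vertex positions."""
    write_obj(
        SurfaceMesh(vertex_rest_positions=positions, triangles=triangles), path
    )


def read_obj(path) -> SurfaceMesh:
    path = Path(path)
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    for line in path.read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(t) for t in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(t.split("/")[0]) - 1 for t in parts[1:]]
            if len(idx) != 3:
                raise SoftcutError(f"{path}: only triangle faces supported")
            faces.append(idx)
    if not verts or not faces:
        raise SoftcutError(f"{path}: no v/f records found")
    return SurfaceMesh(
        vertex_rest_positions=np.array(verts), triangles=np.array(faces)
    )


def write_csv(path, fieldnames, rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fieldnames)
        w.writeheader()
        for row in rows:
            w.writerow(row)
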