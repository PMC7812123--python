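"""Small output helpers: legacy-VTK polyline/scalar export and flat TOML."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .curves import CurveSet
from .matching import ScalarField


def write_vtk_polylines(curves: CurveSet, path: str | Path) -> None:
    """Curves as legacy ASCII VTK polydata (visualization convenience)."""
    pts = []
    lines = []
    off = 0
    for c in curves:
        n = len(c.points)
        pts.append(c.points)
        lines.append([n, *range(off, off + n)])
        off += n
    all_pts = np.vstack(pts) if pts else np.zeros((0, 3))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nendocompare curves\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(all_pts)} float\n")
        for p in all_pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        total = sum(len(l) for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(i) for i in l) + "\n")


def write_vtk_mesh_scalar(mesh, field: ScalarField, name: str, path: str | Path,
                          sentinel: float = -1.0) -> None:
    """Mesh + per-vertex scalar as legacy ASCII VTK (masked -> sentinel)."""
    v = np.asarray(mesh.vertices, dtype=float)
    f = np.asarray(mesh.faces, dtype=np.int64)
    vals = np.where(field.mask, field.values, sentinel)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nendocompare scalar map\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        fh.write(f"POINT_DATA {len(v)}\nSCALARS {name} float 1\nLOOKUP_TABLE default\n")
        for x in vals:
            fh.write(f"{x:.6f}\n")


def dump_flat_toml(sections: dict[str, dict], path: str | Path) -> None:
    """Write a {section: {key: scalar-or-list}} dict as TOML."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, str):
            return f'"{v}"'
        if isinstance(v, (list, tuple, np.ndarray)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise TypeError(f"cannot serialize {type(v)} to TOML")

    out = []
    for sec, kv in sections.items():
        out.append(f"[{sec}]")
        for k, v in kv.items():
            out.append(f"{k} = {fmt(v)}")
        out.append("")
    Path(path).write_text("\n".join(out))
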