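"""File I/O: MRC/TIFF volumes, point-cloud CSV, and a minimal Amira
SpatialGraph ASCII writer.

Files always carry physical units: volumes know their pixel size in
Angstrom per pixel, point-cloud files hold coordinates in nm with the
header ``instance_id,x,y,z`` (``z`` omitted for 2D clouds; instance_id -1
marks noise points). Voxel indices never cross a file boundary.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import tifffile

from .core import PointCloud
from .cut import InstanceSegmentation
from .mask import VolumeImage

__all__ = [
    "read_volume", "write_volume", "read_cloud_csv", "write_cloud_csv",
    "write_instances", "read_amira_spatialgraph_counts",
]


def read_volume(path, pixel_size: float | None = None,
                kind: str = "raw") -> VolumeImage:
    """Read an MRC or TIFF volume.

    MRC files carry their pixel size in the header (overridable via
    ``pixel_size``); TIFF files require an explicit ``pixel_size`` in
    Angstrom per pixel. Data is returned [z, y, x] (x fastest), 2D images
    [y, x].
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".mrcs", ".map", ".ccp4"):
        try:
            mrc = gemmi.read_ccp4_map(str(path))
        except Exception as exc:
            raise ValueError(f"unreadable MRC file {path}: {exc}") from exc
        arr = np.array(mrc.grid, copy=True)           # (nx, ny, nz)
        data = np.ascontiguousarray(arr.transpose(2, 1, 0))   # -> (nz, ny, nx)
        if data.shape[0] == 1:
            data = data[0]
        header_px = float(mrc.grid.spacing[0])
        px = pixel_size if pixel_size is not None else header_px
        if not np.isfinite(px) or px <= 0:
            raise ValueError(
                f"{path}: pixel size missing from MRC header; pass an override")
    elif suffix in (".tif", ".tiff"):
        data = tifffile.imread(str(path))
        if pixel_size is None:
            raise ValueError("TIFF input requires an explicit pixel size (A/px)")
        px = pixel_size
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
    if kind == "binary":
        data = (np.asarray(data) > 0.5).astype(np.uint8)
    return VolumeImage(np.asarray(data), px, kind)


def write_volume(img: VolumeImage, path):
    """Write a volume as MRC (float32) or TIFF."""
    path = Path(path)
    suffix = path.suffix.lower()
    data = img.data
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))
        return
    if suffix not in (".mrc", ".mrcs", ".map", ".ccp4"):
        raise ValueError(f"unsupported volume format: {path.suffix}")
    vol = data[None] if data.ndim == 2 else data
    grid_data = np.ascontiguousarray(vol.transpose(2, 1, 0), dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(grid_data)
    nx, ny, nz = grid_data.shape
    m.grid.unit_cell = gemmi.UnitCell(nx * img.pixel_size, ny * img.pixel_size,
                                      nz * img.pixel_size, 90, 90, 90)
    m.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def write_cloud_csv(cloud: PointCloud, path):
    """CSV dialect ``instance_id,x,y,z`` (z omitted for 2D), nm units."""
    labels = cloud.labels if cloud.labels is not None else np.zeros(cloud.n_points, int)
    cols = {"instance_id": labels, "x": cloud.coords[:, 0], "y": cloud.coords[:, 1]}
    if cloud.n_dims == 3:
        cols["z"] = cloud.coords[:, 2]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_cloud_csv(path) -> PointCloud:
    df = pd.read_csv(path)
    required = {"instance_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: point-cloud CSV needs columns instance_id,x,y[,z]")
    axes = ["x", "y", "z"] if "z" in df.columns else ["x", "y"]
    return PointCloud(df[axes].to_numpy(float), df["instance_id"].to_numpy(int))


def write_instances(seg: InstanceSegmentation, cloud: PointCloud, path,
                    format: str = "csv"):
    """Write an instance segmentation.

    ``csv``: ``instance_id,x,y,z`` rows, chains ordered by traversal.
    ``amira_ascii``: minimal HxSpatialGraph with one edge per instance
    polyline — requires chain traversals.
    """
    if format == "csv":
        if seg.traversals:
            rows = [(lab, i) for lab, tr in enumerate(seg.traversals) for i in tr]
        else:
            rows = [(seg.labels[i], i) for i in range(cloud.n_points)]
        idx = [i for _, i in rows]
        labs = [lab for lab, _ in rows]
        ordered = PointCloud(cloud.coords[idx], np.asarray(labs))
        write_cloud_csv(ordered, path)
        return
    if format != "amira_ascii":
        raise ValueError("format must be 'csv' or 'amira_ascii'")
    if not seg.traversals:
        raise ValueError("amira_ascii output requires chain traversals "
                         "(surface instances have no point ordering)")
    coords = cloud.coords
    if coords.shape[1] == 2:
        coords = np.column_stack([coords, np.zeros(len(coords))])
    n_edges = len(seg.traversals)
    n_vertices = 2 * n_edges
    n_points = sum(len(t) for t in seg.traversals)
    lines = [
        "# AmiraMesh 3D ASCII 2.0",
        "",
        f"define VERTEX {n_vertices}",
        f"define EDGE {n_edges}",
        f"define POINT {n_points}",
        "",
        'Parameters { ContentType "HxSpatialGraph" }',
        "",
        "VERTEX { float[3] VertexCoordinates } @1",
        "EDGE { int[2] EdgeConnectivity } @2",
        "EDGE { int NumEdgePoints } @3",
        "POINT { float[3] EdgePointCoordinates } @4",
        "",
        "@1",
    ]
    for tr in seg.traversals:
        for end in (tr[0], tr[-1]):
            x, y, z = coords[end]
            lines.append(f"{x:.4f} {y:.4f} {z:.4f}")
    lines.append("")
    lines.append("@2")
    for e in range(n_edges):
        lines.append(f"{2 * e} {2 * e + 1}")
    lines.append("")
    lines.append("@3")
    for tr in seg.traversals:
        lines.append(str(len(tr)))
    lines.append("")
    lines.append("@4")
    for tr in seg.traversals:
        for i in tr:
            x, y, z = coords[i]
            lines.append(f"{x:.4f} {y:.4f} {z:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_amira_spatialgraph_counts(path) -> dict:
    """Parse the declared VERTEX/EDGE/POINT counts from a SpatialGraph file."""
    counts = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) == 3 and parts[0] == "define":
            counts[parts[1]] = int(parts[2])
    return counts
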