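"""Sampling DWI volumes at the cortical mid-thickness point.

For each surface vertex the sample point lies half the local cortical
thickness outward from the GM/WM boundary along the outward surface normal.
The DWI signal is read from the voxel *containing* that point (no
interpolation), using the image affine with 0-based, half-open voxel
indexing.  Because the surface tessellation is finer than the DWI grid,
several vertices can land in one voxel; :func:`dedup_vertices` reduces each
voxel group to the vertex closest to the group's mean position so the
vertex -> voxel map becomes injective before any train/test split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CorticalSamples",
    "read_surface_table",
    "midthickness_sample",
    "dedup_vertices",
]

SURFACE_COLUMNS = ["x", "y", "z", "nx", "ny", "nz", "thickness", "label"]


@dataclass
class CorticalSamples:
    """Table of per-vertex geometry plus sampled DWI signal.

    ``table`` holds vertex_id, position, normal, thickness, roi label and the
    voxel index; ``signal`` is (n_vertices, n_volumes), row-aligned with the
    table.
    """

    table: pd.DataFrame
    signal: np.ndarray

    def __post_init__(self) -> None:
        if len(self.table) != len(self.signal):
            raise ValueError("table/signal length mismatch")

    @property
    def positions(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy()

    @property
    def normals(self) -> np.ndarray:
        return self.table[["nx", "ny", "nz"]].to_numpy()

    @property
    def voxel_indices(self) -> np.ndarray:
        return self.table[["i", "j", "k"]].to_numpy()

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()


def read_surface_table(path: str | Path) -> pd.DataFrame:
    """Read a cortical surface vertex table (TSV or ASCII PLY).

    TSV columns: ``x y z nx ny nz thickness label`` (header optional).  ASCII
    PLY must carry the same per-vertex properties.  Normals are re-normalized;
    a ``vertex_id`` column is added from row order.
    """
    path = Path(path)
    if path.suffix.lower() == ".ply":
        df = _read_ascii_ply(path)
    else:
        first = path.read_text().splitlines()[0].split("\t" if "\t" in path.read_text().splitlines()[0] else None)
        has_header = any(tok == "x" for tok in first)
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=0 if has_header else None,
            names=None if has_header else SURFACE_COLUMNS,
        )
    missing = [c for c in SURFACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"surface table missing columns {missing}")
    df = df.reset_index(drop=True)
    if "vertex_id" not in df.columns:
        df.insert(0, "vertex_id", np.arange(len(df)))
    n = df[["nx", "ny", "nz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(n, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length vertex normal")
    df[["nx", "ny", "nz"]] = n / norms[:, None]
    if (df["thickness"] <= 0).any():
        raise ValueError("non-positive cortical thickness")
    return df


def _read_ascii_ply(path: Path) -> pd.DataFrame:
    """Minimal ASCII PLY reader for a vertex element with named properties."""
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError("not a PLY file")
    props: list[str] = []
    n_vertex = None
    i = 1
    in_vertex = False
    while i < len(lines):
        tok = lines[i].split()
        if tok[:1] == ["format"] and tok[1] != "ascii":
            raise ValueError("only ASCII PLY is supported")
        if tok[:1] == ["element"]:
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n_vertex = int(tok[2])
        elif tok[:1] == ["property"] and in_vertex:
            props.append(tok[-1])
        elif tok[:1] == ["end_header"]:
            i += 1
            break
        i += 1
    if n_vertex is None:
        raise ValueError("PLY has no vertex element")
    rows = [lines[i + j].split() for j in range(n_vertex)]
    df = pd.DataFrame(rows, columns=props)
    for c in df.columns:
        if c != "label":
            df[c] = df[c].astype(float)
    return df


def midthickness_sample(volume, surface: pd.DataFrame) -> CorticalSamples:
    """Sample a 4D DWI image at each vertex's mid-thickness voxel.

    ``volume`` is a nibabel spatial image (or anything with ``get_fdata`` and
    ``affine``).  The sample point is ``position + 0.5 * thickness * normal``
    in world mm; its containing voxel is found through the inverse affine.
    Vertices whose sample point falls outside the volume are dropped with a
    logged warning.
    """
    data = np.asarray(volume.get_fdata(), dtype=float)
    if data.ndim == 3:
        data = data[..., None]
    affine = np.asarray(volume.affine, dtype=float)
    inv = np.linalg.inv(affine)

    pos = surface[["x", "y", "z"]].to_numpy(dtype=float)
    nrm = surface[["nx", "ny", "nz"]].to_numpy(dtype=float)
    thick = surface["thickness"].to_numpy(dtype=float)
    points = pos + 0.5 * thick[:, None] * nrm
    vox = (inv[:3, :3] @ points.T).T + inv[:3, 3]
    # half-open convention: voxel i contains voxel coordinates [i, i+1)
    ijk = np.floor(vox).astype(int)
    shape = np.array(data.shape[:3])
    inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
    if not np.all(inside):
        n_out = int((~inside).sum())
        logger.warning("%d vertices sampled outside the volume; excluded", n_out)
    kept = surface.loc[inside].reset_index(drop=True)
    ijk_in = ijk[inside]
    sig = data[ijk_in[:, 0], ijk_in[:, 1], ijk_in[:, 2], :]
    tab = kept.copy()
    tab["i"], tab["j"], tab["k"] = ijk_in[:, 0], ijk_in[:, 1], ijk_in[:, 2]
    return CorticalSamples(table=tab, signal=sig)


def dedup_vertices(samples: CorticalSamples, per_roi: bool = True) -> CorticalSamples:
    """Reduce to a one-to-one vertex -> voxel mapping.

    For each group of vertices sharing a voxel (within an ROI, by default),
    keep the vertex closest to the group's mean world position; distance
    ties — common in two-vertex groups, where both are equidistant from
    their midpoint — go to the lowest vertex_id.  Distances equal within a
    1e-9 relative tolerance count as tied, so the choice does not depend on
    last-ulp rounding.  The result is asserted injective.
    """
    tab = samples.table.reset_index(drop=True)
    pos = tab[["x", "y", "z"]].to_numpy(dtype=float)
    group_cols = ["i", "j", "k"] + (["label"] if per_roi else [])
    keep_rows: list[int] = []
    for _, grp in tab.groupby(group_cols, sort=False):
        rows = grp.index.to_numpy()
        centroid = pos[rows].mean(axis=0)
        d = np.linalg.norm(pos[rows] - centroid, axis=1)
        vid = tab.loc[rows, "vertex_id"].to_numpy()
        tied = d <= d.min() + 1e-9 * (1.0 + d.min())
        keep_rows.append(int(rows[tied][np.argmin(vid[tied])]))
    keep_rows = sorted(keep_rows)
    out_tab = tab.loc[keep_rows].reset_index(drop=True)
    out_sig = samples.signal[keep_rows]
    if not per_roi:
        assert not out_tab.duplicated(subset=["i", "j", "k"]).any()
    else:
        assert not out_tab.duplicated(subset=["i", "j", "k", "label"]).any()
    return CorticalSamples(table=out_tab, signal=out_sig)
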