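"""Imaging I/O and the coordinate contract shared by the whole pipeline.

Volumes are NIfTI scalar maps carried as :class:`ScalarVolume` (3D grid +
4x4 voxel->world affine, RAS mm). Streamlines are TRK/TCK polylines carried
as :class:`StreamlineBundle` in world mm with an anchor point marking the
seed (LGN) end. Voxel indices are 0-based and an integer index denotes the
voxel center, so all half-voxel ambiguity is resolved here and nowhere else.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ScalarVolume",
    "StreamlineBundle",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_streamlines",
    "write_streamlines",
    "world_to_voxel",
    "voxel_to_world",
    "read_profile_table",
    "write_profile_table",
]

PROFILE_COLUMNS = ["subject", "compartment", "metric", "node", "value"]


@dataclass
class ScalarVolume:
    """A 3D scalar grid with a voxel-to-world (RAS mm) affine.

    Diffusivity maps are in units of 1e-3 mm^2/s; FA and masks are unitless.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3D scalar map, got {self.data.ndim}D; pass a 3D map"
            )
        if min(self.data.shape) < 1:
            raise ValueError("grid dimensions must be >= 1 on each axis")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0.0, 1.0)).all())

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """A new volume on the same grid/affine with different values."""
        return ScalarVolume(np.asarray(data, dtype=float), self.affine.copy())


@dataclass
class StreamlineBundle:
    """Ordered 3D polylines in world mm plus the seed-end anchor (LGN)."""

    streamlines: list
    anchor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for i, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(f"streamline {i}: expected an (n>=2, 3) polyline")
            if not np.isfinite(s).all():
                raise ValueError(f"streamline {i}: non-finite coordinates")
        if self.anchor is not None:
            self.anchor = np.asarray(self.anchor, dtype=float).reshape(3)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


def _collapse_duplicates(polyline: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate vertices (exact repeats from writers)."""
    if len(polyline) < 2:
        return polyline
    keep = np.ones(len(polyline), dtype=bool)
    keep[1:] = (np.diff(polyline, axis=0) != 0).any(axis=1)
    return polyline[keep]


def read_scalar_volume(path: str | os.PathLike) -> ScalarVolume:
    """Load a 3D NIfTI map; values pass through untouched beyond scl scaling."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: image has {data.ndim} dimensions; pass a 3D map"
        )
    return ScalarVolume(data, np.asarray(img.affine, dtype=float))


def write_scalar_volume(volume: ScalarVolume, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine),
             os.fspath(path))


def read_streamlines(path: str | os.PathLike,
                     anchor: np.ndarray | None = None) -> StreamlineBundle:
    """Load TRK or TCK streamlines into world (RAS mm) coordinates.

    The TRK header's voxel order / voxel-to-RAS transform is honored by the
    nibabel loader, so both formats come out in the same world frame.
    Consecutive duplicate points are collapsed on read.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in (".trk", ".tck"):
        raise ValueError(f"{path}: unknown streamline format '{ext}' (use .trk/.tck)")
    tractogram = nib.streamlines.load(path).tractogram
    lines = [_collapse_duplicates(np.asarray(s, dtype=float))
             for s in tractogram.streamlines]
    return StreamlineBundle(lines, anchor=anchor)


def write_streamlines(bundle: StreamlineBundle, path: str | os.PathLike,
                      reference: ScalarVolume | None = None) -> None:
    """Write a bundle as TRK or TCK; points are already world mm (RAS)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    tractogram = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in bundle.streamlines],
        affine_to_rasmm=np.eye(4))
    if ext == ".tck":
        nib.streamlines.save(tractogram, path)
        return
    if ext != ".trk":
        raise ValueError(f"{path}: unknown streamline format '{ext}' (use .trk/.tck)")
    header = {}
    if reference is not None:
        header[nib.streamlines.trk.Field.VOXEL_TO_RASMM] = \
            reference.affine.astype(np.float32)
        header[nib.streamlines.trk.Field.VOXEL_SIZES] = np.sqrt(
            (reference.affine[:3, :3] ** 2).sum(axis=0)).astype(np.float32)
        header[nib.streamlines.trk.Field.DIMENSIONS] = np.asarray(
            reference.data.shape, dtype=np.int16)
    nib.streamlines.save(tractogram, path, header=header)


def world_to_voxel(volume: ScalarVolume, points: np.ndarray) -> np.ndarray:
    """Map world-mm point(s) to continuous 0-based voxel indices.

    Integer indices denote voxel centers. Points outside the grid map to
    out-of-range indices; callers decide what that means.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(volume.affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    return vox[0] if np.asarray(points).ndim == 1 else vox


def voxel_to_world(volume: ScalarVolume, indices: np.ndarray) -> np.ndarray:
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    world = idx @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    return world[0] if np.asarray(indices).ndim == 1 else world


def write_profile_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Serialize profile rows as the CSV dialect used throughout.

    Columns: subject, compartment, metric, node (1-based), value.
    """
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table missing columns {missing}")
    df[PROFILE_COLUMNS].to_csv(os.fspath(path), index=False)


def read_profile_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(os.fspath(path))
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"profile table missing columns {missing}")
    bad = df[(df["node"] < 1) | (df["node"] > 50)]
    if len(bad):
        raise ValueError("node index out of [1, 50]")
    return df
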