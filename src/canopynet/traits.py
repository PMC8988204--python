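"""Plot-level trait extraction from fused 3D + spectral point clouds.

Input clouds are assumed already registered, denoised and ground-normalized
(z is height above ground, mm); every point carries four reflectance bands
(blue, green, red, near-infrared) scaled to [0, 1].

Spectral indices (per-point, then averaged over the plot):

* GNDVI  = (NIR - G) / (NIR + G)
* CVI    = (NIR / G) * (R / G)
* NCPI   = (R - B) / (R + B)
* MCARI  = ((NIR - R) - 0.2 * (NIR - G)) * (NIR / R)

Structural traits:

* Hmean  — mean point height (mm)
* H99    — 99th percentile height, linear-interpolation convention (mm)
* PLA    — projected leaf area: occupied xy grid cells x cell area (m^2)
* Volume — occupied xyz voxels x voxel volume (m^3)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (EmptyInputError, InvalidArgumentError,
                     PointCloudFormatError, PointCloudValidationError)

logger = logging.getLogger(__name__)

BAND_NAMES = ("b", "g", "r", "nir")
PLY_PROPERTIES = ("x", "y", "z", "red", "green", "blue", "nir")


@dataclass
class PointCloud:
    """A fused per-plot point cloud.

    ``xyz``: (n, 3) float array, mm, z >= 0 above ground.
    ``bands``: (n, 4) float array of reflectances in [0, 1], columns (b, g, r, nir).
    """

    xyz: np.ndarray
    bands: np.ndarray

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.bands = np.asarray(self.bands, dtype=float).reshape(-1, 4)
        if len(self.xyz) != len(self.bands):
            raise PointCloudFormatError("xyz and bands row counts differ")

    def __len__(self) -> int:
        return len(self.xyz)

    def validate_reflectance(self) -> None:
        bad = np.where((self.bands < 0.0) | (self.bands > 1.0))[0]
        if bad.size:
            rows = np.unique(bad)[:20].tolist()
            raise PointCloudValidationError(
                f"reflectance outside [0, 1] at point rows {rows}"
                + ("..." if np.unique(bad).size > 20 else ""))


@dataclass(frozen=True)
class PlotTraits:
    """All eight trait values for one plot at one time point."""

    GNDVI: float
    CVI: float
    NCPI: float
    MCARI: float
    Hmean: float   # mm
    H99: float     # mm
    PLA: float     # m^2
    Volume: float  # m^3

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("GNDVI", "CVI", "NCPI", "MCARI", "Hmean", "H99", "PLA", "Volume")}


# ---------------------------------------------------------------------------
# readers / writers

def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PointCloudFormatError(f"{path}: not a PLY file")
        fmt = None
        n_vertices = None
        props: list[str] = []
        while True:
            line = fh.readline()
            if not line:
                raise PointCloudFormatError(f"{path}: unterminated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                if tokens[1] != "vertex":
                    raise PointCloudFormatError(
                        f"{path}: only vertex elements are supported, got {tokens[1]}")
                n_vertices = int(tokens[2])
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    raise PointCloudFormatError(f"{path}: list properties unsupported")
                props.append(tokens[2])
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PointCloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
        if tuple(props) != PLY_PROPERTIES:
            raise PointCloudFormatError(
                f"{path}: vertex properties must be {PLY_PROPERTIES}, got {tuple(props)}")
        if n_vertices is None:
            raise PointCloudFormatError(f"{path}: missing vertex element")
        if fmt == "ascii":
            rows = []
            for i in range(n_vertices):
                line = fh.readline().split()
                if len(line) != 7:
                    raise PointCloudFormatError(
                        f"{path}: vertex {i} has {len(line)} values, expected 7")
                rows.append([float(v) for v in line])
            data = np.array(rows, dtype=float).reshape(-1, 7)
        else:
            raw = fh.read(n_vertices * 7 * 4)
            if len(raw) != n_vertices * 7 * 4:
                raise PointCloudFormatError(f"{path}: truncated binary payload")
            data = np.frombuffer(raw, dtype="<f4").astype(float).reshape(n_vertices, 7)
    # PLY column order is x, y, z, red, green, blue, nir
    bands = data[:, [5, 4, 3, 6]]  # -> b, g, r, nir
    return PointCloud(xyz=data[:, :3], bands=bands)


def _read_xyz_csv(path: Path) -> PointCloud:
    frame = pd.read_csv(path)
    expected = ["x", "y", "z", *BAND_NAMES]
    if list(frame.columns) != expected:
        raise PointCloudFormatError(
            f"{path}: columns must be {expected}, got {list(frame.columns)}")
    data = frame.to_numpy(dtype=float)
    return PointCloud(xyz=data[:, :3], bands=data[:, 3:])


def read_point_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a fused point cloud from PLY (ascii/binary) or CSV.

    Reflectances are validated to [0, 1]; an empty file yields an empty
    cloud (trait extraction, not reading, rejects empty input).
    """
    path = Path(path)
    if format is None:
        format = "ply" if path.suffix.lower() == ".ply" else "xyz-csv"
    if format == "ply":
        cloud = _read_ply(path)
    elif format == "xyz-csv":
        cloud = _read_xyz_csv(path)
    else:
        raise InvalidArgumentError(f"unknown point-cloud format {format!r}")
    cloud.validate_reflectance()
    return cloud


def write_point_cloud(cloud: PointCloud, path: str | Path,
                      format: str | None = None, binary: bool = False) -> Path:
    """Write a cloud as ASCII/binary PLY or CSV (round-trips with the reader)."""
    path = Path(path)
    if format is None:
        format = "ply" if path.suffix.lower() == ".ply" else "xyz-csv"
    if format == "xyz-csv":
        frame = pd.DataFrame(np.hstack([cloud.xyz, cloud.bands]),
                             columns=["x", "y", "z", *BAND_NAMES])
        frame.to_csv(path, index=False)
        return path
    data = np.hstack([cloud.xyz, cloud.bands[:, [2, 1, 0, 3]]])  # x y z red green blue nir
    header = ["ply",
              "format binary_little_endian 1.0" if binary else "format ascii 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property float {p}" for p in PLY_PROPERTIES]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(data.astype("<f4").tobytes())
        else:
            for row in data:
                fh.write((" ".join(repr(float(v)) for v in row) + "\n").encode("ascii"))
    return path


# ---------------------------------------------------------------------------
# traits

def compute_spectral_indices(cloud: PointCloud) -> tuple[float, float, float, float]:
    """Plot-mean (GNDVI, CVI, NCPI, MCARI) over all points.

    Points whose index denominator is zero are excluded from that index's
    mean; the exclusion count is logged.
    """
    if len(cloud) == 0:
        raise EmptyInputError("cannot compute spectral indices of an empty cloud")
    b, g, r, nir = (cloud.bands[:, i] for i in range(4))

    def masked_mean(num: np.ndarray, den: np.ndarray, name: str) -> float:
        ok = den != 0.0
        n_bad = int((~ok).sum())
        if n_bad:
            logger.info("%s: excluded %d point(s) with zero denominator", name, n_bad)
        if not ok.any():
            raise EmptyInputError(f"{name}: all points have zero denominators")
        return float(np.mean(num[ok] / den[ok]))

    gndvi = masked_mean(nir - g, nir + g, "GNDVI")
    cvi = masked_mean(nir * r, g * g, "CVI")
    ncpi = masked_mean(r - b, r + b, "NCPI")
    mcari = masked_mean(((nir - r) - 0.2 * (nir - g)) * nir, r, "MCARI")
    return gndvi, cvi, ncpi, mcari


def compute_structural_traits(cloud: PointCloud, grid_cell: float = 5.0,
                              voxel: float = 10.0) -> tuple[float, float, float, float]:
    """(Hmean, H99, PLA, Volume) from point geometry.

    ``grid_cell`` and ``voxel`` are edge lengths in mm. PLA counts occupied
    xy cells; Volume counts occupied xyz voxels; both use floor binning.
    """
    if len(cloud) == 0:
        raise EmptyInputError("cannot compute structural traits of an empty cloud")
    if grid_cell <= 0 or voxel <= 0:
        raise InvalidArgumentError("grid_cell and voxel must be positive")
    z = cloud.xyz[:, 2]
    hmean = float(z.mean())
    h99 = float(np.percentile(z, 99))  # linear interpolation between order stats
    xy_cells = np.unique(np.floor(cloud.xyz[:, :2] / grid_cell).astype(np.int64), axis=0)
    pla = len(xy_cells) * (grid_cell / 1000.0) ** 2
    voxels = np.unique(np.floor(cloud.xyz / voxel).astype(np.int64), axis=0)
    volume = len(voxels) * (voxel / 1000.0) ** 3
    return hmean, h99, float(pla), float(volume)


def extract_plot_traits(cloud: PointCloud, grid_cell: float = 5.0,
                        voxel: float = 10.0) -> PlotTraits:
    """All eight traits of one plot cloud."""
    gndvi, cvi, ncpi, mcari = compute_spectral_indices(cloud)
    hmean, h99, pla, volume = compute_structural_traits(cloud, grid_cell, voxel)
    return PlotTraits(GNDVI=gndvi, CVI=cvi, NCPI=ncpi, MCARI=mcari,
                      Hmean=hmean, H99=h99, PLA=pla, Volume=volume)
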