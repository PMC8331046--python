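"""Reading and writing of calibrated 4D image series and track tables.

All voxel grids are indexed ``(z, y, x)`` (0-based) and physical coordinates
are expressed in micrometres, anchored at voxel centers: the center of voxel
``(k, i, j)`` sits at ``(k*dz, i*dy, j*dx)``.  A two-channel time series is
stored as a single array with axis order ``(t, c, z, y, x)``; channel names
("network" for the endothelial channel, "cells" for the cancer-cell channel)
are bound by configuration, not by acquisition wavelength.
"""

from __future__ import annotations

import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Calibration",
    "ImageSeries4D",
    "MalformedSeriesError",
    "DEFAULT_CHANNELS",
    "STATE_LABELS",
    "TRACK_COLUMNS",
    "read_series",
    "write_series",
    "read_tracks",
    "write_tracks",
]

DEFAULT_CHANNELS: tuple[str, ...] = ("network", "cells")

#: Valid per-frame behavioral state labels.
STATE_LABELS = ("FREE", "APPROACHING", "ON_NETWORK", "INSIDE_NETWORK")

TRACK_COLUMNS = [
    "track_id",
    "time_min",
    "x_um",
    "y_um",
    "z_um",
    "state_label",
    "cell_voxel_count",
]


class MalformedSeriesError(ValueError):
    """Raised when a TIFF series cannot be factored into (t, c, z) pages."""


@dataclass(frozen=True)
class Calibration:
    """Physical calibration of a confocal z-stack time series.

    Defaults follow a typical acquisition of sixty 2.5-μm optical sections
    through 150 μm, one stack every 10 minutes, with 1-μm lateral sampling.

    Parameters
    ----------
    dx_um, dy_um : float
        Lateral voxel size in μm.
    dz_um : float
        Axial step between optical sections in μm.
    dt_min : float
        Frame (stack) interval in minutes.
    n_z : int
        Number of optical sections per stack.
    """

    dx_um: float = 1.0
    dy_um: float = 1.0
    dz_um: float = 2.5
    dt_min: float = 10.0
    n_z: int = 60

    def __post_init__(self) -> None:
        for name in ("dx_um", "dy_um", "dz_um", "dt_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_z < 2:
            raise ValueError("n_z must be >= 2")

    @property
    def depth_um(self) -> float:
        """Total imaged depth, ``n_z * dz_um``."""
        return self.n_z * self.dz_um

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing as ``(dz, dy, dx)`` in μm."""
        return (self.dz_um, self.dy_um, self.dx_um)

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx_um * self.dy_um * self.dz_um


@dataclass
class ImageSeries4D:
    """A two(+)-channel volumetric time series with physical calibration.

    ``data`` has axis order ``(t, c, z, y, x)``; ``times_min`` gives the
    acquisition time of each stack in minutes and must be strictly
    increasing; ``channels`` names axis 1.
    """

    data: np.ndarray
    times_min: np.ndarray
    channels: tuple[str, ...]
    calibration: Calibration

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 5:
            raise ValueError("data must be 5D (t, c, z, y, x)")
        if self.data.shape[0] != self.times_min.shape[0]:
            raise ValueError("times_min length must match number of frames")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        for required in DEFAULT_CHANNELS:
            if required not in self.channels:
                raise ValueError(f"missing required channel {required!r}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def frame(self, t: int, channel: str) -> np.ndarray:
        """The 3D grid of one channel at frame index ``t``."""
        return self.data[t, self.channel_index(channel)]


def _calibration_from_ome(xml_text: str, base: Calibration) -> Calibration:
    """Fill calibration fields from OME-XML pixel metadata when present."""
    try:
        root = ET.fromstring(xml_text)
    except ET.ParseError:
        return base
    ns = {"ome": root.tag.split("}")[0].strip("{")} if "}" in root.tag else {}
    pixels = root.find(".//ome:Pixels", ns) if ns else root.find(".//Pixels")
    if pixels is None:
        return base
    updates = {}
    for attr, field in (
        ("PhysicalSizeX", "dx_um"),
        ("PhysicalSizeY", "dy_um"),
        ("PhysicalSizeZ", "dz_um"),
        ("TimeIncrement", "dt_min"),
    ):
        value = pixels.get(attr)
        if value is not None:
            updates[field] = float(value)
    size_z = pixels.get("SizeZ")
    if size_z is not None:
        updates["n_z"] = int(size_z)
    return replace(base, **updates) if updates else base


def read_series(
    path: str | os.PathLike,
    calibration: Calibration | None = None,
    channels: Sequence[str] = DEFAULT_CHANNELS,
) -> ImageSeries4D:
    """Read a TIFF/OME-TIFF series (file or directory of per-frame stacks).

    Pages are interpreted in ``t -> c -> z`` order.  The page count of a
    single file must factor into ``frames * channels * n_z``; each file of a
    directory must hold ``channels * n_z`` pages (one frame per file, sorted
    by name).  Missing calibration is taken from OME metadata when present,
    else from :class:`Calibration` defaults.
    """
    path = Path(path)
    channels = tuple(channels)
    n_c = len(channels)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise MalformedSeriesError(f"no TIFF files in directory {path}")
        stacks = [_read_pages(f) for f in files]
        cal = _resolve_calibration(files[0], calibration)
        frames = []
        for f, pages in zip(files, stacks):
            if pages.shape[0] != n_c * cal.n_z:
                raise MalformedSeriesError(
                    f"{f}: {pages.shape[0]} pages not equal to "
                    f"channels*n_z = {n_c * cal.n_z}"
                )
            frames.append(pages.reshape(n_c, cal.n_z, *pages.shape[1:]))
        data = np.stack(frames)
    else:
        pages = _read_pages(path)
        cal = _resolve_calibration(path, calibration)
        if pages.ndim == 5:
            data = pages
        else:
            per_frame = n_c * cal.n_z
            if pages.shape[0] % per_frame:
                raise MalformedSeriesError(
                    f"{path}: {pages.shape[0]} pages not divisible by "
                    f"channels*n_z = {per_frame}"
                )
            n_t = pages.shape[0] // per_frame
            data = pages.reshape(n_t, n_c, cal.n_z, *pages.shape[1:])
    times = np.arange(data.shape[0], dtype=float) * cal.dt_min
    return ImageSeries4D(data=data, times_min=times, channels=channels, calibration=cal)


def _read_pages(path: Path) -> np.ndarray:
    try:
        arr = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image series at {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def _resolve_calibration(path: Path, calibration: Calibration | None) -> Calibration:
    if calibration is not None:
        return calibration
    base = Calibration()
    try:
        with tifffile.TiffFile(path) as tif:
            if tif.ome_metadata:
                return _calibration_from_ome(tif.ome_metadata, base)
    except (OSError, ValueError):
        pass
    return base


def write_series(series: ImageSeries4D, path: str | os.PathLike) -> None:
    """Write a series as a multi-page TIFF in ``t -> c -> z`` page order."""
    data = series.data
    pages = data.reshape(-1, *data.shape[3:])
    tifffile.imwrite(os.fspath(path), pages)


def _validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValueError(f"track table missing columns {missing}")
    tracks = tracks[TRACK_COLUMNS]
    if len(tracks):
        if tracks.duplicated(["track_id", "time_min"]).any():
            raise ValueError("duplicate (track_id, time_min) rows")
        bad = set(tracks["state_label"]) - set(STATE_LABELS)
        if bad:
            raise ValueError(f"invalid state labels {sorted(bad)}")
    return tracks


def write_tracks(tracks: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a track table as delimited text (bit-stable for equal input).

    One row per track per frame, sorted by ``(track_id, time_min)``;
    coordinates in μm at 3-decimal precision, times in minutes.
    """
    tracks = _validate_tracks(tracks)
    tracks = tracks.sort_values(["track_id", "time_min"], kind="stable")
    try:
        with open(path, "w", newline="") as fh:
            fh.write("# transvasc track table; coordinates in um, time in min\n")
            tracks.to_csv(fh, index=False, float_format="%.3f", lineterminator="\n")
    except OSError as exc:
        raise OSError(f"cannot write track table to {path}: {exc}") from exc


def read_tracks(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    return _validate_tracks(df)
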