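"""Reading recordings, ROI trace extraction, smoothing and region partitioning.

Handles multi-page TIFF image stacks and trace tables (CSV: first column
time_s, one column per cell), extracts mean-intensity ROI traces, applies the
rolling-average noise reduction (window = 5% of the data points by default),
and splits an islet into the three ordered regions (distal / middle /
proximal) used for wave categorisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, OutOfBoundsError

__all__ = [
    "CalciumRecording",
    "RoiSet",
    "RegionPartition",
    "read_stack",
    "write_stack",
    "extract_roi_traces",
    "smooth_traces",
    "smoothing_window",
    "partition_regions",
    "delta_f_over_f0",
    "read_traces_csv",
    "write_traces_csv",
    "read_rois",
    "write_rois",
]


@dataclass
class CalciumRecording:
    """Per-cell fluorescence traces on a fixed frame clock.

    ``traces`` is (n_cells, n_frames) in arbitrary units; frame timestamps are
    t = frame_index / fps with 0-based frame indices.
    """

    traces: np.ndarray
    fps: float
    cell_ids: Sequence[str]
    geometry: "IsletGeometry | None" = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2D (cells x frames)")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if not np.all(np.isfinite(self.traces)):
            raise ValueError("traces must be finite")
        self.cell_ids = tuple(str(c) for c in self.cell_ids)
        if len(self.cell_ids) != self.traces.shape[0]:
            raise ValueError("cell_ids length must match trace rows")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        """Capture duration n_frames / fps (400 frames at 3 frames/s -> 133 s)."""
        return self.n_frames / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass(frozen=True)
class RoiSet:
    """Circular ROIs: centres (um by default, or pixels), one diameter per ROI."""

    ids: tuple[str, ...]
    centers: np.ndarray  # (n, 2)
    diameters: np.ndarray  # (n,)
    units: str = "um"  # "um" or "px"

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(
            self, "diameters", np.broadcast_to(np.asarray(self.diameters, dtype=float), (len(self.ids),)).copy()
        )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ROI ids must be unique")
        if np.any(self.diameters <= 0):
            raise ValueError("ROI diameters must be > 0")

    def validate_study_range(self, low: int = 18, high: int = 40) -> None:
        """Warn (never error) when the ROI count is outside the advisory range."""
        n = len(self.ids)
        if not low <= n <= high:
            warnings.warn(
                f"{n} ROIs is outside the advisory {low}-{high} per-islet range",
                stacklevel=2,
            )

    @classmethod
    def from_geometry(cls, geometry, diameter: float = 15.0) -> "RoiSet":
        return cls(
            ids=tuple(geometry.cell_ids),
            centers=geometry.positions.copy(),
            diameters=np.full(geometry.n_cells, float(diameter)),
        )


@dataclass(frozen=True)
class RegionPartition:
    """Assignment of each cell to one of n ordered regions along an axis.

    Region labels run 1 (distal, most negative projection) to n_regions
    (proximal). ``projections`` are the cells' coordinates along ``axis`` (um).
    """

    cell_ids: tuple[str, ...]
    labels: np.ndarray  # (n_cells,) int, 1..n_regions
    axis: np.ndarray  # unit 2-vector
    projections: np.ndarray  # (n_cells,)
    n_regions: int

    def region_cells(self, region: int) -> tuple[str, ...]:
        return tuple(
            cid for cid, lab in zip(self.cell_ids, self.labels) if lab == region
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_ids": list(self.cell_ids),
                "labels": self.labels.tolist(),
                "axis": self.axis.tolist(),
                "projections_um": self.projections.tolist(),
                "n_regions": self.n_regions,
            },
            sort_keys=True,
        )


# --------------------------------------------------------------------------
# stacks


def read_stack(path) -> np.ndarray:
    """Read a multi-page single-channel TIFF as a (frames, H, W) array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise FormatError(f"{path}: TIFF has 0 pages")
        spp = tif.pages[0].samplesperpixel
        if spp != 1:
            raise FormatError(
                f"{path}: expected single-channel TIFF, got {spp} channels"
            )
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected frames x H x W, got shape {arr.shape}")
    return arr


def write_stack(stack: np.ndarray, path) -> None:
    """Write a (frames, H, W) array as a multi-page single-channel TIFF."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise FormatError("stack must be (frames, H, W) with >= 1 frame")
    tifffile.imwrite(path, stack, photometric="minisblack")


def extract_roi_traces(
    stack: np.ndarray,
    rois: RoiSet,
    fps: float,
    pixel_size: float | None = None,
) -> CalciumRecording:
    """Mean pixel intensity within each circular ROI, per frame.

    ROI centres in um require ``pixel_size`` (um/pixel); the um origin is
    mapped to the image centre, matching :func:`isletwave.synth.render_movie`.
    Pixel centres sit at integer 0-based coordinates.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise FormatError("stack must be (frames, H, W)")
    nf, h, w = stack.shape
    if rois.units == "um":
        if pixel_size is None:
            raise ValueError("pixel_size (um/pixel) is required for ROIs in um")
        centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        centers_px = rois.centers / pixel_size + centre
        radii_px = rois.diameters / 2.0 / pixel_size
    else:
        centers_px = rois.centers
        radii_px = rois.diameters / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    flat = stack.reshape(nf, -1)
    traces = np.empty((len(rois.ids), nf))
    for i, ((x, y), r) in enumerate(zip(centers_px, radii_px)):
        if x - r < -0.5 or x + r > w - 0.5 or y - r < -0.5 or y + r > h - 0.5:
            raise OutOfBoundsError(
                f"ROI {rois.ids[i]} (centre {x:.1f},{y:.1f} px, radius {r:.1f} px) "
                f"extends outside the {w}x{h} image"
            )
        mask = ((xx - x) ** 2 + (yy - y) ** 2 <= r**2).ravel()
        if not mask.any():
            raise OutOfBoundsError(f"ROI {rois.ids[i]} covers no pixels")
        traces[i] = flat[:, mask].mean(axis=1)
    return CalciumRecording(traces=traces, fps=fps, cell_ids=rois.ids)


# --------------------------------------------------------------------------
# smoothing


def smoothing_window(n_frames: int, window_fraction: float = 0.05) -> int:
    """Rolling-average window: round(fraction * n_frames), forced odd, >= 1.

    400 frames at the default 5% gives round(20) = 20 -> 21.
    """
    if not 0 < window_fraction < 1:
        raise ValueError("window_fraction must be in (0, 1)")
    w = int(round(window_fraction * n_frames))
    if w % 2 == 0:
        w += 1
    return max(w, 1)


def smooth_traces(
    recording: CalciumRecording, window_fraction: float = 0.05
) -> CalciumRecording:
    """Centred moving average with window = round(fraction * n_frames), odd.

    Edges use the truncated (shrinking) window so output length equals input
    length; constant traces pass through unchanged.
    """
    if recording.n_frames < 2:
        raise ValueError("smoothing requires >= 2 frames")
    w = smoothing_window(recording.n_frames, window_fraction)
    df = pd.DataFrame(recording.traces.T)
    sm = df.rolling(window=w, center=True, min_periods=1).mean().to_numpy().T
    return CalciumRecording(
        traces=sm,
        fps=recording.fps,
        cell_ids=recording.cell_ids,
        geometry=recording.geometry,
        meta={**recording.meta, "smoothing_window": w},
    )


def delta_f_over_f0(
    recording: CalciumRecording, f0_quantile: float = 0.1
) -> CalciumRecording:
    """dF/F0 transform with F0 = the per-cell lower decile of the trace."""
    f0 = np.quantile(recording.traces, f0_quantile, axis=1, keepdims=True)
    denom = np.where(np.abs(f0) > 1e-12, f0, 1.0)
    return CalciumRecording(
        traces=(recording.traces - f0) / denom,
        fps=recording.fps,
        cell_ids=recording.cell_ids,
        geometry=recording.geometry,
        meta={**recording.meta, "dff_f0_quantile": f0_quantile},
    )


# --------------------------------------------------------------------------
# region partition


def _principal_axis(positions: np.ndarray) -> np.ndarray:
    centred = positions - positions.mean(axis=0)
    cov = centred.T @ centred
    if np.allclose(cov, 0):
        raise ValueError(
            "degenerate geometry (all positions identical): supply an explicit axis"
        )
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, int(np.argmax(evals))]
    # Rotation-invariant sign convention based on the projection distribution:
    # positive skew; on (near-)symmetric clouds, the largest-magnitude
    # projection points in the positive direction.
    proj = centred @ u
    m3 = np.mean(proj**3)
    scale = np.mean(proj**2) ** 1.5
    skew = m3 / scale if scale > 0 else 0.0
    if skew < -1e-9 or (abs(skew) <= 1e-9 and proj.max() < -proj.min()):
        u = -u
    return u


def partition_regions(
    geometry_or_rois,
    n_regions: int = 3,
    axis: str | np.ndarray = "principal",
) -> RegionPartition:
    """Split cells into n ordered bands of equal count (+-1) along an axis.

    The default axis is the first principal axis of the positions; an explicit
    unit vector may be given instead (e.g. a wave-propagation direction
    recovered from onset times). Bands are ordered distal (region 1, most
    negative projection) to proximal (region ``n_regions``).
    """
    positions = getattr(geometry_or_rois, "positions", None)
    if positions is None:
        positions = geometry_or_rois.centers
        ids = geometry_or_rois.ids
    else:
        ids = geometry_or_rois.cell_ids
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < n_regions:
        raise ValueError(f"need at least {n_regions} cells, got {n}")
    if isinstance(axis, str):
        if axis != "principal":
            raise ValueError("axis must be 'principal' or an explicit unit vector")
        u = _principal_axis(positions)
    else:
        u = np.asarray(axis, dtype=float)
        nrm = np.linalg.norm(u)
        if nrm == 0:
            raise ValueError("axis vector must be nonzero")
        u = u / nrm
    proj = positions @ u
    order = np.argsort(proj, kind="stable")
    labels = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(order, n_regions), start=1):
        labels[chunk] = k
    return RegionPartition(
        cell_ids=tuple(ids),
        labels=labels,
        axis=u,
        projections=proj,
        n_regions=n_regions,
    )


# --------------------------------------------------------------------------
# tables


def write_traces_csv(recording: CalciumRecording, path) -> None:
    """Trace table CSV: first column time_s, then one column per cell id."""
    df = pd.DataFrame(recording.traces.T, columns=list(recording.cell_ids))
    df.insert(0, "time_s", recording.times)
    df.to_csv(path, index=False)


def read_traces_csv(path, fps: float | None = None) -> CalciumRecording:
    """Read a trace table CSV (first column time_s); fps inferred if omitted."""
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise FormatError(f"{path}: expected a time_s column followed by cell columns")
    times = df["time_s"].to_numpy(dtype=float)
    if fps is None:
        if len(times) < 2:
            raise FormatError(f"{path}: cannot infer fps from fewer than 2 frames")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: time_s must be strictly increasing")
        fps = 1.0 / float(np.mean(dt))
    cells = df.columns[1:]
    return CalciumRecording(
        traces=df[cells].to_numpy(dtype=float).T, fps=fps, cell_ids=list(cells)
    )


def write_rois(rois: RoiSet, path) -> None:
    pd.DataFrame(
        {
            "id": rois.ids,
            "x_um": rois.centers[:, 0],
            "y_um": rois.centers[:, 1],
            "diameter_um": rois.diameters,
        }
    ).to_csv(path, index=False)


def read_rois(path) -> RoiSet:
    df = pd.read_csv(path)
    needed = {"id", "x_um", "y_um", "diameter_um"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: ROI CSV needs columns {sorted(needed)}")
    return RoiSet(
        ids=tuple(df["id"].astype(str)),
        centers=df[["x_um", "y_um"]].to_numpy(dtype=float),
        diameters=df["diameter_um"].to_numpy(dtype=float),
    )
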