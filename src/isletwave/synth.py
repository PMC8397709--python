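"""Synthetic islet Ca2+ recordings with ground truth.

Generates 2D islet geometries (cell/ROI centres), per-cell GCaMP-like
fluorescence traces for the five activity regimes used to categorise in vivo
islet recordings, rendered image stacks, and whole longitudinal cohorts.
Every generator is a pure function of its seed, and each recording carries a
ground-truth channel (level, wave origin, true velocity, per-cell onset
times) so downstream detection, classification, velocity and connectivity
code can be validated without animal data.

Activity regimes
----------------
0  inactive       baseline + noise only
1  oscillations   per-cell transients at independent random times, no
                  spatially ordered onsets
2  partial wave   one wavefront from a peripheral origin recruiting only
                  cells within a recruitment radius (< islet diameter)
3  full wave      wavefront recruiting every cell; onset(cell) =
                  distance(origin, cell) / wave_velocity + event start
4  superwave      the full wave repeated n_events (>= 2) times per capture
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import FormatError, OutOfBoundsError, PackingInfeasibleError
from .recording_io import CalciumRecording

__all__ = [
    "IsletGeometry",
    "SimulationParams",
    "GroundTruth",
    "CohortDesign",
    "DEFAULT_COHORT_DESIGN",
    "make_islet_geometry",
    "simulate_recording",
    "render_movie",
    "simulate_cohort",
    "transient_kernel",
]

# Fraction of the islet disc area that rejection sampling can realistically
# fill with min_spacing discs before we call the packing infeasible.
_PACKING_SAFETY = 0.7


@dataclass(frozen=True)
class IsletGeometry:
    """Cell/ROI centre positions (um) inside a bounded circular islet.

    Positions are relative to the islet centroid; every position lies within
    ``islet_radius`` of the origin and pairwise distances are >= ``min_spacing``.
    """

    cell_ids: tuple[str, ...]
    positions: np.ndarray  # (n_cells, 2) um
    islet_radius: float
    min_spacing: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValueError("positions must be a (n_cells, 2) array with n_cells >= 1")
        if len(self.cell_ids) != pos.shape[0]:
            raise ValueError("cell_ids and positions length mismatch")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids must be unique")
        if np.any(np.linalg.norm(pos, axis=1) > self.islet_radius + 1e-9):
            raise ValueError("all positions must lie within islet_radius of the origin")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def diameter(self) -> float:
        return 2.0 * self.islet_radius

    def pairwise_distances(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_ids": list(self.cell_ids),
                "positions_um": self.positions.tolist(),
                "islet_radius_um": self.islet_radius,
                "min_spacing_um": self.min_spacing,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "IsletGeometry":
        d = json.loads(text)
        return cls(
            cell_ids=tuple(d["cell_ids"]),
            positions=np.asarray(d["positions_um"], dtype=float),
            islet_radius=float(d["islet_radius_um"]),
            min_spacing=float(d["min_spacing_um"]),
        )


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one synthetic capture.

    Units: times in s, velocity in um/s, fluorescence in arbitrary relative
    units. Defaults emulate the study's acquisition (3 frames/s, 400-frame
    captures) with GCaMP-like transient kinetics.
    """

    level: int
    wave_velocity: float | None = None  # um/s, required for levels 2-4
    n_events: int = 1
    rise_time: float = 0.3
    decay_time: float = 2.0
    amplitude: float = 1.0
    noise_sd: float = 0.05
    baseline: float = 1.0
    fps: float = 3.0
    n_frames: int = 400
    seed: int = 0
    recruitment_fraction: float = 0.4  # of islet diameter, level 2 only
    osc_rate: float | None = None  # expected level-1 events per cell per capture
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        if self.level not in (0, 1, 2, 3, 4):
            raise ValueError(f"level must be in 0..4, got {self.level}")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.level in (2, 3, 4):
            if self.wave_velocity is None:
                raise ValueError(f"wave_velocity is required for level {self.level}")
            if self.wave_velocity <= 0:
                raise ValueError("wave_velocity must be > 0")
        if self.level == 4 and self.n_events < 2:
            raise ValueError("level 4 (superwave) requires n_events >= 2")
        if self.rise_time <= 0 or self.decay_time <= 0:
            raise ValueError("rise_time and decay_time must be > 0")

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class GroundTruth:
    """Truth channel accompanying a simulated recording."""

    level: int
    origin: np.ndarray | None  # um, levels 2-4
    true_velocity: float | None  # um/s
    onset_times: Mapping[str, tuple[float, ...]]  # per cell, s; may be empty
    recruited_cells: tuple[frozenset, ...]  # per event
    event_starts: tuple[float, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "level": self.level,
                "origin_um": None if self.origin is None else list(map(float, self.origin)),
                "true_velocity_um_s": self.true_velocity,
                "onset_times_s": {k: list(v) for k, v in self.onset_times.items()},
                "recruited_cells": [sorted(s) for s in self.recruited_cells],
                "event_starts_s": list(self.event_starts),
            },
            sort_keys=True,
        )


def make_islet_geometry(
    n_cells: int,
    islet_radius: float = 60.0,
    min_spacing: float = 12.0,
    seed: int = 0,
    max_restarts: int = 50,
) -> IsletGeometry:
    """Sample cell centres uniformly in a disc with a minimum-spacing constraint.

    Rejection sampling with bounded retries. Raises
    :class:`PackingInfeasibleError` when the spacing discs cannot plausibly fit
    (area bound with a safety factor) or when sampling fails repeatedly.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if islet_radius <= 0 or min_spacing <= 0:
        raise ValueError("islet_radius and min_spacing must be > 0")
    # Area-based feasibility: each cell claims a disc of radius min_spacing/2.
    claimed = n_cells * (min_spacing / 2.0) ** 2
    available = _PACKING_SAFETY * (islet_radius + min_spacing / 2.0) ** 2
    if claimed > available:
        raise PackingInfeasibleError(
            f"cannot place {n_cells} cells with spacing {min_spacing} um in a "
            f"{islet_radius} um radius islet (area bound)"
        )
    rng = np.random.default_rng(seed)
    per_point_tries = 200
    for _ in range(max_restarts):
        pts: list[np.ndarray] = []
        ok = True
        for _ in range(n_cells):
            placed = False
            for _ in range(per_point_tries):
                # uniform in the disc
                r = islet_radius * np.sqrt(rng.random())
                th = 2 * np.pi * rng.random()
                p = np.array([r * np.cos(th), r * np.sin(th)])
                if all(np.linalg.norm(p - q) >= min_spacing for q in pts):
                    pts.append(p)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            ids = tuple(f"c{i:03d}" for i in range(n_cells))
            return IsletGeometry(ids, np.array(pts), islet_radius, min_spacing)
    raise PackingInfeasibleError(
        f"rejection sampling failed after {max_restarts} restarts "
        f"(n={n_cells}, radius={islet_radius}, spacing={min_spacing})"
    )


def transient_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Single-compartment Ca2+ transient: (1 - exp(-t/rise)) * exp(-t/decay), t >= 0."""
    t = np.asarray(t, dtype=float)
    k = (1.0 - np.exp(-t / rise)) * np.exp(-t / decay)
    return np.where(t >= 0.0, k, 0.0)


def kernel_half_max_time(rise: float, decay: float) -> float:
    """Time after onset at which the transient kernel first crosses half its peak."""
    tgrid = np.linspace(0.0, rise * np.log(1.0 + decay / rise), 20001)
    k = transient_kernel(tgrid, rise, decay)
    half = 0.5 * k[-1] if k[-1] >= k.max() * (1 - 1e-9) else 0.5 * k.max()
    idx = int(np.searchsorted(k, half))
    if idx == 0:
        return 0.0
    # linear interpolation between grid points
    t0, t1 = tgrid[idx - 1], tgrid[idx]
    k0, k1 = k[idx - 1], k[idx]
    return float(t0 + (half - k0) / (k1 - k0) * (t1 - t0))


def _event_starts(params: SimulationParams) -> np.ndarray:
    """Deterministic event start times, away from the capture edges."""
    T = params.duration_s
    if params.level in (0, 1):
        return np.array([])
    n = params.n_events if params.level == 4 else 1
    if n == 1:
        return np.array([0.25 * T])
    return T * (0.1 + 0.55 * np.arange(n) / (n - 1))


def _pick_origin(geometry: IsletGeometry, rng: np.random.Generator) -> int:
    """Peripheral origin: the cell with maximal projection on a random direction."""
    th = 2 * np.pi * rng.random()
    u = np.array([np.cos(th), np.sin(th)])
    return int(np.argmax(geometry.positions @ u))


def simulate_recording(
    geometry: IsletGeometry, params: SimulationParams
) -> tuple[CalciumRecording, GroundTruth]:
    """Simulate one capture at the requested activity level, with ground truth.

    Onset times for wave levels follow onset(cell) = start + dist(origin, cell)
    / wave_velocity; level-1 onsets are independent per-cell Poisson times with
    no spatial ordering. Identical geometry+params (incl. seed) reproduce
    bit-identical traces.
    """
    rng = np.random.default_rng(params.seed)
    n = geometry.n_cells
    t = np.arange(params.n_frames) / params.fps
    traces = np.full((n, params.n_frames), float(params.baseline))
    onsets: dict[str, list[float]] = {cid: [] for cid in geometry.cell_ids}
    recruited: list[frozenset] = []
    origin = None
    velocity = None
    starts = _event_starts(params)

    if params.level == 1:
        T = params.duration_s
        rate = params.osc_rate if params.osc_rate is not None else 2.0
        counts = rng.poisson(rate, size=n)
        if counts.sum() == 0:
            counts[rng.integers(n)] = 1  # recruited set nonempty for levels >= 1
        ev_cells: list[str] = []
        ev_starts: list[float] = []
        for i, cid in enumerate(geometry.cell_ids):
            times = rng.uniform(0.05 * T, 0.85 * T, size=counts[i])
            for t0 in sorted(times):
                onsets[cid].append(float(t0))
                ev_cells.append(cid)
                ev_starts.append(float(t0))
        recruited.append(frozenset(ev_cells))
        starts = np.array([min(ev_starts)]) if ev_starts else np.array([])
    elif params.level >= 2:
        origin_idx = _pick_origin(geometry, rng)
        origin = geometry.positions[origin_idx].copy()
        velocity = float(params.wave_velocity)
        dists = np.linalg.norm(geometry.positions - origin, axis=1)
        if params.level == 2:
            radius = params.recruitment_fraction * geometry.diameter
            rec_mask = dists <= radius
        else:
            rec_mask = np.ones(n, dtype=bool)
        for start in starts:
            ev = []
            for i, cid in enumerate(geometry.cell_ids):
                if rec_mask[i]:
                    t0 = float(start + dists[i] / velocity)
                    onsets[cid].append(t0)
                    ev.append(cid)
            recruited.append(frozenset(ev))

    # superpose transients
    for i, cid in enumerate(geometry.cell_ids):
        for t0 in onsets[cid]:
            traces[i] += params.amplitude * transient_kernel(
                t - t0, params.rise_time, params.decay_time
            )

    if params.poisson_noise:
        scale = 100.0  # photons per intensity unit
        traces = rng.poisson(np.clip(traces, 0, None) * scale) / scale
    if params.noise_sd > 0:
        traces = traces + rng.normal(0.0, params.noise_sd, size=traces.shape)

    recording = CalciumRecording(
        traces=traces,
        fps=params.fps,
        cell_ids=geometry.cell_ids,
        geometry=geometry,
        meta={"level_truth": params.level, "seed": params.seed},
    )
    truth = GroundTruth(
        level=params.level,
        origin=origin,
        true_velocity=velocity,
        onset_times={cid: tuple(v) for cid, v in onsets.items() if v},
        recruited_cells=tuple(recruited),
        event_starts=tuple(float(s) for s in starts),
    )
    return recording, truth


def render_movie(
    recording: CalciumRecording,
    geometry: IsletGeometry,
    pixel_size: float = 2.0,
    image_shape: tuple[int, int] = (96, 96),
    spot_diameter: float | None = None,
    background: float = 0.0,
    counts_per_unit: float = 1000.0,
) -> np.ndarray:
    """Render traces as a (frames, H, W) uint16 stack of Gaussian spots.

    Each frame is the sum of isotropic Gaussian spots centred at the cell
    positions (islet centroid mapped to the image centre), with per-frame
    amplitude equal to the cell's trace value, on a constant background.
    Intensities are quantised at ``counts_per_unit`` counts per fluorescence
    unit into 16-bit, so a written/re-read TIFF round-trips exactly.
    """
    if recording.n_frames == 0:
        raise FormatError("cannot render an empty recording (0 frames)")
    h, w = image_shape
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    px = geometry.positions / pixel_size + centre  # (x, y) in pixel coords
    for cid, (x, y) in zip(geometry.cell_ids, px):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise OutOfBoundsError(
                f"cell {cid} maps outside the {w}x{h} image at pixel ({x:.1f}, {y:.1f})"
            )
    if spot_diameter is None:
        spot_diameter = geometry.min_spacing
    sigma_px = (spot_diameter / 4.0) / pixel_size
    yy, xx = np.mgrid[0:h, 0:w]
    foot = np.empty((geometry.n_cells, h * w))
    for i, (x, y) in enumerate(px):
        g = np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma_px**2)))
        foot[i] = g.ravel()
    frames = recording.traces.T @ foot + background  # (n_frames, h*w)
    counts = np.clip(np.round(frames * counts_per_unit), 0, 65535).astype(np.uint16)
    return counts.reshape(recording.n_frames, h, w)


# --------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortDesign:
    """Longitudinal cohort specification.

    ``level_distributions[group][week]`` maps activity level -> probability
    (summing to 1). Each islet keeps its geometry across weeks; per-islet,
    per-week seeds derive deterministically from the master seed.
    """

    groups: tuple[str, ...]
    weeks: tuple[int, ...]
    islets_per_group: int
    level_distributions: Mapping[str, Mapping[int, Mapping[int, float]]]
    n_cells_range: tuple[int, int] = (18, 40)
    islet_radius: float = 60.0
    min_spacing: float = 12.0
    wave_velocity: float = 40.0
    noise_sd: float = 0.05
    fps: float = 3.0
    n_frames: int = 400
    islets_per_animal: int = 3

    def validate(self) -> None:
        if self.islets_per_group < 1:
            raise ValueError("islets_per_group must be >= 1")
        for g in self.groups:
            if g not in self.level_distributions:
                raise ValueError(f"missing level distributions for group {g!r}")
            for wk in self.weeks:
                if wk not in self.level_distributions[g]:
                    raise ValueError(f"missing week {wk} distribution for group {g!r}")
                dist = self.level_distributions[g][wk]
                if any(p < 0 for p in dist.values()):
                    raise ValueError("level probabilities must be >= 0")
                if any(lv not in (0, 1, 2, 3, 4) for lv in dist):
                    raise ValueError("levels must be in 0..4")
                if abs(sum(dist.values()) - 1.0) > 1e-9:
                    raise ValueError(
                        f"level distribution for {g!r} week {wk} must sum to 1"
                    )


#: Default design emulating the study's time course: sham islets progressively
#: lose coordinated activity (almost all inactive by week 10) while VSG islets
#: rise to wave/superwave behaviour by week 8 and keep it.
DEFAULT_COHORT_DESIGN = CohortDesign(
    groups=("sham", "VSG"),
    weeks=(0, 4, 8, 10),
    islets_per_group=20,
    level_distributions={
        "sham": {
            0: {1: 0.10, 2: 0.30, 3: 0.50, 4: 0.10},
            4: {0: 0.10, 1: 0.30, 2: 0.30, 3: 0.30},
            8: {0: 0.30, 1: 0.40, 2: 0.20, 3: 0.10},
            10: {0: 0.80, 1: 0.20},
        },
        "VSG": {
            0: {1: 0.10, 2: 0.30, 3: 0.50, 4: 0.10},
            4: {1: 0.10, 2: 0.20, 3: 0.50, 4: 0.20},
            8: {3: 0.60, 4: 0.40},
            10: {3: 0.50, 4: 0.50},
        },
    },
)


@dataclass(frozen=True)
class CohortRecord:
    """One islet x week entry: identity, truth level and analysis provenance."""

    animal: str
    group: str
    week: int
    islet: str
    level_truth: int
    seed: int


def simulate_cohort(
    design: CohortDesign = DEFAULT_COHORT_DESIGN, seed: int = 0
) -> list[tuple[CalciumRecording, GroundTruth, CohortRecord]]:
    """Simulate every islet x week capture of a longitudinal cohort design."""
    design.validate()
    rng = np.random.default_rng(seed)
    out: list[tuple[CalciumRecording, GroundTruth, CohortRecord]] = []
    for group in design.groups:
        for i in range(design.islets_per_group):
            islet_id = f"{group}_islet{i:02d}"
            animal = f"{group}_m{i // design.islets_per_animal:02d}"
            n_cells = int(rng.integers(design.n_cells_range[0], design.n_cells_range[1] + 1))
            geom_seed = int(rng.integers(2**31))
            geometry = make_islet_geometry(
                n_cells, design.islet_radius, design.min_spacing, seed=geom_seed
            )
            for week in design.weeks:
                dist = design.level_distributions[group][week]
                levels = sorted(dist)
                probs = np.array([dist[lv] for lv in levels])
                level = int(rng.choice(levels, p=probs / probs.sum()))
                rec_seed = int(rng.integers(2**31))
                params = SimulationParams(
                    level=level,
                    wave_velocity=design.wave_velocity if level >= 2 else None,
                    n_events=2 if level == 4 else 1,
                    noise_sd=design.noise_sd,
                    fps=design.fps,
                    n_frames=design.n_frames,
                    seed=rec_seed,
                )
                recording, truth = simulate_recording(geometry, params)
                recording.meta.update(
                    {"animal": animal, "group": group, "week": week, "islet": islet_id}
                )
                out.append(
                    (
                        recording,
                        truth,
                        CohortRecord(animal, group, week, islet_id, level, rec_seed),
                    )
                )
    return out
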