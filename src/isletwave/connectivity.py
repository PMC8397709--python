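"""Pairwise Pearson beta-cell connectivity over a 100-frame analysis window.

Computes the cell-pair Pearson correlation matrix (autocorrelation excluded),
decides which pairs are "significantly connected" (circular-shift permutation
null by default, or a fixed R threshold), summarises connectivity (% connected
pairs, % connected cells, mean positive R), assigns the standard colour bins
(blue 0.1-0.25, green 0.26-0.5, yellow 0.51-0.75, red 0.76-1.0), and builds
Cartesian connectivity-map drawing specifications with hub-cell highlighting.
Week-0 baseline correction of longitudinal metrics lives here too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import BaselineUndefinedError
from .recording_io import CalciumRecording

__all__ = [
    "CorrelationMatrix",
    "ConnectivityResult",
    "COLOUR_BINS",
    "pairwise_pearson",
    "significant_pairs",
    "mean_positive_r",
    "bin_correlation",
    "connectivity_map",
    "baseline_correct",
]

#: Colour bins for drawn connections, closed on the printed endpoints and
#: continued half-open between them: values below 0.1 (and all negative R)
#: are not drawn.
COLOUR_BINS = (
    ("blue", 0.1, 0.255),
    ("green", 0.255, 0.505),
    ("yellow", 0.505, 0.755),
    ("red", 0.755, 1.0),
)


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson R with the diagonal masked out.

    ``values`` is (n, n) with NaN on the diagonal and on pairs involving a
    zero-variance trace; ``defined`` flags the usable off-diagonal entries.
    """

    values: np.ndarray
    cell_ids: tuple[str, ...]
    window_start: int
    window_len: int
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        if self.defined is None:
            self.defined = np.isfinite(v) & ~np.eye(v.shape[0], dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def offdiag_values(self) -> np.ndarray:
        """Defined off-diagonal R values, each unordered pair once."""
        iu = np.triu_indices(self.n_cells, k=1)
        vals = self.values[iu]
        return vals[self.defined[iu]]


@dataclass
class ConnectivityResult:
    """Significant-pair adjacency and summary connectivity metrics."""

    adjacency: np.ndarray  # (n, n) bool, symmetric
    cell_ids: tuple[str, ...]
    pct_connected_pairs: float
    pct_connected_cells: float
    mean_positive_r: float | None  # None when no positive R exists (flagged)
    degrees: np.ndarray  # (n,) significant-partner counts
    method: dict = field(default_factory=dict)
    pvalues: np.ndarray | None = None


def pairwise_pearson(
    recording: CalciumRecording,
    window_start: int = 0,
    window_len: int = 100,
) -> CorrelationMatrix:
    """Pearson R for every unordered cell pair over exactly ``window_len`` frames.

    Zero-variance traces within the window yield undefined (NaN, flagged) R —
    never silent zeros. The recording should already be smoothed.
    """
    if recording.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if window_start < 0 or window_start + window_len > recording.n_frames:
        raise ValueError(
            f"window [{window_start}, {window_start + window_len}) outside "
            f"recording of {recording.n_frames} frames"
        )
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    X = recording.traces[:, window_start : window_start + window_len]
    sd = X.std(axis=1)
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R = np.asarray(R, dtype=float)
    R[~ok, :] = np.nan
    R[:, ~ok] = np.nan
    keep = np.isfinite(R)
    R[keep] = np.clip(R[keep], -1.0, 1.0)
    # round-off guard at the boundary: identical (or exactly opposite) traces
    # have |R| = 1 mathematically, but the cov/sd quotient can land an ulp shy
    snap = keep & (np.abs(np.abs(R) - 1.0) < 1e-12)
    R[snap] = np.sign(R[snap])
    np.fill_diagonal(R, np.nan)
    defined = np.isfinite(R)
    return CorrelationMatrix(
        values=R,
        cell_ids=tuple(recording.cell_ids),
        window_start=window_start,
        window_len=window_len,
        defined=defined,
    )


def _circular_r_all_lags(X: np.ndarray) -> np.ndarray:
    """R[i, j, lag] = Pearson of cell i vs cell j circularly shifted by lag.

    Rows are standardised (population SD); zero-variance rows give NaN.
    Computed for all lags at once via FFT cross-correlation.
    """
    n, L = X.shape
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mu) / sd
    F = np.fft.rfft(Z, axis=1)
    prod = F[:, None, :] * np.conj(F[None, :, :])
    return np.fft.irfft(prod, n=L, axis=2) / L


def significant_pairs(
    corr: CorrelationMatrix,
    recording: CalciumRecording,
    method: str = "permutation",
    n_shuffles: int = 1000,
    alpha: float = 0.05,
    threshold_r: float = 0.25,
    seed: int = 0,
) -> ConnectivityResult:
    """Decide which cell pairs are significantly connected.

    Permutation method: the null distribution of R for each pair is built
    from circular shifts of one trace (preserving autocorrelation); a pair is
    significant when p = (1 + #{null >= observed}) / (n_null + 1) <= alpha
    and R > 0 (one-sided, positive). When ``n_shuffles`` >= window_len - 1
    every distinct nonzero lag is used once, making the test exhaustive,
    rank-exact and seed-independent; otherwise ``n_shuffles`` lags are
    sampled with the seed. Threshold method: significant iff R >=
    ``threshold_r``. Undefined correlations are excluded from numerator and
    denominator of all percentages.
    """
    n = corr.n_cells
    if tuple(recording.cell_ids) != corr.cell_ids:
        raise ValueError("recording and correlation matrix cells mismatch")
    adjacency = np.zeros((n, n), dtype=bool)
    pvalues = None
    if method == "threshold":
        with np.errstate(invalid="ignore"):
            adjacency = corr.defined & (corr.values >= threshold_r)
        meta = {"method": "threshold", "threshold_r": threshold_r}
    elif method == "permutation":
        if n_shuffles < 100:
            raise ValueError("n_shuffles < 100 gives unstable null quantiles")
        L = corr.window_len
        X = recording.traces[:, corr.window_start : corr.window_start + L]
        rall = _circular_r_all_lags(X)
        obs = rall[:, :, 0]
        lags = np.arange(1, L)
        if n_shuffles >= L - 1:
            null = rall[:, :, 1:]
            n_null = L - 1
            exhaustive = True
        else:
            rng = np.random.default_rng(seed)
            pick = rng.choice(lags, size=n_shuffles, replace=True)
            null = rall[:, :, pick]
            n_null = n_shuffles
            exhaustive = False
        with np.errstate(invalid="ignore"):
            exceed = np.sum(null >= obs[:, :, None], axis=2)
        pvalues = (1.0 + exceed) / (n_null + 1.0)
        with np.errstate(invalid="ignore"):
            adjacency = corr.defined & (pvalues <= alpha) & (corr.values > 0)
        pvalues = np.where(corr.defined, pvalues, np.nan)
        meta = {
            "method": "permutation",
            "alpha": alpha,
            "n_null": int(n_null),
            "exhaustive": exhaustive,
            "seed": seed,
        }
    else:
        raise ValueError(f"unknown method {method!r}")
    adjacency &= adjacency.T  # symmetry (already symmetric in both methods)
    np.fill_diagonal(adjacency, False)

    iu = np.triu_indices(n, k=1)
    defined_pairs = int(corr.defined[iu].sum())
    sig_pairs = int(adjacency[iu].sum())
    pct_pairs = 100.0 * sig_pairs / defined_pairs if defined_pairs else 0.0
    degrees = adjacency.sum(axis=1)
    has_defined = corr.defined.any(axis=1)
    n_eval_cells = int(has_defined.sum())
    pct_cells = (
        100.0 * int((degrees[has_defined] > 0).sum()) / n_eval_cells
        if n_eval_cells
        else 0.0
    )
    meta.update({"window_start": corr.window_start, "window_len": corr.window_len})
    return ConnectivityResult(
        adjacency=adjacency,
        cell_ids=corr.cell_ids,
        pct_connected_pairs=pct_pairs,
        pct_connected_cells=pct_cells,
        mean_positive_r=mean_positive_r(corr),
        degrees=degrees,
        method=meta,
        pvalues=pvalues,
    )


def mean_positive_r(corr: CorrelationMatrix) -> float | None:
    """Mean of the strictly positive off-diagonal R values; None if none exist."""
    vals = corr.offdiag_values()
    if vals.size == 0:
        raise ValueError("correlation matrix has no defined off-diagonal entries")
    pos = vals[vals > 0]
    if pos.size == 0:
        return None
    return float(pos.mean())


def bin_correlation(r: float) -> str:
    """Colour bin for a drawn connection; 'none' below 0.1 and for negative R."""
    if not np.isfinite(r) or abs(r) > 1.0:
        raise ValueError(f"R must be in [-1, 1], got {r}")
    if r < COLOUR_BINS[0][1]:
        return "none"
    for name, lo, hi in COLOUR_BINS[:-1]:
        if lo <= r < hi:
            return name
    return COLOUR_BINS[-1][0]


def connectivity_map(geometry, corr: CorrelationMatrix, result: ConnectivityResult) -> dict:
    """Drawable Cartesian connectivity-map specification (JSON-serialisable).

    One line segment per significant pair, coloured by its R bin; cells with
    the maximum significant degree (> 0) are flagged as hub dots.
    """
    if tuple(geometry.cell_ids) != corr.cell_ids:
        raise ValueError("geometry and correlation matrix cells mismatch")
    degrees = result.degrees
    max_deg = int(degrees.max()) if degrees.size else 0
    points = [
        {
            "id": cid,
            "x_um": float(geometry.positions[i, 0]),
            "y_um": float(geometry.positions[i, 1]),
            "degree": int(degrees[i]),
            "is_hub": bool(max_deg > 0 and degrees[i] == max_deg),
        }
        for i, cid in enumerate(corr.cell_ids)
    ]
    segments = []
    iu = np.triu_indices(corr.n_cells, k=1)
    for i, j in zip(*iu):
        if result.adjacency[i, j]:
            r = float(corr.values[i, j])
            segments.append(
                {
                    "cell_i": corr.cell_ids[i],
                    "cell_j": corr.cell_ids[j],
                    "R": r,
                    "bin": bin_correlation(max(r, -1.0)),
                }
            )
    return {"points": points, "segments": segments, "islet_radius_um": float(geometry.islet_radius)}


def baseline_correct(
    metric_by_week: Mapping[int, float | None], baseline_week: int = 0
) -> dict[int, float]:
    """Express a longitudinal metric as fold-change over its baseline week.

    Raises :class:`BaselineUndefinedError` when the baseline value is
    missing, undefined (None/NaN) or zero, so callers flag-and-exclude the
    record instead of silently propagating bad numbers. Weeks with undefined
    values are dropped from the output.
    """
    if baseline_week not in metric_by_week:
        raise BaselineUndefinedError(f"baseline week {baseline_week} absent")
    base = metric_by_week[baseline_week]
    if base is None or not np.isfinite(base) or base == 0:
        raise BaselineUndefinedError(
            f"baseline week {baseline_week} value {base!r} is undefined or zero"
        )
    out: dict[int, float] = {}
    for wk, v in metric_by_week.items():
        if v is None or not np.isfinite(v):
            continue
        out[wk] = float(v) / float(base)
    return out
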