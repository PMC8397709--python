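"""Longitudinal cohort aggregation, group comparison and reporting.

Aggregates per-islet metrics (activity level, wavefront velocity, %
significantly connected pairs, mean positive R) into the sham-vs-VSG
longitudinal comparison, applies week-0 baseline correction per islet, runs
the two-group unpaired t-test as plumbing, and writes a deterministic report
(CSV tables, JSON of every number, optional map/heatmap gallery).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import (
    baseline_correct,
    connectivity_map,
    pairwise_pearson,
    significant_pairs,
)
from .errors import BaselineUndefinedError
from .recording_io import smooth_traces
from .synth import CohortDesign, DEFAULT_COHORT_DESIGN, simulate_cohort
from .waves import classify_recording

__all__ = [
    "GroupComparison",
    "summarize_levels",
    "compare_groups",
    "analyze_cohort",
    "add_baseline_corrected",
    "report",
]

METRIC_COLUMNS = ("level", "pct_connected_pairs", "mean_positive_r")


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided unpaired Student's t-test result."""

    t: float
    p: float
    df: float
    n1: int
    n2: int
    flag: str | None = None  # e.g. "zero-variance"


def summarize_levels(records: pd.DataFrame, level_col: str = "level") -> pd.DataFrame:
    """Mean level +- SEM, islet count and level distribution per group x week.

    Empty group x week combinations are omitted (with a warning upstream when
    requested explicitly). Distribution columns n_level_0..4 sum to n.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["group", "week", "n", "mean_level", "sem_level"]
            + [f"n_level_{k}" for k in range(5)]
        )
    rows = []
    for (group, week), sub in records.groupby(["group", "week"], sort=True):
        lv = sub[level_col].to_numpy(dtype=float)
        row = {
            "group": group,
            "week": week,
            "n": len(lv),
            "mean_level": float(lv.mean()),
            "sem_level": float(lv.std(ddof=1) / np.sqrt(len(lv))) if len(lv) > 1 else 0.0,
        }
        for k in range(5):
            row[f"n_level_{k}"] = int((lv == k).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(sample1, sample2) -> GroupComparison:
    """Two-sided unpaired Student's t-test (equal variances) between two samples.

    Identical samples return t = 0, p = 1. Zero pooled variance with unequal
    means is reported as p -> 0 with a flag rather than NaN.
    """
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2 finite values")
    df = len(a) + len(b) - 2
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, 1.0, df, len(a), len(b))
        return GroupComparison(np.inf, 0.0, df, len(a), len(b), flag="zero-variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(float(t), float(p), df, len(a), len(b))


def analyze_cohort(
    design: CohortDesign = DEFAULT_COHORT_DESIGN,
    seed: int = 0,
    connectivity_method: str = "permutation",
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    window_start: int = 0,
    window_len: int = 100,
    keep_artifacts: bool = False,
):
    """Simulate a cohort and run the full analysis on every capture.

    Returns a metrics DataFrame (one row per islet x week) carrying analysis
    provenance; with ``keep_artifacts`` also returns per-capture
    (geometry, correlation matrix, connectivity result) keyed by
    (islet, week) for map galleries.
    """
    sims = simulate_cohort(design, seed=seed)
    rows = []
    artifacts = {}
    for recording, truth, rec in sims:
        cls = classify_recording(recording, recording.geometry)
        smoothed = smooth_traces(recording)
        corr = pairwise_pearson(smoothed, window_start, window_len)
        conn = significant_pairs(
            corr,
            smoothed,
            method=connectivity_method,
            n_shuffles=n_shuffles,
            alpha=alpha,
            seed=rec.seed,
        )
        vels = cls.velocities
        rows.append(
            {
                "animal": rec.animal,
                "group": rec.group,
                "week": rec.week,
                "islet": rec.islet,
                "level": cls.level,
                "level_truth": truth.level,
                "mean_velocity_um_s": float(np.mean(vels)) if vels else np.nan,
                "pct_connected_pairs": conn.pct_connected_pairs,
                "pct_connected_cells": conn.pct_connected_cells,
                "mean_positive_r": (
                    np.nan if conn.mean_positive_r is None else conn.mean_positive_r
                ),
                "seed": rec.seed,
                "method": connectivity_method,
                "window_start": window_start,
                "window_len": window_len,
            }
        )
        if keep_artifacts:
            artifacts[(rec.islet, rec.week)] = (recording.geometry, corr, conn)
    df = pd.DataFrame(rows)
    if keep_artifacts:
        return df, artifacts
    return df


def add_baseline_corrected(
    records: pd.DataFrame,
    metrics: tuple[str, ...] = ("pct_connected_pairs", "mean_positive_r"),
    baseline_week: int = 0,
) -> pd.DataFrame:
    """Add per-islet fold-change columns ``<metric>_bc`` over the baseline week.

    Islets whose baseline value is missing, undefined or zero are flagged in
    ``<metric>_bc_excluded`` and left NaN — never silently propagated.
    """
    out = records.copy()
    for m in metrics:
        out[f"{m}_bc"] = np.nan
        out[f"{m}_bc_excluded"] = False
    for islet, sub in records.groupby("islet"):
        for m in metrics:
            series = {
                int(wk): (None if not np.isfinite(v) else float(v))
                for wk, v in zip(sub["week"], sub[m])
            }
            try:
                corrected = baseline_correct(series, baseline_week)
            except BaselineUndefinedError:
                out.loc[sub.index, f"{m}_bc_excluded"] = True
                continue
            for idx, wk in zip(sub.index, sub["week"]):
                if int(wk) in corrected:
                    out.loc[idx, f"{m}_bc"] = corrected[int(wk)]
    return out


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def report(
    records: pd.DataFrame,
    output_dir,
    baseline_week: int = 0,
    artifacts: dict | None = None,
    make_figures: bool = False,
) -> dict:
    """Write the cohort report: tables, machine-readable JSON, optional gallery.

    Emits ``levels_summary.csv`` (level time course per group x week),
    ``metrics.csv`` (per-islet rows with baseline-corrected columns) and
    ``report.json`` containing every reported number plus provenance; rerun on
    identical inputs produces byte-identical JSON. Empty record sets produce
    an explicit no-data report.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    payload: dict = {"n_records": int(len(records))}
    if records.empty:
        payload["levels_summary"] = []
        payload["group_tests"] = []
        payload["note"] = "no data"
        levels = summarize_levels(records)
        levels.to_csv(output_dir / "levels_summary.csv", index=False)
        records.to_csv(output_dir / "metrics.csv", index=False)
    else:
        corrected = add_baseline_corrected(records, baseline_week=baseline_week)
        levels = summarize_levels(records)
        levels.to_csv(output_dir / "levels_summary.csv", index=False)
        corrected.to_csv(output_dir / "metrics.csv", index=False)
        payload["levels_summary"] = levels.to_dict(orient="records")
        tests = []
        groups = sorted(records["group"].unique())
        if len(groups) == 2:
            g1, g2 = groups
            for week in sorted(records["week"].unique()):
                wk = records[records["week"] == week]
                for metric in METRIC_COLUMNS:
                    a = wk.loc[wk["group"] == g1, metric].to_numpy(dtype=float)
                    b = wk.loc[wk["group"] == g2, metric].to_numpy(dtype=float)
                    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
                    if len(a) < 2 or len(b) < 2:
                        warnings.warn(
                            f"week {week} {metric}: insufficient data for t-test"
                        )
                        continue
                    cmpres = compare_groups(a, b)
                    tests.append(
                        {
                            "week": int(week),
                            "metric": metric,
                            "group1": g1,
                            "group2": g2,
                            "mean1": float(a.mean()),
                            "mean2": float(b.mean()),
                            "t": cmpres.t if np.isfinite(cmpres.t) else None,
                            "p": cmpres.p,
                            "flag": cmpres.flag,
                        }
                    )
        payload["group_tests"] = tests
        payload["provenance"] = {
            "seeds": sorted(int(s) for s in records["seed"].unique())
            if "seed" in records
            else [],
            "method": sorted(records["method"].unique()) if "method" in records else [],
            "window_len": sorted(int(w) for w in records["window_len"].unique())
            if "window_len" in records
            else [],
            "baseline_week": baseline_week,
        }
    if artifacts and make_figures:
        _write_gallery(artifacts, output_dir / "gallery")
        payload["gallery"] = sorted(p.name for p in (output_dir / "gallery").iterdir())
    text = json.dumps(_round_floats(payload), sort_keys=True, indent=1)
    (output_dir / "report.json").write_text(text)
    return payload


def _write_gallery(artifacts: dict, gallery_dir: Path) -> None:
    """Per-islet Cartesian connectivity maps and R heatmaps as PNGs."""
    from matplotlib.figure import Figure

    gallery_dir.mkdir(parents=True, exist_ok=True)
    bin_colors = {"blue": "#3b6fd4", "green": "#2e9e4f", "yellow": "#e3c000", "red": "#d43b3b"}
    for (islet, week), (geometry, corr, conn) in sorted(artifacts.items()):
        spec = connectivity_map(geometry, corr, conn)
        fig = Figure(figsize=(8, 4))
        ax1, ax2 = fig.subplots(1, 2)
        for seg in spec["segments"]:
            i = corr.cell_ids.index(seg["cell_i"])
            j = corr.cell_ids.index(seg["cell_j"])
            ax1.plot(
                geometry.positions[[i, j], 0],
                geometry.positions[[i, j], 1],
                color=bin_colors.get(seg["bin"], "0.7"),
                lw=1,
            )
        hubs = [p for p in spec["points"] if p["is_hub"]]
        ax1.scatter(
            geometry.positions[:, 0], geometry.positions[:, 1], s=20, c="0.3", zorder=3
        )
        if hubs:
            ax1.scatter(
                [p["x_um"] for p in hubs],
                [p["y_um"] for p in hubs],
                s=60,
                c="red",
                zorder=4,
            )
        ax1.set_aspect("equal")
        ax1.set_title(f"{islet} wk{week}")
        ax1.set_xlabel("x (um)")
        ax1.set_ylabel("y (um)")
        im = ax2.imshow(
            np.nan_to_num(corr.values, nan=0.0), vmin=0, vmax=1, cmap="jet"
        )
        fig.colorbar(im, ax=ax2, label="Pearson R")
        ax2.set_title("pairwise R")
        fig.tight_layout()
        fig.savefig(gallery_dir / f"{islet}_wk{week}.png", dpi=90)
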