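"""Aggregation of transition measurements over printing conditions.

Groups per-image transition distances by the experimental factors
(extrusion pressure, nozzle inner diameter, silicone coating), computes
per-condition summaries, and reports descriptive trend slopes of the mean
transition distance against pressure and nozzle diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, MixedCorrectionError
from .metric import TransitionResult

__all__ = [
    "PrintCondition",
    "ConditionSummary",
    "summarize",
    "pool_summaries",
    "trend_report",
    "results_to_dataframe",
    "summaries_to_dataframe",
    "plot_summaries",
]

#: flags whose presence excludes a result from summaries by default
_EXCLUDE_FLAGS = frozenset({"clipped_at_boundary", "negative_after_correction"})


@dataclass(frozen=True, order=True)
class PrintCondition:
    """Experimental factor levels of one printed filament."""

    pressure_psi: float
    nozzle_id_um: float
    coated: bool = False
    bioink_pair: str = "red-blue"

    def __post_init__(self) -> None:
        if self.pressure_psi <= 0 or self.nozzle_id_um <= 0:
            raise InvalidInputError("pressure and nozzle diameter must be > 0")


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition n / mean / sd / min / max of the transition distance."""

    condition: PrintCondition
    n: int
    mean_mm: float
    sd_mm: float
    min_mm: float
    max_mm: float
    used_corrected: bool


def _value(r: TransitionResult, use_corrected: bool) -> float:
    if use_corrected:
        if r.corrected_mm is None:
            raise MixedCorrectionError(
                f"result {r.image_id!r} lacks a diffusion correction but "
                "corrected summaries were requested"
            )
        return r.corrected_mm
    return r.distance_mm


def summarize(
    results: Iterable[TransitionResult],
    use_corrected: bool = False,
    include_flagged: bool = False,
) -> list[ConditionSummary]:
    """One summary per distinct printing condition.

    Flagged results (boundary-clipped or negative after correction) are
    excluded unless ``include_flagged``. Output order is deterministic:
    pressure, then nozzle diameter, then coated. Empty input gives an
    empty list. Requesting corrected summaries while any retained result
    lacks a correction is an explicit error, never a silent mix.
    """
    groups: dict[PrintCondition, list[float]] = {}
    for r in results:
        if r.condition is None:
            raise InvalidInputError(
                f"result {r.image_id!r} carries no printing condition"
            )
        if not include_flagged and r.flags & _EXCLUDE_FLAGS:
            continue
        groups.setdefault(r.condition, []).append(_value(r, use_corrected))

    out = []
    for cond in sorted(groups, key=lambda c: (c.pressure_psi, c.nozzle_id_um, c.coated)):
        # sorted so the summary depends only on the multiset of values,
        # making input-order invariance exact in floating point
        vals = np.sort(np.asarray(groups[cond], dtype=float))
        out.append(
            ConditionSummary(
                condition=cond,
                n=len(vals),
                mean_mm=float(vals.mean()),
                sd_mm=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                min_mm=float(vals.min()),
                max_mm=float(vals.max()),
                used_corrected=use_corrected,
            )
        )
    return out


def pool_summaries(summaries: Sequence[ConditionSummary]) -> list[ConditionSummary]:
    """Merge summaries of the same condition with exact pooling formulas.

    Pooled mean is the n-weighted mean; pooled variance combines
    within-batch sums of squares and between-batch mean offsets, matching
    what a single pass over the concatenated raw values would give.
    """
    groups: dict[PrintCondition, list[ConditionSummary]] = {}
    for s in list(summaries):
        groups.setdefault(s.condition, []).append(s)

    out = []
    for cond in sorted(groups, key=lambda c: (c.pressure_psi, c.nozzle_id_um, c.coated)):
        parts = groups[cond]
        if len({p.used_corrected for p in parts}) > 1:
            raise MixedCorrectionError(
                "cannot pool corrected with uncorrected summaries"
            )
        n = sum(p.n for p in parts)
        mean = sum(p.n * p.mean_mm for p in parts) / n
        ss = sum(
            (p.n - 1) * p.sd_mm**2 + p.n * (p.mean_mm - mean) ** 2 for p in parts
        )
        out.append(
            ConditionSummary(
                condition=cond,
                n=n,
                mean_mm=float(mean),
                sd_mm=float(np.sqrt(ss / (n - 1))) if n > 1 else 0.0,
                min_mm=min(p.min_mm for p in parts),
                max_mm=max(p.max_mm for p in parts),
                used_corrected=parts[0].used_corrected,
            )
        )
    return out


def _ls_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Ordinary least-squares slope (with intercept)."""
    return float(np.polyfit(x, y, 1)[0])


def trend_report(summaries: Sequence[ConditionSummary]) -> dict:
    """Descriptive slope diagnostics of mean distance vs each factor.

    Per (nozzle, coated) cell: the least-squares slope of mean_mm against
    pressure (needs >= 2 pressure levels, else the cell is marked 'n/a').
    Per (pressure, coated) cell: the slope of mean_mm against nozzle inner
    diameter. Purely descriptive; no hypothesis tests.
    """
    df = summaries_to_dataframe(summaries)
    report: dict = {"pressure_trends": [], "nozzle_trends": []}
    if df.empty:
        return report

    for (nozzle, coated), cell in df.groupby(["nozzle_id_um", "coated"]):
        entry = {"nozzle_id_um": float(nozzle), "coated": bool(coated)}
        if cell["pressure_psi"].nunique() >= 2:
            entry["slope_mm_per_psi"] = _ls_slope(
                cell["pressure_psi"].to_numpy(), cell["mean_mm"].to_numpy()
            )
            entry["n_levels"] = int(cell["pressure_psi"].nunique())
        else:
            entry["slope_mm_per_psi"] = "n/a"
            entry["n_levels"] = int(cell["pressure_psi"].nunique())
        report["pressure_trends"].append(entry)

    for (pressure, coated), cell in df.groupby(["pressure_psi", "coated"]):
        entry = {"pressure_psi": float(pressure), "coated": bool(coated)}
        if cell["nozzle_id_um"].nunique() >= 2:
            entry["slope_mm_per_um"] = _ls_slope(
                cell["nozzle_id_um"].to_numpy(), cell["mean_mm"].to_numpy()
            )
            entry["n_levels"] = int(cell["nozzle_id_um"].nunique())
        else:
            entry["slope_mm_per_um"] = "n/a"
            entry["n_levels"] = int(cell["nozzle_id_um"].nunique())
        report["nozzle_trends"].append(entry)
    return report


def results_to_dataframe(results: Iterable[TransitionResult]) -> pd.DataFrame:
    """Flat measurement table (one row per image) for CSV export."""
    rows = []
    for r in results:
        row = {
            "image_id": r.image_id,
            "start_px": r.start_px,
            "end_px": r.end_px,
            "distance_px": r.distance_px,
            "distance_mm": r.distance_mm,
            "corrected_mm": r.corrected_mm,
            "uncertainty_mm": r.uncertainty_mm,
            "direction": r.direction,
            "elapsed_s": r.elapsed_s,
            "flags": ";".join(sorted(r.flags)),
        }
        if r.condition is not None:
            row.update(
                pressure_psi=r.condition.pressure_psi,
                nozzle_id_um=r.condition.nozzle_id_um,
                coated=r.condition.coated,
                bioink_pair=r.condition.bioink_pair,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_to_dataframe(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    rows = [
        {
            "pressure_psi": s.condition.pressure_psi,
            "nozzle_id_um": s.condition.nozzle_id_um,
            "coated": s.condition.coated,
            "bioink_pair": s.condition.bioink_pair,
            "n": s.n,
            "mean_mm": s.mean_mm,
            "sd_mm": s.sd_mm,
            "min_mm": s.min_mm,
            "max_mm": s.max_mm,
            "used_corrected": s.used_corrected,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


def plot_summaries(
    summaries: Sequence[ConditionSummary], out_dir: str | Path
) -> list[Path]:
    """Transition distance vs pressure, one panel per nozzle size,
    regular vs coated series with sd error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = summaries_to_dataframe(summaries)
    paths = []
    for nozzle, panel in df.groupby("nozzle_id_um"):
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for coated, series in panel.groupby("coated"):
            series = series.sort_values("pressure_psi")
            ax.errorbar(
                series["pressure_psi"],
                series["mean_mm"],
                yerr=series["sd_mm"],
                marker="o",
                capsize=3,
                label="coated" if coated else "regular",
            )
        ax.set_xlabel("pressure (psi)")
        ax.set_ylabel("transition distance (mm)")
        ax.set_title(f"nozzle {nozzle:g} μm")
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"transition_vs_pressure_nozzle{nozzle:g}um.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
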