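"""Through-origin diffusion model and transition-distance correction.

After deposition the dyes keep spreading inside the filament, so the
apparent transition distance grows with the time elapsed before imaging.
Empirically this growth is well described by a straight line through the
origin, D(t) = slope * t; fitting that line on a time series of repeated
measurements of one filament and subtracting its prediction isolates the
printing-induced transition distance from the dye-spreading artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CorrectionRefusedError, DegenerateDesignError, InvalidInputError
from .metric import TransitionResult

__all__ = ["DiffusionModel", "fit_diffusion_model", "correct_transition"]


@dataclass(frozen=True)
class DiffusionModel:
    """Through-origin linear growth law of apparent transition distance.

    ``r_squared`` is the uncentered coefficient of determination about the
    through-origin fit (1 - SS_res / sum d^2). ``slope_se_mm_per_s`` is NaN
    when fewer than two points leave no residual degrees of freedom. A
    negative fitted slope is kept as fitted and flagged, never clamped.
    """

    slope_mm_per_s: float
    n_points: int
    r_squared: float
    residual_sd_mm: float
    slope_se_mm_per_s: float = float("nan")
    intercept_mm: float = 0.0
    negative_slope: bool = False

    def predict(self, t_s: float | np.ndarray) -> np.ndarray:
        """Diffusion-attributable transition distance at elapsed time t."""
        return self.intercept_mm + self.slope_mm_per_s * np.asarray(t_s, dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope_mm_per_s": self.slope_mm_per_s,
                    "n_points": self.n_points,
                    "r_squared": self.r_squared,
                    "residual_sd_mm": self.residual_sd_mm,
                    "slope_se_mm_per_s": self.slope_se_mm_per_s,
                    "intercept_mm": self.intercept_mm,
                    "negative_slope": self.negative_slope,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DiffusionModel":
        return cls(**json.loads(Path(path).read_text()))


def fit_diffusion_model(
    times_s, distances_mm, with_intercept: bool = False
) -> DiffusionModel:
    """Least-squares fit of distance on elapsed time, through the origin.

    slope = sum(t_i d_i) / sum(t_i^2), the closed-form through-origin
    estimator; ``with_intercept=True`` fits an ordinary line instead, for
    diagnostics only. A single (t, d) pair with t > 0 gives slope d/t.
    """
    t = np.asarray(times_s, dtype=float)
    d = np.asarray(distances_mm, dtype=float)
    if t.shape != d.shape or t.ndim != 1:
        raise InvalidInputError("times and distances must be 1-D and equal length")
    if len(t) < 1:
        raise InvalidInputError("need at least one (time, distance) pair")
    if np.any(t < 0):
        raise InvalidInputError("elapsed times must be >= 0")
    if not np.any(t > 0):
        raise DegenerateDesignError("all elapsed times are zero: slope unidentifiable")

    n = len(t)
    if with_intercept:
        if n < 2:
            raise InvalidInputError("intercept fit needs >= 2 points")
        slope, intercept = np.polyfit(t, d, 1)
        resid = d - (intercept + slope * t)
        dof = n - 2
    else:
        slope = float(t @ d) / float(t @ t)
        intercept = 0.0
        resid = d - slope * t
        dof = n - 1

    ss_res = float(resid @ resid)
    ss_tot = float(d @ d) if not with_intercept else float(((d - d.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    residual_sd = float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0
    slope_se = (
        residual_sd / float(np.sqrt(t @ t)) if dof > 0 else float("nan")
    )
    return DiffusionModel(
        slope_mm_per_s=float(slope),
        n_points=n,
        r_squared=float(r_squared),
        residual_sd_mm=residual_sd,
        slope_se_mm_per_s=slope_se,
        intercept_mm=float(intercept),
        negative_slope=bool(slope < 0),
    )


def correct_transition(
    result: TransitionResult,
    model: DiffusionModel,
    elapsed_s: float | None = None,
) -> TransitionResult:
    """Subtract the model's diffusion prediction from a measured distance.

    corrected = distance_mm - slope * elapsed_s. The elapsed time comes
    from the argument or, failing that, the measurement's own metadata; it
    is never silently assumed to be zero. A negative corrected value is
    kept and flagged. When the model carries a finite slope standard
    error, the measurement uncertainty is propagated as
    sqrt(u^2 + (t * se)^2).
    """
    t = elapsed_s if elapsed_s is not None else result.elapsed_s
    if t is None:
        raise CorrectionRefusedError(
            "no elapsed time available; refusing to assume t = 0"
        )
    if t < 0:
        raise InvalidInputError("elapsed_s must be >= 0")
    corrected = result.distance_mm - model.slope_mm_per_s * t
    uncertainty = result.uncertainty_mm
    if np.isfinite(model.slope_se_mm_per_s):
        uncertainty = float(
            np.hypot(result.uncertainty_mm, t * model.slope_se_mm_per_s)
        )
    return result.with_correction(float(corrected), uncertainty_mm=uncertainty)
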