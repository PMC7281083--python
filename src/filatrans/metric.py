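"""The 90-10 transition-distance statistic.

The transition distance is the length of filament over which the smoothed
red signal, normalized to its own extremes, falls from 90% to 10% of its
maximum while the dispensed material switches from the red ink to the blue
one. Crossings are located to sub-pixel precision by linear interpolation
and the pixel distance converted to millimetres with a stated uncertainty
floor of 0.02 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Optional

import numpy as np

from .errors import NoTransitionError
from .pipeline import ColorProfile

if TYPE_CHECKING:  # pragma: no cover
    from .report import PrintCondition

__all__ = [
    "TransitionResult",
    "normalize_red",
    "find_crossings",
    "measure_transition",
    "UNCERTAINTY_FLOOR_MM",
]

#: Measurement-uncertainty floor, mm.
UNCERTAINTY_FLOOR_MM = 0.02

_FLAT_EPS = 1e-12


@dataclass(frozen=True)
class TransitionResult:
    """One measured transition distance.

    ``start_px``/``end_px`` are the fractional axial positions of the 90%
    and 10% crossings (in scan order along the print direction);
    ``corrected_mm`` stays None until a diffusion correction is applied.
    Flags: ``undetermined_direction``, ``clipped_at_boundary``,
    ``negative_after_correction``.
    """

    start_px: float
    end_px: float
    distance_px: float
    distance_mm: float
    uncertainty_mm: float
    direction: str | None
    corrected_mm: float | None = None
    flags: frozenset[str] = frozenset()
    image_id: str = ""
    elapsed_s: float | None = None
    mm_per_px: float | None = None
    condition: Optional["PrintCondition"] = None

    def with_correction(
        self, corrected_mm: float, uncertainty_mm: float | None = None
    ) -> "TransitionResult":
        flags = set(self.flags)
        if corrected_mm < 0:
            flags.add("negative_after_correction")
        return replace(
            self,
            corrected_mm=corrected_mm,
            uncertainty_mm=self.uncertainty_mm if uncertainty_mm is None else uncertainty_mm,
            flags=frozenset(flags),
        )


def normalize_red(profile: ColorProfile) -> np.ndarray:
    """Smoothed red channel rescaled to [0, 1] by its own extremes.

    Self-normalization makes the statistic invariant to affine intensity
    changes (exposure, white balance along the red axis). A flat red
    profile carries no transition and raises :class:`NoTransitionError`.
    """
    if len(profile) < 2:
        raise NoTransitionError("profile has fewer than 2 positions")
    r = profile.smoothed_rgb[:, 0]
    lo, hi = float(r.min()), float(r.max())
    if hi - lo < _FLAT_EPS:
        raise NoTransitionError("flat red profile: no transition present")
    return (r - lo) / (hi - lo)


def find_crossings(
    r_norm: np.ndarray,
    hi: float = 0.9,
    lo: float = 0.1,
    direction: str = "a_to_b",
    pixel_exact: bool = False,
) -> tuple[float, float]:
    """Fractional sample indices of the hi and lo crossings.

    Scanning in the print direction, the end of the transition is the first
    sample where the signal has dropped to <= ``lo``; its start is the last
    preceding sample still >= ``hi``. This outermost-bracket rule is robust
    to repeated threshold crossings under noise. Each crossing is refined
    by linear interpolation between the bracketing samples unless
    ``pixel_exact`` is set. For direction ``b_to_a`` the signal is scanned
    in reverse and indices mapped back, so start <= end always holds in
    scan order (returned here in array coordinates).
    """
    if not 0.0 < lo < hi < 1.0:
        raise NoTransitionError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    r = np.asarray(r_norm, dtype=float)
    n = len(r)
    if direction == "b_to_a":
        s, e = find_crossings(r[::-1], hi=hi, lo=lo, direction="a_to_b",
                              pixel_exact=pixel_exact)
        return (n - 1) - s, (n - 1) - e
    if direction != "a_to_b":
        raise NoTransitionError(f"direction must be determined, got {direction!r}")

    below = np.flatnonzero(r <= lo)
    if len(below) == 0:
        raise NoTransitionError(
            f"signal never reaches the lower bound {lo}", failed_bound="lo"
        )
    j = int(below[0])
    above = np.flatnonzero(r[:j] >= hi)
    if len(above) == 0:
        raise NoTransitionError(
            f"signal never reaches the upper bound {hi} before dropping to "
            f"{lo}", failed_bound="hi",
        )
    i = int(above[-1])

    if pixel_exact:
        return float(i), float(j)
    # r[i] >= hi and r[i+1] < hi; r[j-1] > lo and r[j] <= lo
    start = float(i) if r[i] == hi else i + (r[i] - hi) / (r[i] - r[i + 1])
    end = float(j) if j == 0 else (j - 1) + (r[j - 1] - lo) / (r[j - 1] - r[j])
    return start, end


def measure_transition(
    profile: ColorProfile,
    hi: float = 0.9,
    lo: float = 0.1,
    uncertainty_floor_mm: float = UNCERTAINTY_FLOOR_MM,
    pixel_exact: bool = False,
) -> TransitionResult:
    """Measure the 90-10 transition distance of a color profile.

    Composes :func:`normalize_red` and :func:`find_crossings`; the pixel
    distance is converted with the profile's mm/px scale. The reported
    uncertainty is the larger of the 0.02 mm floor and one pixel.
    Crossings that touch the profile boundary set ``clipped_at_boundary``.
    """
    flags: set[str] = set()
    if profile.direction is None:
        raise NoTransitionError("transition direction undetermined")
    r_norm = normalize_red(profile)
    idx_start, idx_end = find_crossings(
        r_norm, hi=hi, lo=lo, direction=profile.direction, pixel_exact=pixel_exact
    )
    n = len(r_norm)
    # a crossing whose bracketing interval touches the first or last sample
    # means the transition is not fully contained in the analyzed crop
    if min(idx_start, idx_end) < 1 or max(idx_start, idx_end) > n - 2:
        flags.add("clipped_at_boundary")

    # map fractional array indices to axial positions (handles crops whose
    # covered columns are not 0-based)
    grid = np.arange(n, dtype=float)
    start_px, end_px = np.interp(
        [idx_start, idx_end], grid, profile.positions_px
    )
    distance_px = abs(end_px - start_px)
    distance_mm = distance_px * profile.mm_per_px
    uncertainty_mm = max(uncertainty_floor_mm, profile.mm_per_px)

    return TransitionResult(
        start_px=float(start_px),
        end_px=float(end_px),
        distance_px=float(distance_px),
        distance_mm=float(distance_mm),
        uncertainty_mm=float(uncertainty_mm),
        direction=profile.direction,
        flags=frozenset(flags),
        image_id=profile.image_id,
        elapsed_s=profile.elapsed_s,
        mm_per_px=profile.mm_per_px,
        condition=profile.condition,
    )
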