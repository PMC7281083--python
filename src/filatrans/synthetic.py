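"""Synthetic filament-image generator with closed-form ground truth.

Renders a straight, horizontal two-ink filament (ink A upstream, ink B
downstream) on a plain background. The axial color blend follows a chosen
profile shape whose 90-10 transition width is known analytically, optionally
widened by a post-print dye-spreading law, so every downstream measurement
stage can be validated against an exact oracle without any photograph.

Conventions: pixels are float RGB in [0, 1], row-major, origin top-left;
the filament axis runs along image columns (x), the band spans rows (y).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import norm

from .errors import InvalidSpecError
from .pipeline import RasterImage

__all__ = [
    "Z_90_10",
    "RAMP_90_10_FRACTION",
    "SyntheticFilamentSpec",
    "GroundTruth",
    "mixing_fraction",
    "generate_filament_image",
    "write_image",
    "write_ground_truth",
]

#: 90-10 width of a Gaussian-CDF profile per unit spread sigma:
#: z_{0.9} - z_{0.1} = 2 * Phi^{-1}(0.9).
Z_90_10: float = float(2.0 * norm.ppf(0.9))

#: 90-10 width of a unit linear ramp: the normalized signal spends 80% of
#: the ramp length between the 0.9 and 0.1 levels.
RAMP_90_10_FRACTION: float = 0.8

_PROFILE_KINDS = ("step", "linear_ramp", "gaussian_cdf")
_GROWTH_LAWS = ("none", "linear", "sqrt")


@dataclass(frozen=True)
class SyntheticFilamentSpec:
    """Parameters of one synthetic filament image.

    Defaults emulate the study conditions of the red-to-blue starch-ink
    filaments: a band a few millimetres wide photographed at roughly
    20 px/mm, with a Gaussian-CDF color blend and a linear-in-time apparent
    widening of 0.03060 mm/s (the empirically fitted dye-spreading rate).

    Parameters
    ----------
    profile_param
        Ramp length L in px for ``linear_ramp``; spread sigma in px for
        ``gaussian_cdf``; ignored for ``step``.
    growth_coeff
        mm/s for ``growth_law='linear'``, mm/sqrt(s) for ``'sqrt'``. The
        90-10 width gains ``growth_coeff * t`` (resp. ``* sqrt(t)``) mm.
    edge_softness_px
        Gaussian sigma of the band-boundary blur (0 = hard edges).
    """

    image_height_px: int = 120
    image_width_px: int = 800
    filament_width_px: int = 40
    filament_center_row_px: int = 60
    mm_per_px: float = 0.05
    color_a: tuple[float, float, float] = (0.80, 0.10, 0.12)
    color_b: tuple[float, float, float] = (0.10, 0.12, 0.70)
    background: tuple[float, float, float] = (0.96, 0.95, 0.92)
    profile_kind: str = "gaussian_cdf"
    transition_center_px: float | None = None
    profile_param: float = 10.0
    elapsed_s: float = 0.0
    growth_law: str = "linear"
    growth_coeff: float = 0.03060
    noise_sigma: float = 0.01
    edge_softness_px: float = 1.0
    seed: int = 0

    @property
    def center_px(self) -> float:
        """Transition center; defaults to the middle of the image."""
        if self.transition_center_px is None:
            return self.image_width_px / 2.0
        return float(self.transition_center_px)

    def validate(self) -> None:
        if self.image_height_px < 1 or self.image_width_px < 1:
            raise InvalidSpecError("image dimensions must be >= 1 px")
        if self.mm_per_px <= 0:
            raise InvalidSpecError("mm_per_px must be > 0")
        if self.filament_width_px < 1:
            raise InvalidSpecError("filament_width_px must be >= 1")
        top, bottom = self.band_rows()
        if top < 0 or bottom > self.image_height_px:
            raise InvalidSpecError(
                f"filament band rows [{top}, {bottom}) fall outside the "
                f"{self.image_height_px}-row image"
            )
        if not 0 <= self.center_px < self.image_width_px:
            raise InvalidSpecError("transition_center_px outside the image")
        for name in ("color_a", "color_b", "background"):
            c = getattr(self, name)
            if len(c) != 3 or not all(0.0 <= v <= 1.0 for v in c):
                raise InvalidSpecError(f"{name} must be an RGB triple in [0, 1]")
        if self.profile_kind not in _PROFILE_KINDS:
            raise InvalidSpecError(f"unknown profile_kind {self.profile_kind!r}")
        if self.growth_law not in _GROWTH_LAWS:
            raise InvalidSpecError(f"unknown growth_law {self.growth_law!r}")
        if self.profile_kind != "step" and self.profile_param <= 0:
            raise InvalidSpecError("profile_param must be > 0 for ramp/CDF profiles")
        if self.elapsed_s < 0:
            raise InvalidSpecError("elapsed_s must be >= 0")
        if self.noise_sigma < 0 or self.edge_softness_px < 0:
            raise InvalidSpecError("noise_sigma and edge_softness_px must be >= 0")

    def band_rows(self) -> tuple[int, int]:
        """Half-open row range [top, bottom) of the filament band."""
        top = self.filament_center_row_px - self.filament_width_px // 2
        return top, top + self.filament_width_px

    def growth_widening_px(self) -> float:
        """Additive 90-10 width gain from the post-print growth law, in px."""
        if self.growth_law == "none" or self.elapsed_s == 0:
            return 0.0
        if self.growth_law == "linear":
            gain_mm = self.growth_coeff * self.elapsed_s
        else:  # sqrt
            gain_mm = self.growth_coeff * np.sqrt(self.elapsed_s)
        return float(gain_mm / self.mm_per_px)

    def true_width_px(self) -> float:
        """Closed-form 90-10 width of the rendered profile, in px."""
        if self.profile_kind == "step":
            base = 0.0
        elif self.profile_kind == "linear_ramp":
            base = RAMP_90_10_FRACTION * self.profile_param
        else:
            base = Z_90_10 * self.profile_param
        return base + self.growth_widening_px()


@dataclass(frozen=True)
class GroundTruth:
    """Oracle record accompanying a generated image."""

    true_width_90_10_px: float
    true_width_90_10_mm: float
    transition_center_px: float
    direction: str = "a_to_b"


def mixing_fraction(x, spec: SyntheticFilamentSpec) -> np.ndarray:
    """Fraction g(x) of ink A at axial position ``x`` (px).

    g is monotone non-increasing from 1 (pure A, upstream) to 0 (pure B).
    The profile shape is widened so that its 90-10 width equals the spec's
    closed-form ``true_width_px()``; a step that must carry a positive width
    (nonzero growth) is rendered as the linear ramp of that width.
    """
    spec.validate()
    x = np.asarray(x, dtype=float)
    c = spec.center_px
    width = spec.true_width_px()

    kind = spec.profile_kind
    if kind == "step" and width > 0:
        kind = "linear_ramp"
    if kind == "step":
        return (x < c).astype(float)
    if kind == "linear_ramp":
        L_eff = width / RAMP_90_10_FRACTION
        return np.clip(0.5 - (x - c) / L_eff, 0.0, 1.0)
    sigma_eff = width / Z_90_10
    return norm.sf((x - c) / sigma_eff)


def generate_filament_image(
    spec: SyntheticFilamentSpec,
) -> tuple[RasterImage, GroundTruth]:
    """Render a filament image and its analytic ground truth.

    Pixel color inside the band is ``g(x) * color_a + (1 - g(x)) * color_b``;
    the band boundary is optionally softened by a vertical Gaussian blur;
    i.i.d. Gaussian noise of sd ``noise_sigma`` is added per channel and the
    result clipped to [0, 1]. Identical specs (including seed) give bitwise
    identical rasters.
    """
    spec.validate()
    h, w = spec.image_height_px, spec.image_width_px
    x = np.arange(w, dtype=float)
    g = mixing_fraction(x, spec)

    color_a = np.asarray(spec.color_a, dtype=float)
    color_b = np.asarray(spec.color_b, dtype=float)
    background = np.asarray(spec.background, dtype=float)
    filament_rgb = g[:, None] * color_a + (1.0 - g[:, None]) * color_b  # (W, 3)

    top, bottom = spec.band_rows()
    band = np.zeros(h, dtype=float)
    band[top:bottom] = 1.0
    if spec.edge_softness_px > 0:
        band = gaussian_filter1d(band, sigma=spec.edge_softness_px, mode="constant")

    alpha = band[:, None, None]  # (H, 1, 1)
    pixels = alpha * filament_rgb[None, :, :] + (1.0 - alpha) * background

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        pixels = pixels + rng.normal(0.0, spec.noise_sigma, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)

    image = RasterImage(
        pixels=pixels,
        mm_per_px=spec.mm_per_px,
        elapsed_s=spec.elapsed_s,
        id=f"synthetic-seed{spec.seed}",
    )
    width_px = spec.true_width_px()
    truth = GroundTruth(
        true_width_90_10_px=width_px,
        true_width_90_10_mm=width_px * spec.mm_per_px,
        transition_center_px=spec.center_px,
    )
    return image, truth


def write_image(image: RasterImage, path: str | Path) -> None:
    """Write an 8-bit RGB PNG."""
    import imageio.v3 as iio

    data = np.round(np.clip(image.pixels, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), data, extension=".png")


def write_ground_truth(
    spec: SyntheticFilamentSpec, truth: GroundTruth, path: str | Path
) -> None:
    """Write a JSON sidecar with the spec fields and the true widths."""
    record = {
        "spec": dataclasses.asdict(spec),
        "ground_truth": dataclasses.asdict(truth),
    }
    Path(path).write_text(json.dumps(record, indent=2) + "\n")
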