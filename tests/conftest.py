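import numpy as np
import pytest

from filatrans import ColorProfile, SyntheticFilamentSpec


def clean_spec(**overrides) -> SyntheticFilamentSpec:
    """Noiseless hard-edged spec with no post-print growth, for oracle tests."""
    base = dict(noise_sigma=0.0, edge_softness_px=0.0, growth_law="none")
    base.update(overrides)
    return SyntheticFilamentSpec(**base)


def profile_from_signal(red, mm_per_px=1.0, window_px=1, direction="a_to_b"):
    """Wrap a bare red signal into a ColorProfile (green/blue flat)."""
    red = np.asarray(red, dtype=float)
    rgb = np.column_stack([red, np.full_like(red, 0.1), 1.0 - red])
    return ColorProfile(
        positions_px=np.arange(len(red), dtype=float),
        mean_rgb=rgb,
        smoothed_rgb=rgb.copy(),
        window_px=window_px,
        mm_per_px=mm_per_px,
        direction=direction,
    )


@pytest.fixture
def gauss10_image():
    from filatrans import generate_filament_image

    spec = clean_spec(profile_kind="gaussian_cdf", profile_param=10.0)
    return generate_filament_image(spec)
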