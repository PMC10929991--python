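import numpy as np
import pytest

from ssdekit.imaging_io import CTSlice
from ssdekit.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default thoracic phantom: (spec, hu_image, truth)."""
    spec = PhantomSpec()
    hu, truth = generate_phantom(spec)
    return spec, hu, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom with sigma=20 HU Gaussian noise."""
    spec = PhantomSpec(noise_sigma=20.0, seed=42)
    hu, truth = generate_phantom(spec)
    return spec, hu, truth


@pytest.fixture()
def default_slice(default_phantom) -> CTSlice:
    spec, hu, _ = default_phantom
    return CTSlice(hu_pixels=hu, pixel_spacing=spec.pixel_spacing, ctdi_vol=spec.ctdi_vol)


def ellipse_mask(shape, center, semi_axes, angle_deg=0.0):
    """Boolean raster of a (possibly rotated) ellipse, in pixel units."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    y = rr - center[0]
    x = cc - center[1]
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    a, b = semi_axes  # (along u, along v)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0
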