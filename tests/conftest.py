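import numpy as np
import pytest

from somalayer.core_io import VolumeImage
from somalayer.synthetic import (
    LayerSpec,
    VolumeSpec,
    generate_folded_layer,
    generate_soma_volume,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20150527)


@pytest.fixture(scope="session")
def coordinate_convention():
    """Shared assertion of the package-wide axis convention.

    A voxel set at (x, y, z) = (5, 3, 1) must live at data[z, y, x]: x is
    the fastest-varying storage axis and dims reports (X, Y, Z).
    """
    data = np.zeros((4, 6, 8), dtype=np.uint8)  # (Z, Y, X)
    data[1, 3, 5] = 255
    vol = VolumeImage(data)
    assert vol.dims == (8, 6, 4)
    assert vol.data[1, 3, 5] == 255
    return vol


@pytest.fixture(scope="session")
def small_soma_volume():
    """20 bright spheres (radius 6, 5% peak noise) plus the true centers."""
    spec = VolumeSpec(
        dims=(128, 128, 128),
        n_somata=20,
        soma_radius_vox=6.0,
        min_separation_vox=15.0,
        peak_intensity=200.0,
        background=10.0,
        noise_sigma=10.0,  # 5% of peak
        seed=42,
    )
    return generate_soma_volume(spec)


@pytest.fixture(scope="session")
def flat_layer_with_gap():
    """A flat layer with one planted 30 µm gap disc."""
    spec = LayerSpec(
        extent_um=(300.0, 300.0),
        fold_amplitude_um=0.0,
        cell_spacing_um=12.0,
        jitter_um=1.5,
        gaps=[(150.0, 150.0, 30.0)],
        seed=7,
    )
    return generate_folded_layer(spec)


@pytest.fixture(scope="session")
def folded_layer_with_fps():
    """A folded layer with 5% off-layer false positives at >= 30 µm offset."""
    spec = LayerSpec(
        extent_um=(500.0, 500.0),
        fold_amplitude_um=80.0,
        fold_wavelength_um=400.0,
        cell_spacing_um=12.0,
        jitter_um=1.5,
        fp_fraction=0.05,
        fp_offset_um=(30.0, 60.0),
        seed=11,
    )
    return generate_folded_layer(spec)
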