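import numpy as np
import pytest

from fingermvpa.synth import SynthConfig, generate_subject


@pytest.fixture(scope="session")
def default_subject():
    """One subject at the package's default study conditions."""
    return generate_subject(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced voxel count for simulation-heavy tests (same SNR regime)."""
    return SynthConfig(n_voxels=100, noise_sd=3.2, noise_sd_imagery=4.2,
                       modality_offset_amplitude=8.0, seed=0)


def make_noise_cfg(seed, n_voxels=120):
    """Pure-noise configuration: every signal source switched off."""
    return SynthConfig(
        n_voxels=n_voxels,
        exec_amplitude=0.0,
        imagery_scale=0.0,
        modality_offset_amplitude=0.0,
        noise_sd=1.0,
        noise_sd_imagery=1.0,
        seed=seed,
    )
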