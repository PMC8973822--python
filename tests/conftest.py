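import numpy as np
import pytest

from celloc import segment, synthgen


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, PSF-free, jitter-free membrane-only scene spec."""
    return synthgen.SceneSpec(
        alpha=1.0, alpha_jitter_sd=0.0, psf_sigma=0.0,
        noise_model=synthgen.NoiseModel(poisson_gain=0.0, gaussian_sd=0.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def default_scene():
    """One default-noise scene with its ground truth (seed fixed)."""
    spec = synthgen.SceneSpec(seed=3)
    stack, truth = synthgen.generate_scene(spec)
    return spec, stack, truth


def truth_label_mask(truth: synthgen.GroundTruth) -> segment.LabelMask:
    return segment.LabelMask(labels=truth.true_mask.copy(), provenance="auto")
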