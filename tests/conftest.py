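import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octraman import pipeline, synth
from octraman.octmask import MaskImage, OCTImage

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_cfg() -> synth.SynthConfig:
    """The study conditions: 10 samples/class, 4 images + 8 spectra each."""
    return synth.SynthConfig(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_cfg):
    return synth.simulate_dataset(default_cfg)


@pytest.fixture(scope="session")
def default_matrices(default_dataset):
    return pipeline.extract_features(default_dataset)


@pytest.fixture(scope="session")
def default_results(default_matrices):
    return pipeline.run_datasets(default_matrices)


def full_mask(arr) -> MaskImage:
    """A mask with all provenance flags set, for feeding scan_image directly."""
    return MaskImage(mask=np.asarray(arr, dtype=bool), thresholded=True,
                     voids_filled=True, saturation_removed=True)


def image_of(arr) -> OCTImage:
    return OCTImage(pixels=np.asarray(arr))
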