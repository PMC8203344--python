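from dataclasses import replace

import pytest

import ecgstress as e

# Study-condition corpus: 28 resting + 30 stressed records, 30 s at 360 Hz,
# with mild R-R/amplitude jitter and measurement noise.
N_WITHOUT, N_UNDER = 28, 30
CORPUS_SEED = 0
IMAGE_SIZE = 32  # reduced resolution for training tests; full size is traced separately


def corpus_configs():
    without = replace(e.WITHOUT_STRESS, rr_jitter=0.02, rs_jitter=0.05, noise_sd=0.02)
    under = replace(e.UNDER_STRESS, rr_jitter=0.05, rs_jitter=0.05, noise_sd=0.02)
    return without, under


@pytest.fixture(scope="session")
def corpus():
    without, under = corpus_configs()
    records, manifest = e.synth_dataset(N_WITHOUT, N_UNDER, without, under, seed=CORPUS_SEED)
    return records, manifest


@pytest.fixture(scope="session")
def image_sets(corpus):
    records, _ = corpus
    params = e.STFTParams(image_size=IMAGE_SIZE)
    time_imgs, freq_imgs = e.build_dataset(records, stft_params=params)
    return time_imgs, freq_imgs


@pytest.fixture(scope="session")
def small_images(image_sets):
    """A small balanced image subset for quick estimator tests."""
    time_imgs, _ = image_sets
    without = [im for im in time_imgs if im.label == "without_stress"][:6]
    under = [im for im in time_imgs if im.label == "under_stress"][:6]
    return e.images_to_arrays(without + under)
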