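import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from convar.backbone import ResponseStack, alexnet_backbone
from convar.pipeline import compute_feature_table
from convar.synthetic import generate_labeled_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Seed battery used by all stochastic invariant checks.
BATTERY_SEEDS = (0, 1, 2, 3, 4)

#: Seed of the shared synthetic study set (fixed once for the whole suite).
STUDY_SEED = 20210


def random_stack(seed: int, k: int = 5, h: int = 6, w: int = 6) -> ResponseStack:
    rng = np.random.default_rng(seed)
    return ResponseStack(layer_id=1, responses=rng.random((k, h, w)))


@pytest.fixture(scope="session")
def gabor_cfg():
    return alexnet_backbone("builtin_gabor")


@pytest.fixture(scope="session")
def study_table(gabor_cfg):
    """Features + self-similarity for the 300-image synthetic study set.

    75 images per class (art_like / pattern_like / sparse_like / noise), i.e.
    75 art vs 225 non-art, extracted once per session with the Gabor bank.
    """
    records, _ = generate_labeled_set(n_per_class=75, seed=STUDY_SEED)
    return compute_feature_table(records, gabor_cfg, include_selfsim=True)
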