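from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pai import SyntheticConfig, generate_trial

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture
def small_trial():
    """A small synthetic trial (n=60) with the full nine-variable model."""
    cfg = replace(SyntheticConfig(), n_per_arm=(25, 35))
    return generate_trial(cfg, seed=42)


@pytest.fixture
def noiseless_trial():
    """Zero residual noise: endpoints are an exact function of the design."""
    cfg = replace(SyntheticConfig(), n_per_arm=(30, 50), residual_sd=0.0)
    return generate_trial(cfg, seed=31), cfg


def _nondegenerate(dataset) -> bool:
    """Count-based full-rank guarantee, robust to any single-patient removal.

    Every categorical level must appear at least twice in each arm and each
    numeric covariate must keep at least two distinct values per arm, so no
    leave-one-out fold can have a constant-within-arm column (the condition
    under which a treatment interaction becomes collinear)."""
    for spec in dataset.specs:
        for arm in dataset.arms:
            vals = [r.covariates[spec.name] for r in dataset.records if r.arm == arm]
            if spec.kind in ("binary", "ordinal3"):
                levels = {str(v) for v in vals}
                counts = [sum(str(v) == lv for v in vals) for lv in levels]
                if len(levels) < 2 or min(counts) < 2:
                    return False
            else:
                nums = [float(v) for v in vals]
                if spec.kind == "capped_count":
                    nums = [min(v, float(spec.cap)) for v in nums]
                distinct = sorted(set(nums))
                if len(distinct) < 2:
                    return False
                if sum(v == distinct[0] for v in nums) > len(nums) - 2 and len(distinct) == 2:
                    return False
    return True


def random_small_trial(rng: np.random.Generator):
    """A random nondegenerate trial with total n <= 60."""
    while True:
        n_a = int(rng.integers(18, 29))
        n_b = int(rng.integers(20, 32))
        sd = float(rng.uniform(0.2, 1.2))
        cfg = replace(SyntheticConfig(), n_per_arm=(n_a, n_b), residual_sd=sd)
        seed = int(rng.integers(0, 2**31 - 1))
        dataset = generate_trial(cfg, seed=seed)
        if _nondegenerate(dataset):
            return dataset
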