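import numpy as np
import pytest

from mkmri import (
    BrainMask,
    cohort_labels,
    extract_feature_matrices,
    full_mask,
    generate_cohort,
    single_effect_config,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A fast 8-subject cohort on a small grid with a volume effect."""
    cfg = single_effect_config(
        "volume", seed=7, n_pos=4, n_neg=4, grid_dims=(8, 8, 8),
        n_volumes=40, n_discard=4,
    )
    # default box (1,4)^3 fits the 8^3 grid
    scans = generate_cohort(cfg)
    mask = full_mask(cfg.grid_dims)
    return cfg, scans, mask


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    cfg, scans, mask = tiny_cohort
    mats = extract_feature_matrices(scans, mask, n_discard=cfg.n_discard)
    return mats, cohort_labels(scans), mask


def brute_force_kendall_w(series):
    """Independent rank-and-sum concordance oracle (loops, no vectorization)."""
    series = [list(map(float, s)) for s in series]
    K = len(series)
    n = len(series[0])

    def ranks(values):
        out = [0.0] * n
        for idx, v in enumerate(values):
            less = sum(1 for u in values if u < v)
            equal = sum(1 for u in values if u == v)
            # average rank of the tied block containing v
            out[idx] = less + (equal + 1) / 2.0
        return out

    ranked = [ranks(s) for s in series]
    R = [sum(ranked[k][t] for k in range(K)) for t in range(n)]
    Rbar = sum(R) / n
    S = sum((r - Rbar) ** 2 for r in R)
    return 12.0 * S / (K ** 2 * (n ** 3 - n))


def random_mask(rng, dims, fill=0.7):
    grid = rng.random(dims) < fill
    grid.flat[0] = True  # never empty
    return BrainMask(grid)
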