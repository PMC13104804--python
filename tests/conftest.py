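import numpy as np
import pandas as pd
import pytest

from iit import FeatureMatrix, load_region_atlas
from iit.atlas import RegionRecord


@pytest.fixture(scope="session")
def atlas():
    return load_region_atlas()


@pytest.fixture(scope="session")
def mini_atlas():
    """Three hand-made regions for cheap simulator tests."""
    return [
        RegionRecord("Region A", "LH", 4.0, 4.1, 3.0, -2.5, 25.0),
        RegionRecord("Region B", "RH", 10.0, 10.5, 9.0, -5.0, 10.0),
        RegionRecord("Region C", "midline", 1.5, 1.6, 1.2, -6.7, 20.0),
    ]


def gaussian_features(rng, means_by_cohort, n_per_cohort, sd=1.0):
    """FeatureMatrix with Gaussian features; means_by_cohort: cohort -> array(p)."""
    frames, labels = [], []
    for cohort, means in means_by_cohort.items():
        means = np.asarray(means, dtype=float)
        block = rng.normal(means, sd, size=(n_per_cohort, means.size))
        idx = [f"{cohort}_{i}" for i in range(n_per_cohort)]
        frames.append(pd.DataFrame(block, index=idx,
                                   columns=[f"f{j}" for j in range(means.size)]))
        labels += [cohort] * n_per_cohort
    values = pd.concat(frames)
    values.index.name = "subject_id"
    cohort = pd.Series(labels, index=values.index, name="cohort")
    return FeatureMatrix(values=values, cohort=cohort)


@pytest.fixture
def gaussian_factory():
    return gaussian_features
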