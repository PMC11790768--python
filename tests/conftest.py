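import numpy as np
import pytest
from hypothesis import settings

from ribfrac.experiment import mine_study_samples
from ribfrac.mining import PatchSample
from ribfrac.partition import GroupedDataset

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_grouped_dataset(
    n_groups: int,
    group_size: int = 5,
    labels: list[str] | None = None,
    patch_shape: tuple[int, int] = (1, 1),
) -> GroupedDataset:
    """Lightweight dataset for partition tests: real group structure, dummy
    pixel content."""
    labels = labels or ["nondisplaced"]
    samples = []
    for g in range(n_groups):
        label = labels[g % len(labels)]
        for i in range(group_size):
            samples.append(
                PatchSample(
                    patch=np.zeros(patch_shape, dtype=np.uint8),
                    label=label,
                    image_id=f"img{g // 10}",
                    group_id=f"g{g:04d}",
                    center=(50, 50),
                )
            )
    return GroupedDataset.from_samples(samples)


@pytest.fixture(scope="session")
def tiny_mined():
    """A small mined corpus (few hundred separable patches, two fracture
    classes so stratified splits always work) shared by training tests."""
    import dataclasses

    from ribfrac.experiment import STUDY_PARAMS

    params = dataclasses.replace(
        STUDY_PARAMS, class_mix={"nondisplaced": 0.5, "cum_distractione": 0.5}
    )
    positives, negatives = mine_study_samples(
        params=params, n_positive=4, n_negative=2, seed=7
    )
    return positives, negatives


@pytest.fixture(scope="session")
def tiny_dataset(tiny_mined):
    positives, negatives = tiny_mined
    return GroupedDataset.from_samples(positives + negatives)
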