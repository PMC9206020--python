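import numpy as np
import pandas as pd
import pytest

from lesionmap import Cohort, LesionMask, SyntheticSpec, VolumeGrid, generate_cohort
from lesionmap.synthetic import default_grid


@pytest.fixture(scope="session")
def small_grid() -> VolumeGrid:
    """10x12x10 grid at 2 mm, centered MNI-style."""
    return default_grid(voxel_mm=2.0, dims=(10, 12, 10))


def make_mask(grid: VolumeGrid, voxels, subject_id="s1") -> LesionMask:
    data = np.zeros(grid.dims, dtype=np.uint8)
    for v in voxels:
        data[tuple(v)] = 1
    return LesionMask(subject_id=subject_id, grid=grid, data=data)


def make_cohort(grid: VolumeGrid, lesion_sets, score_values, score="FMA_UL") -> Cohort:
    masks = [
        make_mask(grid, voxels, subject_id=f"s{i}")
        for i, voxels in enumerate(lesion_sets)
    ]
    scores = pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in masks],
            "score": score,
            "value": score_values,
        }
    )
    return Cohort(masks=masks, scores=scores)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (seed 1) shared across tests."""
    cohort, truth = generate_cohort(SyntheticSpec(seed=1))
    return cohort, truth
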