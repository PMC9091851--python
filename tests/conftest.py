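import numpy as np
import pytest

from rppkit import (
    RPPTrajectory,
    SpecimenMetadata,
    four_group_design,
    generate_rpp_dataset,
    trajectories_from_frame,
    two_group_design,
)


def make_traj(values, specimen="s1", element="humerus", **meta):
    return RPPTrajectory(
        metadata=SpecimenMetadata(specimen_id=specimen, element=element, **meta),
        values=tuple(values),
    )


def adjusted_rand(labels_a, labels_b):
    """Adjusted Rand index between two labelings (pair-counting form)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[(np.logical_and(a == x, b == y)).sum() for y in ub] for x in ua])

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


@pytest.fixture(scope="session")
def two_group_data():
    table, truth = generate_rpp_dataset(two_group_design(seed=101))
    data = trajectories_from_frame(table)
    return data, truth


@pytest.fixture(scope="session")
def four_group_data():
    table, truth = generate_rpp_dataset(four_group_design(seed=202))
    data = trajectories_from_frame(table)
    return data, truth
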