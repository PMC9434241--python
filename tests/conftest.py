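import numpy as np
import pytest
from hypothesis import settings

from mfblup.pedigree import Pedigree, sort_and_validate
from mfblup.simulate import simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def random_pedigree(
    n: int,
    n_founders: int,
    k_groups: int = 0,
    seed: int = 0,
    single_parent_prob: float = 0.1,
) -> Pedigree:
    """Random acyclic pedigree; missing slots get group labels when k_groups>0."""
    rng = np.random.default_rng(seed)
    labels = [f"g{t + 1}" for t in range(k_groups)] if k_groups else []

    def grp():
        return str(rng.choice(labels)) if labels else None

    ids = [f"P{i + 1}" for i in range(n)]
    sires: list = []
    dams: list = []
    sgrp: list = []
    dgrp: list = []
    for i in range(n):
        if i < n_founders:
            sires.append(None), dams.append(None)
            sgrp.append(grp()), dgrp.append(grp())
        elif rng.random() < single_parent_prob:
            sires.append(ids[int(rng.integers(0, i))]), dams.append(None)
            sgrp.append(None), dgrp.append(grp())
        else:
            s, d = rng.integers(0, i, size=2)
            sires.append(ids[int(s)]), dams.append(ids[int(d)])
            sgrp.append(None), dgrp.append(None)
    return sort_and_validate(Pedigree(ids, sires, dams, sgrp, dgrp))


@pytest.fixture(scope="session")
def trio():
    """Founders A, B and their offspring C."""
    return sort_and_validate(Pedigree(["C", "A", "B"], ["A", 0, 0], ["B", 0, 0]))


@pytest.fixture(scope="session")
def mini_dataset():
    """Small simulated dataset shared by the slower integration tests."""
    return simulate_dataset("mini", seed=11)
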