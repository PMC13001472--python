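import numpy as np
import pytest

from csmkit import (
    TargetSite,
    build_index,
    build_species_references,
    enumerate_micro_junctions,
)
from csmkit.simulate import random_sequence


@pytest.fixture(scope="session")
def amplicon() -> str:
    """400-nt amplicon-style reference with a default site placeable at its centre."""
    return random_sequence(400, np.random.default_rng(7))


@pytest.fixture(scope="session")
def site(amplicon):
    return TargetSite.from_reference("amp", amplicon, 184, 216)


@pytest.fixture(scope="session")
def micro_lib(site, amplicon):
    return enumerate_micro_junctions(site, {"amp": amplicon}, flank_k=12)


@pytest.fixture(scope="session")
def index(micro_lib, amplicon):
    return build_index(micro_lib, amplicon, anchor_k=12)


@pytest.fixture(scope="session")
def species_refs(micro_lib, amplicon):
    return build_species_references(micro_lib, amplicon, intact_name="intact")


@pytest.fixture(scope="session")
def pool_fractions(micro_lib):
    """Composition emulating the measured pool: 88% intact, 12% religated
    split 7/3/1.5/0.5% across the 6/12/18/24-nt deletion classes, each class
    budget divided equally among its junctions."""
    budgets = {6: 0.07, 12: 0.03, 18: 0.015, 24: 0.005}
    fractions = {}
    for d, budget in budgets.items():
        members = [j for j in micro_lib if j.deletion_length == d]
        for j in members:
            fractions[j.id] = budget / len(members)
    fractions["intact"] = 1.0 - sum(fractions.values())
    return fractions
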