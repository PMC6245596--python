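"""Shared fixture networks.

All fixtures are generated in memory by :mod:`efmsampler.synth`; the only
file-based model used anywhere in the suite is the core E. coli model that
ships inside the installed cobrapy distribution.
"""

from pathlib import Path

import numpy as np
import pytest

from efmsampler import MetabolicNetwork, make_chain, make_parallel, make_random, split_reversible


@pytest.fixture(scope="session")
def chain():
    """3-reaction irreversible chain: unique EFM = all reactions."""
    return make_chain(2)


@pytest.fixture(scope="session")
def chain_rev():
    """Chain with a reversible middle conversion (4 split columns)."""
    return make_chain(2, reversible_middle=True)


@pytest.fixture(scope="session")
def diamond():
    """2-branch parallel network: two EFMs."""
    return make_parallel(2)


@pytest.fixture(scope="session")
def parallel5():
    """5-branch parallel network: five EFMs, the diversity testbed."""
    return make_parallel(5)


@pytest.fixture(scope="session")
def random20():
    """20-reaction random sparse fixture with a nontrivial pathway.

    Genome-scale reconstructions are majority-reversible, and reversibility is
    what gives the network alternative routes, so the fixture carries a
    realistic reversible fraction.
    """
    return make_random(m=8, n=20, density=0.25, reversible_fraction=0.4, rng_seed=42)


@pytest.fixture(scope="session")
def dead_end():
    """R1 produces A, R2 turns A into a metabolite nothing consumes, R3 drains A.

    Seeding R2 is infeasible: B would accumulate, violating the steady state.
    """
    return MetabolicNetwork(
        metabolite_ids=("A", "B"),
        reaction_ids=("R1", "R2", "R3"),
        S=np.array([[1.0, -1.0, -1.0], [0.0, 1.0, 0.0]]),
        reversible=np.zeros(3, dtype=bool),
    )


@pytest.fixture(scope="session")
def core_model_path():
    """The BiGG core E. coli model (SBML) bundled with the installed cobrapy."""
    import cobra

    path = Path(cobra.__file__).parent / "data" / "textbook.xml.gz"
    assert path.exists()
    return path


@pytest.fixture(scope="session")
def splits(chain, chain_rev, diamond, parallel5, random20):
    """Split views of every fixture, keyed by name."""
    return {
        "chain": split_reversible(chain),
        "chain_rev": split_reversible(chain_rev),
        "diamond": split_reversible(diamond),
        "parallel5": split_reversible(parallel5),
        "random20": split_reversible(random20),
    }
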