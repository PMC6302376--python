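import numpy as np
import pytest

from grndesign import (
    BooleanNetwork,
    ControlProblem,
    UncertaintyClass,
    bnp_tpm,
    cpms_from_tpm,
    random_bnp,
    undesirable_states,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def identity_1gene():
    """One self-regulating gene that copies its own value."""
    return BooleanNetwork.from_truth_tables([[0]], [[0, 1]], p=0.01)


@pytest.fixture
def bnp6():
    """A random 6-gene BNp under the synthetic protocol defaults."""
    return random_bnp(rng=12345)


@pytest.fixture
def synthetic_problem():
    """The synthetic benchmark control problem: control X6, U = {X1=0, X2=0}."""
    return ControlProblem(
        n_genes=6,
        control_gene=5,
        undesirable=undesirable_states(6, {0: 0, 1: 0}),
        zeta=0.2,
    )


@pytest.fixture
def bnp6_cpms(bnp6):
    return cpms_from_tpm(bnp_tpm(bnp6), bnp6.regulators)


def random_tpm(S, rng):
    """A dense random row-stochastic matrix (Dirichlet rows)."""
    return rng.dirichlet(np.ones(S), size=S)


def random_problem(n, rng, zeta=0.2):
    """A random control problem with a random cost table and undesirable set."""
    S = 2 ** n
    n_u = int(rng.integers(1, S))
    U = rng.choice(S, size=n_u, replace=False)
    cost = rng.uniform(0, 5, size=(S, S, 2))
    return ControlProblem(
        n_genes=n,
        control_gene=int(rng.integers(n)),
        undesirable=U,
        zeta=zeta,
        cost=cost,
    )
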