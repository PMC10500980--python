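import numpy as np
import pytest

from cpprop.problems import (OperatorGradient, ResponseProblem,
                             generate_synthetic_problem)


@pytest.fixture(scope="session")
def small_problem():
    """28-parameter stable RPA problem (half dim), dense dipole gradients."""
    return generate_synthetic_problem(20, 8, seed=7)


@pytest.fixture(scope="session")
def medium_problem():
    """Half dim 100, used by solver-behaviour tests."""
    return generate_synthetic_problem(80, 20, seed=3)


@pytest.fixture(scope="session")
def diagonal_problem():
    """Fully decoupled problem (A diagonal, B = Delta = 0, Sigma = I)."""
    return generate_synthetic_problem(30, 10, seed=5, coupling_scale=0.0)


@pytest.fixture(scope="session")
def decoupled_rpa_problem():
    """Problem with B and Delta zeroed: TDA and RPA coincide exactly."""
    p = generate_synthetic_problem(30, 10, seed=13)
    return ResponseProblem(
        n_orb=p.n_orb, n_ci=p.n_ci,
        A_block=p.A_block, B_block=np.zeros_like(p.B_block),
        Sigma_block=p.Sigma_block, Delta_block=np.zeros_like(p.Delta_block),
        gradients=p.gradients, orbital_pair_map=p.orbital_pair_map,
        ci_transition_map=p.ci_transition_map, metadata=dict(p.metadata),
    )


def one_parameter_problem(a=0.35, b=0.0, grad=1.3):
    """Smallest paired problem: scalar blocks, a single orbital parameter."""
    return ResponseProblem(
        n_orb=1, n_ci=0,
        A_block=np.array([[a]]), B_block=np.array([[b]]),
        Sigma_block=np.array([[1.0]]), Delta_block=np.array([[0.0]]),
        gradients=[OperatorGradient("electric-dipole-length", c,
                                    np.array([grad if c == "x" else 0.0]),
                                    np.zeros(1)) for c in "xyz"],
        orbital_pair_map=np.array([[0, 0, 1]]),
        ci_transition_map=np.zeros((1, 0)),
    )


@pytest.fixture
def scalar_problem():
    return one_parameter_problem()
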