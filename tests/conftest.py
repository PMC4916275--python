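"""Shared fixtures.

The expensive end-to-end trainings (Example 1 across five seeds,
Example 2 once) are session-scoped so that every test asserting on
them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import wtalearn as wl

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


EX1_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def example1_target():
    return wl.target_example1()


@pytest.fixture(scope="session")
def example1_runs(example1_target):
    """Five independently seeded 1200 s trainings of the Example-1 module."""
    runs = []
    for seed in EX1_SEEDS:
        res = wl.example1_module().fit(
            target=example1_target, duration=1200.0, seed=seed
        )
        runs.append(res)
    return runs


@pytest.fixture(scope="session")
def example2_run():
    """One 1200 s training of the four-module Example-2 network."""
    return wl.example2_network().fit(duration=1200.0, seed=1)


@pytest.fixture(scope="session")
def tiny_theta():
    """A small arbitrary theta (I=2 binary inputs, L=2, J=2) for oracles."""
    rng = np.random.default_rng(7)
    C = 4
    w_hat = [
        np.vstack(
            [
                np.full((1, C), -50.0),
                np.log(rng.dirichlet([1.0, 1.0], size=C).T * 0.9),
            ]
        )
        for _ in range(2)
    ]
    b_hat = np.log(rng.dirichlet(np.ones(C)) * 1.2)
    return wl.Theta(
        M=(2, 2),
        J=(2, 2),
        w_hat=w_hat,
        b_hat=b_hat,
        w_minus=wl.experiments.W_MINUS,
        b_minus=-15.0,
    )
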