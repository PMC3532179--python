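"""Shared fixtures: the bundled model, a calibrated reporting horizon, and
an independent term-by-term oracle for compiled right-hand sides."""

from __future__ import annotations

import numpy as np
import pytest

import cisapop as ca


def rhs_oracle(network: ca.ReactionNetwork, y: np.ndarray) -> np.ndarray:
    """Hand-assembled mass-action derivative, independent of build_rhs.

    Evaluates every reaction's rate by direct name lookup and accumulates
    net stoichiometry species by species.
    """
    values = {}
    for s in network.constant_species:
        values[s.name] = s.initial_value
    dyn = [s.name for s in network.dynamic_species]
    for name, i in zip(dyn, range(len(dyn))):
        values[name] = y[i]
    deriv = dict.fromkeys(dyn, 0.0)
    for r in network.reactions:
        rate = network.parameters[r.rate_constant_id]
        for name, nu in r.consumed.items():
            rate *= values[name] ** nu
        for name in r.catalysts:
            rate *= values[name]
        for name, nu in r.consumed.items():
            if name in deriv:
                deriv[name] -= nu * rate
        for name, nu in r.produced.items():
            if name in deriv:
                deriv[name] += nu * rate
    return np.array([deriv[name] for name in dyn])


@pytest.fixture(scope="session")
def bundled() -> ca.ReactionNetwork:
    return ca.build_cisplatin_network()


@pytest.fixture(scope="session")
def tstar() -> float:
    """Horizon at which the full-dose apoptosis level reaches its reference
    value (the model's single free time-scale convention)."""
    return ca.calibrate_horizon()


@pytest.fixture(scope="session")
def cal_settings(tstar) -> ca.SimulationSettings:
    return ca.SimulationSettings(t_end=tstar)


@pytest.fixture(scope="session")
def baseline_cal(bundled, cal_settings) -> ca.Trajectory:
    return ca.simulate(bundled, cal_settings)


@pytest.fixture(scope="session")
def baseline_24(bundled) -> ca.Trajectory:
    return ca.simulate(bundled, ca.SimulationSettings())
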