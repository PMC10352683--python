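"""Scenario-construction helpers shared across test modules."""

import numpy as np

from fieldca import SimulationConfig
from fieldca.automaton import init_grid

QUIESCENT = np.array([0.0, 1.0, 0.0, 0.0])
PROLIFERATIVE = np.array([1.0, 0.0, 0.0, 0.0])

#: an expression profile with every gene positively mutated
ALL_POSITIVE = np.array([-0.2] * 5 + [0.2] * 5)


def blank_state(N, panel, seed=0, **config_kwargs):
    """An all-empty lattice for forced-scenario tests."""
    kwargs = dict(
        grid_size=N,
        steps=10,
        rng_seed=seed,
        carcinogens=[],
        seed_fractions=(0.0, 0.0, 1.0),
        cold_start_ages=True,
    )
    kwargs.update(config_kwargs)
    config = SimulationConfig(**kwargs)
    return init_grid(N, config, panel, np.random.default_rng(seed))


def place(state, x, y, cls, P=QUIESCENT, E=None, lineage=0, age=0, tac=0, tacgen=0):
    """Drop a cell with explicit state onto the lattice; returns its
    flat site index."""
    k = y * state.N + x
    state.cls[k] = cls
    state.P[k] = P
    state.E[k] = np.zeros(state.panel.G) if E is None else E
    state.lin[k] = lineage
    state.age[k] = age
    state.tac[k] = tac
    state.tacgen[k] = tacgen
    return k
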