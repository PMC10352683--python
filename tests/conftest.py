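"""Shared fixtures.

The expensive lattice experiments (homeostasis, carcinogen potency,
excision recurrence, clonality vs grid size) are session-scoped so the
acceptance tests and the property tests can share a single set of runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from fieldca import CarcinogenSpec, SimulationConfig, build_hnscc_panel, run_simulation
from fieldca.automaton import excise, step
from fieldca.cell_rules import MNSC, MNTC, TC
from fieldca.lineage import classify_clonality, lineage_table


@pytest.fixture(scope="session")
def panel():
    return build_hnscc_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _first_mutated(state):
    firsts = [state.first_seen[c] for c in (1, 3, 4, 5) if c in state.first_seen]
    return min(firsts) if firsts else None


# ---------------------------------------------------------------------------
# Homeostasis: 128x128, zero carcinogens, 1,000 steps
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def homeostasis_run():
    config = SimulationConfig(
        grid_size=128, steps=1000, rng_seed=101, carcinogens=[], record_every=50
    )
    result = run_simulation(config)
    return result


# ---------------------------------------------------------------------------
# Carcinogen potency: paired smoking-only vs alcohol-only runs
# ---------------------------------------------------------------------------

POTENCY_SEEDS = (201, 202, 203, 204, 205)
POTENCY_CAP = 2400


@pytest.fixture(scope="session")
def potency_runs():
    """For each seed: a smoking-only run stopped at the first mutated
    cell (or the cap) and an alcohol-only run over the same horizon.
    Returns a list of dicts with the final mutated fractions."""
    out = []
    for seed in POTENCY_SEEDS:
        smoking_cfg = SimulationConfig(
            grid_size=128,
            steps=POTENCY_CAP,
            rng_seed=seed,
            carcinogens=[CarcinogenSpec(name="smoking")],
            record_every=10**9,
        )
        smoking = run_simulation(
            smoking_cfg,
            stop_when=lambda s: _first_mutated(s) is not None,
            record=False,
        )
        horizon = smoking.state.t
        alcohol_cfg = SimulationConfig(
            grid_size=128,
            steps=horizon,
            rng_seed=seed,
            carcinogens=[CarcinogenSpec(name="alcohol")],
            record_every=10**9,
        )
        alcohol = run_simulation(alcohol_cfg, record=False)

        def mutated_fraction(state):
            counts = state.class_counts()
            return counts[[1, 3, 4, 5]].sum() / counts.sum()

        out.append(
            {
                "seed": seed,
                "horizon": horizon,
                "smoking_mutated": mutated_fraction(smoking.state),
                "alcohol_mutated": mutated_fraction(alcohol.state),
                "smoking_onset": _first_mutated(smoking.state),
                "alcohol_onset": _first_mutated(alcohol.state),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Excision recurrence: paired tumor-only vs field removal
# ---------------------------------------------------------------------------

EXCISION_SEEDS = (301, 302, 303, 304, 305)
EXCISION_BASE_CAP = 10500
EXCISION_CONT_CAP = 2200


@pytest.fixture(scope="session")
def excision_pairs():
    """Paired recurrence times.  Each replicate runs a smoking-only
    128x128 lattice until 18 months after the first tumor cell, then
    branches: the same pre-excision state is excised in ``tumor`` mode
    and in ``field`` mode and each branch continues until a tumor cell
    reappears (censored at the cap, recorded as cap+1)."""
    pairs = []
    for seed in EXCISION_SEEDS:
        config = SimulationConfig(
            grid_size=128,
            steps=EXCISION_BASE_CAP,
            rng_seed=seed,
            carcinogens=[CarcinogenSpec(name="smoking")],
            record_every=10**9,
        )
        delay = config.months_to_steps(config.excision.delay_months)

        def stop(state):
            first_tc = state.first_seen.get(TC)
            return first_tc is not None and state.t >= first_tc + delay

        base = run_simulation(config, stop_when=stop, record=False).state
        if TC not in base.first_seen:
            pairs.append({"seed": seed, "tumor": None, "field": None})
            continue
        times = {}
        for i, mode in enumerate(("tumor", "field")):
            branch = base.copy()
            branch.rng = np.random.default_rng(100_000 + 10 * seed + i)
            excise(branch, mode, rings=config.excision.rings)
            branch.excision_steps.append(branch.t)
            recurrence = EXCISION_CONT_CAP + 1
            for _ in range(EXCISION_CONT_CAP):
                step(branch)
                if "recurrence_tc" in branch.first_seen:
                    recurrence = (
                        branch.first_seen["recurrence_tc"] - branch.excision_steps[-1]
                    )
                    break
            times[mode] = recurrence
        pairs.append({"seed": seed, **times})
    return pairs


# ---------------------------------------------------------------------------
# Clonality vs grid size
# ---------------------------------------------------------------------------

SMALL_GRID_SEEDS = (401, 402, 403)


def _clonality_run(grid_size, seed, extra_steps, cap):
    config = SimulationConfig(
        grid_size=grid_size,
        steps=cap,
        rng_seed=seed,
        carcinogens=[CarcinogenSpec(name="smoking")],
        record_every=10**9,
    )

    def stop(state):
        first_tc = state.first_seen.get(TC)
        return first_tc is not None and state.t >= first_tc + extra_steps

    result = run_simulation(config, stop_when=stop, record=False)
    return classify_clonality(lineage_table(result.state))


@pytest.fixture(scope="session")
def small_grid_clonalities():
    return [_clonality_run(64, seed, 200, 15000) for seed in SMALL_GRID_SEEDS]


@pytest.fixture(scope="session")
def large_grid_clonality():
    return _clonality_run(256, 411, 800, 4500)
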