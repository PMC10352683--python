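"""Lattice engine: seeding, neighborhoods, stepping, competition,
class-transition machinery, excision, and trajectory-level properties."""

import numpy as np
import pytest

from fieldca import CarcinogenSpec, SimulationConfig, run_simulation
from fieldca.automaton import (
    choose_action,
    excise,
    init_grid,
    moore_neighborhood,
    step,
)
from fieldca.cell_rules import CSC, EMPTY, MNSC, MNTC, NSC, NTC, TC
from fieldca.gene_panel import build_hnscc_panel

from _helpers import ALL_POSITIVE, PROLIFERATIVE, QUIESCENT, blank_state, place


class TestInitGrid:
    def test_seed_counts_within_one_site(self, panel):
        config = SimulationConfig(grid_size=128, carcinogens=[])
        state = init_grid(128, config, panel, np.random.default_rng(5))
        counts = state.class_counts()
        assert counts.sum() == 128 * 128
        assert counts[NTC] in (10567, 10568)  # 64.5% of 16384
        assert counts[NSC] in (1064, 1065)
        assert counts[EMPTY] in (4751, 4752)

    def test_seed_contains_only_healthy_classes(self, panel):
        config = SimulationConfig(grid_size=64, carcinogens=[])
        state = init_grid(64, config, panel, np.random.default_rng(1))
        counts = state.class_counts()
        assert counts[[MNTC, MNSC, CSC, TC]].sum() == 0

    def test_identical_seed_identical_grid(self, panel):
        config = SimulationConfig(grid_size=32, carcinogens=[])
        a = init_grid(32, config, panel, np.random.default_rng(9))
        b = init_grid(32, config, panel, np.random.default_rng(9))
        assert np.array_equal(a.cls, b.cls)
        assert np.array_equal(a.age, b.age)
        assert np.array_equal(a.lin, b.lin)

    def test_each_occupied_site_founds_unique_lineage(self, panel):
        config = SimulationConfig(grid_size=32, carcinogens=[])
        state = init_grid(32, config, panel, np.random.default_rng(2))
        occupied = state.lin[state.cls != EMPTY]
        assert len(np.unique(occupied)) == len(occupied)
        assert np.all(state.lin[state.cls == EMPTY] == -1)


class TestMooreNeighborhood:
    def test_wraparound_at_origin(self):
        nb = moore_neighborhood(0, 0, 4)
        assert (3, 3) in nb
        assert len(nb) == 9

    def test_contains_focal_cell(self):
        assert (2, 2) in moore_neighborhood(2, 2, 8)

    def test_every_site_in_exactly_nine_neighborhoods(self):
        N = 5
        hits = np.zeros((N, N), dtype=int)
        for y in range(N):
            for x in range(N):
                for nx, ny in moore_neighborhood(x, y, N):
                    hits[ny, nx] += 1
        assert np.all(hits == 9)


class TestChooseAction:
    def test_degenerate_distributions(self, rng):
        assert choose_action(np.array([1.0, 0, 0, 0]), rng) == 0
        assert choose_action(np.array([0, 0, 1.0, 0]), rng) == 2

    def test_frequencies_match_probabilities(self, rng):
        P = np.array([0.2, 0.5, 0.2, 0.1])
        n = 40_000
        draws = np.array([choose_action(P, rng) for _ in range(n)])
        freqs = np.bincount(draws, minlength=4) / n
        se = np.sqrt(P * (1 - P) / n)
        assert np.all(np.abs(freqs - P) < 4 * se)


class TestStepMechanics:
    def test_site_conservation_every_step(self, panel):
        config = SimulationConfig(
            grid_size=16, steps=50, rng_seed=3,
            carcinogens=[CarcinogenSpec(name="smoking")],
        )
        state = init_grid(16, config, panel, np.random.default_rng(3))
        for _ in range(50):
            step(state)
            assert state.class_counts().sum() == 256

    def test_identical_seed_identical_trajectory(self):
        runs = []
        for _ in range(2):
            config = SimulationConfig(
                grid_size=32, steps=25, rng_seed=17,
                carcinogens=[CarcinogenSpec(name="smoking")],
            )
            runs.append(run_simulation(config, record=False).state)
        a, b = runs
        assert np.array_equal(a.cls, b.cls)
        assert np.array_equal(a.E, b.E)
        assert np.array_equal(a.P, b.P)
        assert np.array_equal(a.lin, b.lin)


class TestProliferationCompetition:
    def test_all_empty_neighborhood_always_succeeds(self, panel):
        state = blank_state(8, panel, dediff_prob=0.0)
        place(state, 4, 4, NTC, P=PROLIFERATIVE)
        step(state)
        assert (state.cls != EMPTY).sum() == 2
        # daughter copies class and lineage, both ages reset (then +1)
        occupied = np.nonzero(state.cls != EMPTY)[0]
        assert np.all(state.cls[occupied] == NTC)
        assert np.all(state.lin[occupied] == 0)
        assert np.all(state.age[occupied] == 1)

    def test_uniformly_fitter_neighborhood_blocks_normal_parent(self, panel):
        # the parent (fitness 1 - age cost < 1) targets occupants with the
        # cancer bonus (fitness 1): placement must never occur
        state = blank_state(3, panel, dediff_prob=0.0, move_prob=0.0)
        place(state, 1, 1, NTC, P=PROLIFERATIVE, age=10, lineage=0)
        for i, (x, y) in enumerate(
            [(x, y) for y in range(3) for x in range(3) if (x, y) != (1, 1)]
        ):
            place(state, x, y, TC, P=QUIESCENT, E=ALL_POSITIVE, lineage=1 + i)
        config_counts = state.class_counts()
        for _ in range(5):
            step(state)
        assert np.array_equal(state.class_counts(), config_counts)
        assert (state.lin == 0).sum() == 1

    def test_cancer_cells_break_equal_fitness_deadlock_via_kappa(self, panel):
        # a full grid of equally fit cancer cells can only change through
        # the kill roll (probability kappa per blocked attempt); with
        # kappa > 0 some lineage must eventually copy itself
        state = blank_state(3, panel, dediff_prob=0.0, move_prob=0.0)
        for i, (x, y) in enumerate((x, y) for y in range(3) for x in range(3)):
            place(state, x, y, TC, P=PROLIFERATIVE, E=ALL_POSITIVE, lineage=i)
        for _ in range(30):
            step(state)
        sizes = np.bincount(state.lin[state.lin >= 0])
        assert sizes.max() >= 2

    def test_kappa_zero_freezes_equal_fitness_grid(self, panel):
        # phenotype modification is disabled so fitness ties can never
        # break by probability drift
        state = blank_state(
            3, panel, dediff_prob=0.0, move_prob=0.0, kill_prob=0.0,
            phenotype_mod_prob=0.0,
        )
        for i, (x, y) in enumerate((x, y) for y in range(3) for x in range(3)):
            place(state, x, y, TC, P=PROLIFERATIVE, E=ALL_POSITIVE, lineage=i)
        before = state.lin.copy()
        for _ in range(10):
            step(state)
        assert np.array_equal(state.lin, before)


class TestQuiescentMovement:
    def test_moves_into_empty_space(self, panel):
        state = blank_state(8, panel, move_prob=1.0)
        k = place(state, 4, 4, NTC, P=QUIESCENT)
        step(state)
        assert (state.cls != EMPTY).sum() == 1
        new_k = int(np.nonzero(state.cls != EMPTY)[0][0])
        assert new_k != k  # forced move probability

    def test_normal_cell_never_displaces_occupants(self, panel):
        state = blank_state(3, panel, move_prob=1.0, dediff_prob=0.0)
        for y in range(3):
            for x in range(3):
                place(state, x, y, NTC, P=QUIESCENT, lineage=y * 3 + x)
        before = state.lin.copy()
        for _ in range(10):
            step(state)
        # a full grid of normal cells cannot rearrange by movement
        assert np.array_equal(state.lin, before)

    def test_tumor_cell_displacement_rate(self, panel):
        # TC surrounded by normal occupants displaces at ~move*kill = 0.05
        n_trials, displaced = 600, 0
        for trial in range(n_trials):
            state = blank_state(3, panel, seed=trial, dediff_prob=0.0)
            center = place(state, 1, 1, TC, P=QUIESCENT, E=ALL_POSITIVE, lineage=0)
            for i, (x, y) in enumerate(
                [(x, y) for y in range(3) for x in range(3) if (x, y) != (1, 1)]
            ):
                place(state, x, y, NTC, P=QUIESCENT, lineage=1 + i)
            step(state)
            if state.cls[center] != TC:
                displaced += 1
        p = 0.25 * 0.2
        se = np.sqrt(p * (1 - p) * n_trials)
        assert abs(displaced - p * n_trials) < 4 * se


class TestClassTransitions:
    def test_forced_csc_conversion_preserves_lineage(self, panel):
        state = blank_state(8, panel, csc_prob=1.0, move_prob=0.0)
        place(state, 4, 4, MNSC, P=QUIESCENT, E=ALL_POSITIVE, lineage=42)
        step(state)
        assert (state.cls == CSC).sum() == 1
        assert state.lin[state.cls == CSC][0] == 42

    def test_unmutated_stem_cells_do_not_convert_by_default(self, panel):
        state = blank_state(8, panel, csc_prob=1.0, move_prob=0.0)
        place(state, 4, 4, NSC, P=QUIESCENT)
        step(state)
        assert (state.cls == CSC).sum() == 0
        assert (state.cls == NSC).sum() == 1

    def test_as_printed_flag_converts_unmutated_stem_cells(self, panel):
        state = blank_state(
            8, panel, csc_prob=1.0, move_prob=0.0, restrict_csc_to_mutated=False
        )
        place(state, 4, 4, NSC, P=QUIESCENT)
        step(state)
        assert (state.cls == CSC).sum() == 1

    def test_mutation_status_flips_class_both_ways(self, panel):
        state = blank_state(8, panel, move_prob=0.0, dediff_prob=0.0)
        k = place(state, 4, 4, NTC, P=QUIESCENT, E=ALL_POSITIVE)
        step(state)
        assert state.cls[k] == MNTC
        state.E[k] = 0.0  # expressions repaired to normal
        step(state)
        assert state.cls[k] == NTC


class TestDedifferentiation:
    def test_isolated_cell_reverts_to_stem(self, panel):
        # no stem neighbors and 8 empty neighbors: both triggers hold
        state = blank_state(8, panel, dediff_prob=1.0, move_prob=0.0)
        k = place(state, 4, 4, NTC, P=QUIESCENT)
        step(state)
        assert state.cls[k] == NSC

    def test_stem_neighbor_and_few_empties_block_trigger(self, panel):
        state = blank_state(8, panel, dediff_prob=1.0, move_prob=0.0)
        k = place(state, 1, 1, NTC, P=QUIESCENT)
        place(state, 0, 1, NSC, P=QUIESCENT, lineage=1)
        place(state, 1, 0, NTC, P=QUIESCENT, lineage=2)
        place(state, 2, 1, NTC, P=QUIESCENT, lineage=3)
        place(state, 1, 2, NTC, P=QUIESCENT, lineage=4)
        step(state)
        assert state.cls[k] == NTC

    def test_tumor_cell_dedifferentiates_to_cancer_stem(self, panel):
        state = blank_state(8, panel, dediff_prob=1.0, move_prob=0.0)
        k = place(state, 4, 4, TC, P=QUIESCENT, E=ALL_POSITIVE)
        step(state)
        assert state.cls[k] == CSC


class TestExcision:
    def _developed_state(self, panel):
        state = blank_state(12, panel)
        place(state, 5, 5, TC, E=ALL_POSITIVE, lineage=0)
        place(state, 0, 0, CSC, E=ALL_POSITIVE, lineage=1)
        place(state, 5, 6, NTC, lineage=2)  # inside the 2-ring of the TC
        place(state, 5, 9, MNTC, E=ALL_POSITIVE, lineage=3)  # outside the ring
        place(state, 10, 10, NSC, lineage=4)
        place(state, 9, 9, MNSC, E=ALL_POSITIVE, lineage=5)
        return state

    def test_tumor_mode_keeps_the_field(self, panel):
        state = self._developed_state(panel)
        excise(state, "tumor", rings=2)
        counts = state.class_counts()
        assert counts[TC] == 0 and counts[CSC] == 0
        assert counts[NTC] == 0  # swept away by the ring around the TC
        assert counts[MNTC] == 1 and counts[MNSC] == 1 and counts[NSC] == 1

    def test_field_mode_leaves_only_healthy_classes(self, panel):
        state = self._developed_state(panel)
        excise(state, "field", rings=2)
        remaining = set(np.unique(state.cls))
        assert remaining <= {NTC, NSC, EMPTY}
        assert state.class_counts()[NSC] == 1

    def test_excising_healthy_grid_is_identity(self, panel):
        state = blank_state(8, panel)
        place(state, 2, 2, NTC)
        place(state, 6, 6, NSC, lineage=1)
        before = state.cls.copy()
        excise(state, "tumor", rings=2)
        assert np.array_equal(state.cls, before)

    def test_unknown_mode_rejected(self, panel):
        with pytest.raises(ValueError):
            excise(blank_state(8, panel), "partial")


class TestTrajectoryProperties:
    def test_stem_fraction_stays_near_seeded_ratio(self, homeostasis_run):
        # dedifferentiation maintains the stem share of occupied tissue
        # within +-50% (relative) of the seeded 6.5/71 ratio
        df = homeostasis_run.timeseries
        final = df.iloc[-1]
        occupied = 1.0 - final["frac_empty"]
        stem_share = final["frac_NSC"] / occupied
        seeded = 0.065 / 0.71
        assert 0.5 * seeded < stem_share < 1.5 * seeded

    def test_onset_time_nonincreasing_in_carcinogen_dose(self, potency_runs):
        # a dose far below the activation peak mutates much later than
        # the full-strength field (median over replicates)
        high_onsets = [r["smoking_onset"] for r in potency_runs]
        assert all(o is not None for o in high_onsets)
        cap = 2400
        config = SimulationConfig(
            grid_size=128, steps=cap, rng_seed=501,
            carcinogens=[CarcinogenSpec(name="smoking")],
            carcinogen_multiplier=3e-4, record_every=10**9,
        )
        low = run_simulation(
            config,
            stop_when=lambda s: any(c in s.first_seen for c in (1, 3, 4, 5)),
            record=False,
        ).state
        low_onset = min(
            (low.first_seen[c] for c in (1, 3, 4, 5) if c in low.first_seen),
            default=cap,
        )
        assert np.median(high_onsets) <= low_onset
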