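"""The lattice engine.

A toroidal ``N x N`` grid of cells evolves in discrete time-steps, each
representing one cell cycle.  Every step applies, in order: (1) the
gene-expression network, (2) the expression update, (3) genetic
instability, (4) the phenotype-probability update, (5) class transitions
(mutation status, cancer-stem conversion), (6) dedifferentiation, (7) one
sampled phenotypic action per cell with competition, killing and
quiescent movement, and (8) a scheduled excision, if any.

Stages 1–6 are local to each cell (dedifferentiation reads a
start-of-step neighborhood snapshot); stage 7 processes cells in a fresh
random permutation with first-actor-claims conflict resolution.  State
lives in flat structure-of-arrays form and the hot stages run in
compiled kernels; see :mod:`fieldca._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import maximum_filter

from . import _kernels
from .carcinogen_field import (
    CarcinogenField,
    always_on,
    exposure_grids,
    field_from_file,
    gaussian_field,
    uniform_field,
    window_schedule,
)
from .cell_rules import (
    CANCER_CLASSES,
    CSC,
    EMPTY,
    MNSC,
    MNTC,
    MUTATED_CLASSES,
    NSC,
    NTC,
    TC,
    InitialPhenotypeTable,
)
from .config import SimulationConfig
from .gene_panel import GenePanel, build_hnscc_panel, load_panel

__all__ = [
    "LatticeState",
    "init_grid",
    "moore_neighborhood",
    "choose_action",
    "build_fields",
    "step",
    "excise",
    "run_simulation",
    "RunResult",
]


def choose_action(P: np.ndarray, rng: np.random.Generator) -> int:
    """Sample one phenotypic action index (0 proliferate, 1 quiesce,
    2 apoptose, 3 differentiate) from a cell's phenotype vector."""
    r = rng.random() * float(np.sum(P))
    c = 0.0
    for i in range(3):
        c += P[i]
        if r < c:
            return i
    return 3

_SEED_CLASSES = (NTC, NSC, EMPTY)


@dataclass
class LatticeState:
    """Full simulation state in structure-of-arrays form.

    Cell ``k`` sits at lattice coordinates ``(x, y) = (k % N, k // N)``.
    """

    N: int
    config: SimulationConfig
    panel: GenePanel
    table: InitialPhenotypeTable
    fields: list[CarcinogenField]
    rng: np.random.Generator
    t: int
    cls: np.ndarray  # (n,) int8
    age: np.ndarray  # (n,) int64
    E: np.ndarray  # (n, G) float64
    P: np.ndarray  # (n, 4) float64
    tac: np.ndarray  # (n,) uint8
    tacgen: np.ndarray  # (n,) int8
    lin: np.ndarray  # (n,) int64
    first_seen: dict = field(default_factory=dict)
    excision_steps: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.N * self.N

    def class_counts(self) -> np.ndarray:
        """Counts of the seven site classes; always sums to ``N**2``."""
        return np.bincount(self.cls, minlength=7)

    def grid(self) -> np.ndarray:
        """Class codes as an ``(N, N)`` grid (row = y)."""
        return self.cls.reshape(self.N, self.N)

    def copy(self) -> "LatticeState":
        return LatticeState(
            N=self.N,
            config=self.config,
            panel=self.panel,
            table=self.table,
            fields=self.fields,
            rng=np.random.default_rng(),
            t=self.t,
            cls=self.cls.copy(),
            age=self.age.copy(),
            E=self.E.copy(),
            P=self.P.copy(),
            tac=self.tac.copy(),
            tacgen=self.tacgen.copy(),
            lin=self.lin.copy(),
            first_seen=dict(self.first_seen),
            excision_steps=list(self.excision_steps),
        )


def moore_neighborhood(x: int, y: int, N: int) -> list[tuple[int, int]]:
    """The 3x3 Moore neighborhood of ``(x, y)`` with toroidal wraparound,
    focal site included (9 coordinates)."""
    return [((x + dx) % N, (y + dy) % N) for dy in (-1, 0, 1) for dx in (-1, 0, 1)]


def _table_from_config(config: SimulationConfig) -> InitialPhenotypeTable:
    return InitialPhenotypeTable(
        c_tilde=config.cell_cycle_hours,
        c1=config.lifespan_tissue_hours,
        c2=config.lifespan_stem_hours,
        p1=config.prolif_factor_tissue,
        p2=config.prolif_factor_stem,
        alpha_bar=config.apoptosis_factor,
        d_bar=config.diff_factor,
        theta=config.theta,
    )


def build_fields(config: SimulationConfig, panel: GenePanel) -> list[CarcinogenField]:
    """Construct carcinogen fields from the config, one per configured
    carcinogen.  Field order follows the panel's carcinogen columns;
    carcinogens the config omits contribute zero exposure."""
    N = config.grid_size
    by_name = {spec.name: spec for spec in config.carcinogens}
    fields: list[CarcinogenField] = []
    for name in panel.carcinogen_names:
        spec = by_name.get(name)
        if spec is None:
            grid = np.zeros((N, N))
            fields.append(CarcinogenField(name=name, concentration=grid))
            continue
        if spec.shape == "gaussian":
            grid = spec.level * gaussian_field(N)
        elif spec.shape == "uniform":
            grid = uniform_field(N, spec.level)
        elif spec.shape == "file":
            grid = field_from_file(spec.path)
        else:
            raise ValueError(f"unknown field shape {spec.shape!r}")
        schedule = always_on if spec.windows is None else window_schedule(spec.windows)
        fields.append(CarcinogenField(name=name, concentration=grid, schedule=schedule))
    unknown = set(by_name) - set(panel.carcinogen_names)
    if unknown:
        raise ValueError(f"carcinogens not in panel: {sorted(unknown)}")
    return fields


def init_grid(
    N: int,
    config: SimulationConfig,
    panel: GenePanel,
    rng: np.random.Generator,
) -> LatticeState:
    """Seed a fresh lattice.

    Site classes are assigned by exact-count randomized rounding: each
    class receives the floor of its target count, and the leftover sites
    are distributed with probabilities proportional to the fractional
    remainders, so every realized count is within one site of its target.
    Expressions start at zero, phenotype vectors at the class's initial
    row, ages uniform over one expected lifespan (or zero with
    ``cold_start_ages``), and every non-empty site founds its own
    lineage.
    """
    n = N * N
    table = _table_from_config(config)
    fractions = np.asarray(config.seed_fractions, dtype=float)
    ideal = fractions * n
    counts = np.floor(ideal).astype(np.int64)
    leftover = n - counts.sum()
    if leftover > 0:
        resid = ideal - counts
        extra = rng.choice(3, size=leftover, replace=False, p=resid / resid.sum())
        for c in extra:
            counts[c] += 1
    assignment = np.repeat(np.array(_SEED_CLASSES, dtype=np.int8), counts)
    rng.shuffle(assignment)

    cls = assignment
    age = np.zeros(n, dtype=np.int64)
    E = np.zeros((n, panel.G))
    P = np.zeros((n, 4))
    tac = np.zeros(n, dtype=np.uint8)
    tacgen = np.zeros(n, dtype=np.int8)
    lin = np.full(n, -1, dtype=np.int64)

    occupied = cls != EMPTY
    for c in (NTC, NSC):
        mask = cls == c
        P[mask] = table.table[c]
        if not config.cold_start_ages:
            span = max(1, int(table.lifespan(c) / table.c_tilde))
            age[mask] = rng.integers(0, span, size=int(mask.sum()))
    lin[occupied] = np.arange(int(occupied.sum()))

    state = LatticeState(
        N=N,
        config=config,
        panel=panel,
        table=table,
        fields=build_fields(config, panel),
        rng=rng,
        t=0,
        cls=cls,
        age=age,
        E=E,
        P=P,
        tac=tac,
        tacgen=tacgen,
        lin=lin,
    )
    _update_first_seen(state)
    return state


def _update_first_seen(state: LatticeState) -> None:
    counts = state.class_counts()
    for c in range(7):
        if counts[c] > 0 and c not in state.first_seen:
            state.first_seen[c] = state.t


_NB_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_counts(cls_grid: np.ndarray, classes: Sequence[int]) -> np.ndarray:
    """8-neighbor counts of the given classes, with wraparound."""
    mask = np.isin(cls_grid, classes).astype(np.int8)
    total = np.zeros_like(mask)
    for dy, dx in _NB_SHIFTS:
        total = total + np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
    return total


def _excision_due(state: LatticeState) -> bool:
    exc = state.config.excision
    if exc.mode == "none" or state.excision_steps:
        return False
    if exc.fixed_step is not None:
        return state.t == exc.fixed_step
    first_tc = state.first_seen.get(TC)
    if first_tc is None:
        return False
    return state.t == first_tc + state.config.months_to_steps(exc.delay_months)


def step(state: LatticeState) -> np.ndarray:
    """Advance the lattice by one time-step (stages 1–8).

    Returns the per-action counts of chosen phenotypic actions
    ``(proliferation, quiescence, apoptosis, differentiation)``.
    """
    cfg = state.config
    panel = state.panel
    N = state.N
    n = state.n_sites

    conc = exposure_grids(state.fields, state.t).reshape(panel.C, n)
    if cfg.carcinogen_multiplier != 1.0:
        conc = conc * cfg.carcinogen_multiplier

    cls_grid = state.grid()
    stem_nb = _neighbor_counts(cls_grid, (NSC, MNSC, CSC)).reshape(n)
    empty_nb = _neighbor_counts(cls_grid, (EMPTY,)).reshape(n)

    wy_rows, wy_cols = np.nonzero(panel.WY)
    wy_vals = panel.WY[wy_rows, wy_cols]

    seed1, seed2 = state.rng.integers(0, 2**31 - 1, size=2)
    _kernels.gene_class_kernel(
        seed1,
        state.cls,
        state.age,
        state.E,
        state.P,
        np.ascontiguousarray(conc),
        panel.WX_carc,
        wy_rows,
        wy_cols,
        wy_vals,
        panel.T,
        np.ascontiguousarray(panel.instability_pairs),
        panel.U_inc,
        panel.D_inc,
        state.table.table,
        stem_nb,
        empty_nb,
        cfg.nu,
        cfg.beta,
        cfg.age_sign_p,
        cfg.expression_scale,
        panel.age_weight,
        panel.M_bar,
        panel.Upsilon,
        cfg.instability_prob,
        cfg.expression_scale / cfg.nu,
        cfg.phenotype_mod_prob,
        cfg.csc_prob,
        cfg.restrict_csc_to_mutated,
        cfg.dediff_prob,
        cfg.dediff_stem_threshold,
        cfg.dediff_empty_threshold,
        cfg.dediff_empty_at_least,
    )

    action_counts = _kernels.action_kernel(
        seed2,
        N,
        state.cls,
        state.age,
        state.E,
        state.P,
        state.tac,
        state.tacgen,
        state.lin,
        state.table.table,
        cfg.theta,
        cfg.move_prob,
        cfg.kill_prob,
        cfg.tac_prolif_boost,
        cfg.fitness_w_proliferation,
        cfg.fitness_w_apoptosis,
        cfg.fitness_w_age,
        cfg.fitness_cancer_bonus,
        cfg.cell_cycle_hours,
        cfg.lifespan_tissue_hours,
        cfg.lifespan_stem_hours,
    )

    state.t += 1
    _update_first_seen(state)

    if _excision_due(state):
        excise(state, cfg.excision.mode, cfg.excision.rings)
        state.excision_steps.append(state.t)
    elif (
        state.excision_steps
        and "recurrence_tc" not in state.first_seen
        and np.any(state.cls == TC)
    ):
        state.first_seen["recurrence_tc"] = state.t

    state.age[state.cls != EMPTY] += 1
    return action_counts


def excise(state: LatticeState, mode: str, rings: int = 2) -> None:
    """Surgical removal.

    ``tumor``: every TC and CSC, plus every cell within Chebyshev
    distance ``rings`` of any TC, becomes empty.  ``field``:
    additionally every mutated normal cell (MNTC, MNSC) is removed.
    """
    if mode not in ("tumor", "field"):
        raise ValueError(f"unknown excision mode {mode!r}")
    grid = state.grid()
    tc_mask = grid == TC
    ring_mask = maximum_filter(
        tc_mask.astype(np.uint8), size=2 * rings + 1, mode="wrap"
    ).astype(bool)
    remove = ring_mask | np.isin(grid, CANCER_CLASSES)
    if mode == "field":
        remove |= np.isin(grid, (MNTC, MNSC))
    flat = remove.reshape(state.n_sites)
    state.cls[flat] = EMPTY
    state.age[flat] = 0
    state.E[flat] = 0.0
    state.P[flat] = 0.0
    state.tac[flat] = 0
    state.tacgen[flat] = 0
    state.lin[flat] = -1


@dataclass
class RunResult:
    """Outcome of :func:`run_simulation`."""

    state: LatticeState
    timeseries: "object"  # pandas.DataFrame
    events: "object"  # analysis_io.EventRecord
    metadata: dict


def run_simulation(
    config: SimulationConfig,
    panel: GenePanel | None = None,
    stop_when: Callable[[LatticeState], bool] | None = None,
    record: bool = True,
) -> RunResult:
    """Run a complete simulation.

    Parameters
    ----------
    config
        The run configuration; ``config.rng_seed`` seeds the single
        master random stream.
    panel
        Gene panel; defaults to the shipped HNSCC panel (or the panel
        file named in the config).
    stop_when
        Optional early-stopping predicate, checked after every step.
    record
        Record a time-series row every ``config.record_every`` steps.
    """
    from . import __version__, analysis_io

    if panel is None:
        panel = (
            load_panel(config.panel_file) if config.panel_file else build_hnscc_panel()
        )
    rng = np.random.default_rng(config.rng_seed)
    state = init_grid(config.grid_size, config, panel, rng)

    rows = []
    if record:
        rows.append(analysis_io.record_step(state, np.zeros(4, dtype=np.int64)))
    for _ in range(config.steps):
        action_counts = step(state)
        if record and (
            state.t % config.record_every == 0 or state.t == config.steps
        ):
            rows.append(analysis_io.record_step(state, action_counts))
        if stop_when is not None and stop_when(state):
            break

    timeseries = analysis_io.rows_to_frame(rows)
    events = analysis_io.detect_events(state)
    metadata = {
        "package_version": __version__,
        "config": config.to_dict(),
        "rng_seed": config.rng_seed,
        "expression_scale": config.expression_scale,
        "panel": panel.name,
        "steps_run": state.t,
    }
    return RunResult(state=state, timeseries=timeseries, events=events, metadata=metadata)
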