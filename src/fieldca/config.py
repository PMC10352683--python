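"""Run configuration: dataclasses, defaults, and YAML (de)serialization.

All tunable constants of the automaton are surfaced here.  The defaults
reproduce the HNSCC study conditions: 64.5 % normal tissue cells, 6.5 %
normal stem cells and 29 % empty sites at seed, two TAC generations,
quiescent-move probability 0.25, kill threshold 0.2, stem-to-cancer-stem
conversion probability 2.5e-6 per step, dedifferentiation probability
1e-4, instability probability 0.45, phenotype-modification probability
0.35, a 10-hour cell cycle, and Gaussian carcinogen fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["CarcinogenSpec", "ExcisionSpec", "SimulationConfig", "HOURS_PER_MONTH"]

#: average hours per month (365.25 * 24 / 12); one step is `cell_cycle_hours`.
HOURS_PER_MONTH = 730.5


@dataclass
class CarcinogenSpec:
    """One carcinogen input field.

    ``shape`` is ``gaussian``, ``uniform`` or ``file``; ``level`` scales
    the field; ``windows`` lists active ``[start, end)`` step intervals
    (``None`` = always active).
    """

    name: str
    shape: str = "gaussian"
    level: float = 1.0
    windows: list[tuple[int, int]] | None = None
    path: str | None = None


@dataclass
class ExcisionSpec:
    """Surgery plan.

    ``mode``: ``none``, ``tumor`` (remove TC/CSC plus ``rings`` Chebyshev
    rings of tissue around every TC) or ``field`` (additionally remove
    every mutated cell).  The excision triggers either at ``fixed_step``
    or ``delay_months`` after the first tumor cell appears.
    """

    mode: str = "none"
    delay_months: float = 18.0
    fixed_step: int | None = None
    rings: int = 2


@dataclass
class SimulationConfig:
    grid_size: int = 128
    steps: int = 1000
    rng_seed: int = 0

    # initial composition (NTC, NSC, empty); must sum to 1
    seed_fractions: tuple[float, float, float] = (0.645, 0.065, 0.29)
    cold_start_ages: bool = False

    # stem-cell hierarchy
    theta: int = 2
    tac_prolif_boost: float = 1.0 / 3.0

    # movement and competition
    move_prob: float = 0.25
    kill_prob: float = 0.2

    # class-transition probabilities
    csc_prob: float = 2.5e-6
    restrict_csc_to_mutated: bool = True
    dediff_prob: float = 1e-4
    dediff_stem_threshold: int = 0
    dediff_empty_threshold: int = 6
    dediff_empty_at_least: bool = True

    # gene dynamics
    instability_prob: float = 0.45
    phenotype_mod_prob: float = 0.35
    nu: float = 1e6
    beta: float = 1e-3
    age_sign_p: float = 0.5
    expression_scale: float = 1.0

    # phenotype-table parameters
    cell_cycle_hours: float = 10.0
    lifespan_tissue_hours: float = 250.0
    lifespan_stem_hours: float = 25550.0
    prolif_factor_tissue: float = 0.65
    prolif_factor_stem: float = 14.75
    apoptosis_factor: float = 1.625
    diff_factor: float = 1.485

    # fitness weights
    fitness_w_proliferation: float = 1.0
    fitness_w_apoptosis: float = 1.0
    fitness_w_age: float = 1.0
    fitness_cancer_bonus: float = 1.0

    # carcinogens; a global multiplier scales every active field
    carcinogens: list[CarcinogenSpec] = field(
        default_factory=lambda: [
            CarcinogenSpec(name="alcohol"),
            CarcinogenSpec(name="smoking"),
        ]
    )
    carcinogen_multiplier: float = 1.0

    excision: ExcisionSpec = field(default_factory=ExcisionSpec)

    record_every: int = 1
    panel_file: str | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.seed_fractions) - 1.0) > 1e-9:
            raise ValueError("seed_fractions must sum to 1")
        for p in (
            self.move_prob,
            self.kill_prob,
            self.csc_prob,
            self.dediff_prob,
            self.instability_prob,
            self.phenotype_mod_prob,
            self.age_sign_p,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.grid_size < 2:
            raise ValueError("grid_size must be at least 2")
        if self.excision.mode not in ("none", "tumor", "field"):
            raise ValueError(f"unknown excision mode {self.excision.mode!r}")

    @property
    def steps_per_month(self) -> float:
        return HOURS_PER_MONTH / self.cell_cycle_hours

    def months_to_steps(self, months: float) -> int:
        return int(round(months * self.steps_per_month))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        doc = dict(doc)
        if "carcinogens" in doc:
            doc["carcinogens"] = [
                c if isinstance(c, CarcinogenSpec) else CarcinogenSpec(**c)
                for c in doc["carcinogens"]
            ]
        if "excision" in doc and not isinstance(doc["excision"], ExcisionSpec):
            doc["excision"] = ExcisionSpec(**doc["excision"])
        if "seed_fractions" in doc:
            doc["seed_fractions"] = tuple(doc["seed_fractions"])
        return cls(**doc)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
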