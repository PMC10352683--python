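"""Per-cell state model: mutation classification, genetic instability,
phenotype-probability updates, the initial phenotype table, and fitness.

Cell classes are encoded as integers::

    0  NTC    normal tissue cell
    1  MNTC   mutated normal tissue cell
    2  NSC    normal stem cell
    3  MNSC   mutated normal stem cell
    4  CSC    cancer stem cell
    5  TC     tumor cell
    6  empty

The phenotype vector ``P = (p, q, a, d)`` holds the probabilities of
proliferation, quiescence, apoptosis and differentiation and is kept on
the probability simplex by every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gene_panel import GenePanel, ONCOGENE

__all__ = [
    "NTC",
    "MNTC",
    "NSC",
    "MNSC",
    "CSC",
    "TC",
    "EMPTY",
    "CLASS_NAMES",
    "STEM_CLASSES",
    "MUTATED_CLASSES",
    "CANCER_CLASSES",
    "StateError",
    "CellState",
    "InitialPhenotypeTable",
    "FitnessWeights",
    "positively_mutated",
    "count_positive",
    "is_mutated_cell",
    "gene_instability_step",
    "phenotype_update",
    "initial_phenotype",
    "fitness",
]

NTC, MNTC, NSC, MNSC, CSC, TC, EMPTY = range(7)
CLASS_NAMES = ("NTC", "MNTC", "NSC", "MNSC", "CSC", "TC", "empty")
STEM_CLASSES = (NSC, MNSC, CSC)
MUTATED_CLASSES = (MNTC, MNSC, CSC, TC)
CANCER_CLASSES = (CSC, TC)

#: cell classes using the tissue-cell lifespan (stem classes use the stem
#: lifespan) when converting age to fractions of a lifespan.
_TISSUE_CLASSES = (NTC, MNTC, TC)


class StateError(ValueError):
    """Raised when an operation is applied to a cell class it does not
    support."""


@dataclass
class CellState:
    """One lattice occupant (convenience container; the lattice engine
    stores the same fields in flat arrays)."""

    cls: int
    age: int
    E: np.ndarray
    P: np.ndarray
    tac_flag: int = 0
    tac_gen: int = 0
    lineage: int = -1


# ---------------------------------------------------------------------------
# Mutation classification
# ---------------------------------------------------------------------------


def positively_mutated(e, gene_type, M_bar: float):
    """Whether a gene is mutated in its cancer-promoting direction.

    True iff (tumor suppressor and ``e <= -M_bar``) or (oncogene and
    ``e >= M_bar``).  Broadcasts over arrays.
    """
    if M_bar <= 0:
        raise ValueError("M_bar must be positive")
    e = np.asarray(e, dtype=float)
    gene_type = np.asarray(gene_type)
    onco = gene_type == ONCOGENE
    out = np.where(onco, e >= M_bar, e <= -M_bar)
    return bool(out) if out.ndim == 0 else out


def count_positive(E: np.ndarray, T: np.ndarray, M_bar: float):
    """Number of positively mutated genes (last-axis reduction)."""
    E = np.asarray(E, dtype=float)
    T = np.asarray(T)
    if E.shape[-1] != T.shape[0]:
        raise ValueError("E and T length mismatch")
    return positively_mutated(E, T, M_bar).sum(axis=-1)


def is_mutated_cell(count, Upsilon: int):
    """A cell is mutated when it carries at least ``Upsilon`` positively
    mutated genes."""
    out = np.asarray(count) >= Upsilon
    return bool(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Genetic instability
# ---------------------------------------------------------------------------


def gene_instability_step(
    E: np.ndarray,
    panel: GenePanel,
    p_mod: float,
    rng: np.random.Generator,
    max_change: float | None = None,
    nu: float = 1e6,
) -> np.ndarray:
    """One genetic-instability update of a single cell's expressions.

    For each directed related pair ``(i, j)`` (``R[i, j] = 1``, taken in
    row-major order), with probability ``p_mod`` gene ``j`` is nudged by
    ``u * max_change`` (``u ~ U(0, 1)``): toward its cancer-promoting
    direction when gene ``i`` is positively mutated, otherwise back
    toward normal expression (a repair that never overshoots zero).

    ``max_change`` defaults to ``1 / nu``, the cap on any single
    instability change.
    """
    if not 0.0 <= p_mod <= 1.0:
        raise ValueError("p_mod must be in [0, 1]")
    cap = (1.0 / nu) if max_change is None else float(max_change)
    E = np.array(E, dtype=float)
    for i, j in panel.instability_pairs:
        if rng.random() >= p_mod:
            continue
        u = rng.random()
        if positively_mutated(E[i], panel.T[i], panel.M_bar):
            direction = 1.0 if panel.T[j] == ONCOGENE else -1.0
            E[j] += u * cap * direction
        else:
            E[j] -= np.sign(E[j]) * min(abs(E[j]), u * cap)
    return E


# ---------------------------------------------------------------------------
# Phenotype updates
# ---------------------------------------------------------------------------


def phenotype_update(
    P: np.ndarray,
    E: np.ndarray,
    panel: GenePanel,
    p_mod_ph: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Increment phenotype probabilities from mutated genes.

    For every gene whose expression lies past the mutation threshold, the
    corresponding column of ``U_inc`` (upregulated) or ``D_inc``
    (downregulated) is applied with probability ``p_mod_ph``.  Each
    non-quiescence change is balanced by an equal opposite change to
    quiescence; the result is clipped to nonnegative values and
    renormalized so the vector stays a probability distribution.

    Accepts a single ``(4,)`` vector with ``(G,)`` expressions, or
    batches ``(n, 4)`` with ``(n, G)``.
    """
    if not 0.0 <= p_mod_ph <= 1.0:
        raise ValueError("p_mod_ph must be in [0, 1]")
    P = np.array(P, dtype=float)
    E = np.asarray(E, dtype=float)
    single = P.ndim == 1
    Pb = P[None, :] if single else P
    Eb = E[None, :] if single else E
    n = Pb.shape[0]
    for j in range(panel.G):
        up = Eb[:, j] >= panel.M_bar
        down = Eb[:, j] <= -panel.M_bar
        hit = up | down
        if not hit.any():
            continue
        gate = rng.random(n) < p_mod_ph
        col = np.where(up[:, None], panel.U_inc[:, j], panel.D_inc[:, j])
        delta = np.where((hit & gate)[:, None], col, 0.0)
        # balance the non-quiescence increments against quiescence
        delta[:, 1] -= delta[:, 0] + delta[:, 2] + delta[:, 3]
        Pb = Pb + delta
    Pb = np.clip(Pb, 0.0, None)
    Pb = Pb / Pb.sum(axis=1, keepdims=True)
    return Pb[0] if single else Pb


# ---------------------------------------------------------------------------
# Initial phenotype table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InitialPhenotypeTable:
    """Initial phenotype probabilities per cell class.

    The table is built from the cell-cycle length ``c_tilde`` (hours),
    the tissue- and stem-cell lifespans ``c1`` and ``c2`` (hours), the
    proliferation factors ``p1`` (tissue) and ``p2`` (stem), the
    apoptotic factor ``alpha_bar``, the differentiation factor ``d_bar``
    and the maximum TAC generation count ``theta``.

    The per-class rows follow a telescoping construction so that each row
    sums to one exactly: apoptosis is ``a = c_tilde / lifespan`` (divided
    by ``alpha_bar`` for the mutated classes and by ``(5 alpha_bar)**2``
    for the cancer classes), proliferation is the class's proliferation
    factor times ``a``, differentiation is ``d_bar * d_tilde`` for the
    stem classes (zero otherwise), and quiescence takes the remainder.
    ``d_tilde = 1 / (2**(theta+1) - 2)`` is the reciprocal of the number
    of cells a single transit-amplifying cell produces.
    """

    c_tilde: float = 10.0
    c1: float = 250.0
    c2: float = 25550.0
    p1: float = 0.65
    p2: float = 14.75
    alpha_bar: float = 1.625
    d_bar: float = 1.485
    theta: int = 2
    table: np.ndarray = field(init=False, repr=False)

    @property
    def a1(self) -> float:
        """Baseline apoptosis probability of a tissue cell per step."""
        return self.c_tilde / self.c1

    @property
    def a2(self) -> float:
        """Baseline apoptosis probability of a stem cell per step."""
        return self.c_tilde / self.c2

    @property
    def d_tilde(self) -> float:
        return 1.0 / (2 ** (self.theta + 1) - 2)

    def __post_init__(self) -> None:
        a1, a2 = self.a1, self.a2
        ab, p1, p2 = self.alpha_bar, self.p1, self.p2
        dd = self.d_bar * self.d_tilde
        cancer_div = (5.0 * ab) ** 2
        rows = np.zeros((6, 4))

        def row(p_factor, a_base, a_div, diff):
            a = a_base / a_div
            p = p_factor * a_base
            q = 1.0 - p - a - diff
            return (p, q, a, diff)

        rows[NTC] = row(p1, a1, 1.0, 0.0)
        rows[MNTC] = row(p1, a1, ab, 0.0)
        rows[NSC] = row(p2, a2, 1.0, dd)
        rows[MNSC] = row(p2, a2, ab, dd)
        rows[CSC] = row(p2, a2, cancer_div, dd)
        rows[TC] = row(p1, a1, cancer_div, 0.0)
        if (rows < 0).any() or (rows > 1).any():
            raise ValueError("inadmissible phenotype parameters: row out of [0, 1]")
        object.__setattr__(self, "table", rows)

    def lifespan(self, cls: int) -> float:
        """Lifespan (hours) governing a class's age scale."""
        return self.c1 if cls in _TISSUE_CLASSES else self.c2


def initial_phenotype(cls: int, table: InitialPhenotypeTable) -> np.ndarray:
    """Initial phenotype row for a (non-empty) cell class."""
    if not 0 <= cls <= 5:
        raise StateError(f"no initial phenotype for class {cls}")
    return table.table[cls].copy()


# ---------------------------------------------------------------------------
# Fitness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitnessWeights:
    w_proliferation: float = 1.0
    w_apoptosis: float = 1.0
    w_age: float = 1.0
    cancer_bonus: float = 1.0


def fitness(
    cell: CellState,
    weights: FitnessWeights = FitnessWeights(),
    table: InitialPhenotypeTable = InitialPhenotypeTable(),
) -> float:
    """Deterministic competitive fitness of a cell.

    Increasing in the proliferation probability, decreasing in the
    apoptosis probability and in age (measured in fractions of the
    class's lifespan), with an additive bonus for the cancer classes,
    which outcompete normal tissue.
    """
    if cell.cls == EMPTY:
        raise StateError("empty sites have no fitness")
    age_frac = cell.age * table.c_tilde / table.lifespan(cell.cls)
    f = (
        weights.w_proliferation * cell.P[0]
        - weights.w_apoptosis * cell.P[2]
        - weights.w_age * age_frac
    )
    if cell.cls in CANCER_CLASSES:
        f += weights.cancer_bonus
    return float(f)
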