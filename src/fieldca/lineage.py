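"""Lineage tracking, ranking, and clonality classification.

Every non-empty site on a freshly seeded lattice founds its own lineage;
daughters inherit the parent's lineage id and no transition (mutation,
cancer-stem conversion, dedifferentiation, TAC maturation) ever changes
it, so the number of living lineages can only shrink.  A field or tumor
is *monoclonal* when exactly one lineage contributes cancer-class cells
(CSC or TC) and *polyclonal* when several do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_rules import CANCER_CLASSES, CellState, EMPTY, MUTATED_CLASSES, TC

__all__ = [
    "LineageTable",
    "inherit",
    "lineage_table",
    "top_k",
    "classify_clonality",
    "top_k_map",
]


@dataclass
class LineageTable:
    """Per-lineage census at one time point.

    ``sizes`` counts all living members, ``mutated_sizes`` the members in
    mutated classes, ``cancer_sizes`` the members in cancer classes
    (CSC + TC).  Only living lineages appear.
    """

    ids: np.ndarray
    sizes: np.ndarray
    mutated_sizes: np.ndarray
    cancer_sizes: np.ndarray
    tc_sizes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lineage": self.ids,
                "size": self.sizes,
                "mutated_size": self.mutated_sizes,
                "cancer_size": self.cancer_sizes,
                "tc_size": self.tc_sizes,
            }
        )

    @property
    def n_living(self) -> int:
        return len(self.ids)


def inherit(parent: CellState, child: CellState) -> CellState:
    """Copy the parent's lineage id onto a daughter cell."""
    if parent.cls == EMPTY:
        raise ValueError("empty sites cannot found daughters")
    child.lineage = parent.lineage
    return child


def lineage_table(state) -> LineageTable:
    """Census the living lineages of a lattice state."""
    alive = state.lin >= 0
    ids = state.lin[alive]
    cls = state.cls[alive]
    if ids.size == 0:
        empty = np.array([], dtype=np.int64)
        return LineageTable(
            empty, empty.copy(), empty.copy(), empty.copy(), empty.copy()
        )
    max_id = int(ids.max()) + 1
    sizes = np.bincount(ids, minlength=max_id)
    mutated = np.bincount(
        ids[np.isin(cls, MUTATED_CLASSES)], minlength=max_id
    )
    cancer = np.bincount(ids[np.isin(cls, CANCER_CLASSES)], minlength=max_id)
    tc = np.bincount(ids[cls == TC], minlength=max_id)
    living = sizes > 0
    lid = np.nonzero(living)[0]
    return LineageTable(lid, sizes[lid], mutated[lid], cancer[lid], tc[lid])


def top_k(table: LineageTable, k: int) -> np.ndarray:
    """The ``k`` largest living lineages by current size; ties broken by
    the smaller (earlier-founded) id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    # sort by (-size, id): lexsort's last key is primary
    order = np.lexsort((table.ids, -table.sizes))
    return table.ids[order[:k]]


def classify_clonality(table: LineageTable, use_csc: bool = True) -> str:
    """Classify cancer origin.

    Returns ``"none"`` (no cancer-class cells), ``"monoclonal"`` (one
    contributing lineage) or ``"polyclonal"``.  With ``use_csc=False``
    only lineages carrying tumor cells are counted.
    """
    sizes = table.cancer_sizes if use_csc else table.tc_sizes
    n = int((sizes > 0).sum())
    if n == 0:
        return "none"
    return "monoclonal" if n == 1 else "polyclonal"


def n_cancer_lineages(table: LineageTable) -> int:
    """Number of lineages with at least one CSC or TC member."""
    return int((table.cancer_sizes > 0).sum())


def top_k_map(state, k: int = 20) -> np.ndarray:
    """Categorical lineage image: ``(N, N)`` array with values 1..k for
    membership in the k largest lineages (1 = largest), 0 for cells not
    in any top lineage, and -1 for empty sites."""
    table = lineage_table(state)
    out = np.zeros(state.n_sites, dtype=np.int32)
    out[state.cls == EMPTY] = -1
    if table.n_living:
        for rank, lid in enumerate(top_k(table, k), start=1):
            out[state.lin == lid] = rank
    return out.reshape(state.N, state.N)
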