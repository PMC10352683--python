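"""Time-series extraction, event detection, summaries, and all I/O.

One time-series row per recorded step carries the class fractions, the
mutated-cell fraction, the fraction of cells executing each phenotypic
action, the mean expression of every gene over occupied sites, the
fraction of panel genes whose population-mean expression is positively
mutated, and the number of lineages carrying cancer-class cells.

Snapshots are rendered with the standard class color map: NTC brown,
MNTC green, NSC blue, MNSC yellow, CSC purple, TC red, empty white.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_rules import (
    CLASS_NAMES,
    CSC,
    EMPTY,
    MUTATED_CLASSES,
    TC,
    count_positive,
)
from .gene_panel import ACTIONS
from .lineage import lineage_table, n_cancer_lineages

__all__ = [
    "CLASS_COLORS",
    "EventRecord",
    "record_step",
    "rows_to_frame",
    "detect_events",
    "replicate_summary",
    "write_timeseries",
    "read_timeseries",
    "write_metadata",
    "read_metadata",
    "class_image",
    "save_snapshot",
]

#: RGB colors per class code 0..6 (brown, green, blue, yellow, purple,
#: red, white).
CLASS_COLORS = np.array(
    [
        (139, 69, 19),  # NTC brown
        (34, 139, 34),  # MNTC green
        (30, 80, 200),  # NSC blue
        (240, 200, 0),  # MNSC yellow
        (128, 0, 128),  # CSC purple
        (220, 20, 20),  # TC red
        (255, 255, 255),  # empty white
    ],
    dtype=np.uint8,
)


@dataclass
class EventRecord:
    """First-occurrence steps of the key events of a run.

    Missing events are ``None``.  ``recurrence_step`` is the first step
    with a tumor cell after the (first) excision.
    """

    first_mutated_cell_step: int | None
    first_csc_step: int | None
    first_tc_step: int | None
    excision_steps: list[int]
    recurrence_step: int | None
    final_clonality: str

    def to_dict(self) -> dict:
        return asdict(self)


def record_step(state, action_counts: np.ndarray) -> dict:
    """Measure one time-series row from a lattice state (O(N^2))."""
    counts = state.class_counts()
    n = counts.sum()
    occupied = int(n - counts[EMPTY])
    row: dict = {"step": state.t}
    for c, name in enumerate(CLASS_NAMES):
        row[f"frac_{name}"] = counts[c] / n
    row["frac_mutated"] = counts[list(MUTATED_CLASSES)].sum() / n
    acted = action_counts.sum()
    for i, action in enumerate(ACTIONS):
        row[f"frac_action_{action}"] = (
            action_counts[i] / acted if acted > 0 else 0.0
        )
    panel = state.panel
    if occupied > 0:
        mean_E = state.E[state.cls != EMPTY].mean(axis=0)
        row.update(
            {f"mean_expr_{g}": mean_E[j] for j, g in enumerate(panel.gene_names)}
        )
        row["frac_genes_positive"] = (
            count_positive(mean_E, panel.T, panel.M_bar) / panel.G
        )
    else:
        row.update({f"mean_expr_{g}": np.nan for g in panel.gene_names})
        row["frac_genes_positive"] = np.nan
    row["n_cancer_lineages"] = n_cancer_lineages(lineage_table(state))
    return row


def rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def frac_genes_positive_per_cell(state) -> float:
    """Alternative aggregation: mean over occupied cells of the per-cell
    fraction of positively mutated genes."""
    occ = state.cls != EMPTY
    if not occ.any():
        return float("nan")
    per_cell = count_positive(state.E[occ], state.panel.T, state.panel.M_bar)
    return float(per_cell.mean() / state.panel.G)


def detect_events(state) -> EventRecord:
    """Extract the event record from a finished (or running) state."""
    from .lineage import classify_clonality

    first = state.first_seen
    mutated_firsts = [first[c] for c in MUTATED_CLASSES if c in first]
    excisions = list(state.excision_steps)
    recurrence = first.get("recurrence_tc")
    record = EventRecord(
        first_mutated_cell_step=min(mutated_firsts) if mutated_firsts else None,
        first_csc_step=first.get(CSC),
        first_tc_step=first.get(TC),
        excision_steps=excisions,
        recurrence_step=recurrence,
        final_clonality=classify_clonality(lineage_table(state)),
    )
    return record


def replicate_summary(results: list[tuple[str, "object"]]) -> pd.DataFrame:
    """Summarize event records across replicates.

    ``results`` holds ``(condition_label, EventRecord)`` pairs.  Returns
    per-condition medians and quartiles of the event times along with
    clonality counts; missing events are ignored in the quantiles.
    """
    rows = []
    frame = pd.DataFrame(
        [
            {
                "condition": label,
                "first_mutated": ev.first_mutated_cell_step,
                "first_csc": ev.first_csc_step,
                "first_tc": ev.first_tc_step,
                "clonality": ev.final_clonality,
            }
            for label, ev in results
        ]
    )
    for condition, grp in frame.groupby("condition", sort=False):
        row = {"condition": condition, "n": len(grp)}
        for col in ("first_mutated", "first_csc", "first_tc"):
            vals = grp[col].dropna()
            row[f"{col}_median"] = vals.median() if len(vals) else np.nan
            row[f"{col}_q1"] = vals.quantile(0.25) if len(vals) else np.nan
            row[f"{col}_q3"] = vals.quantile(0.75) if len(vals) else np.nan
        for kind in ("none", "monoclonal", "polyclonal"):
            row[f"n_{kind}"] = int((grp["clonality"] == kind).sum())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_metadata(metadata: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metadata, indent=2, default=_json_default))


def read_metadata(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def class_image(state) -> np.ndarray:
    """Render the class grid as an ``(N, N, 3)`` RGB image using the
    standard color map."""
    return CLASS_COLORS[state.grid()]


def save_snapshot(state, png_path: str | Path, npz_path: str | Path | None = None) -> None:
    """Write a PNG render of the grid and, optionally, the full state
    arrays as a compressed ``.npz``."""
    from PIL import Image

    Image.fromarray(class_image(state)).save(png_path)
    if npz_path is not None:
        np.savez_compressed(
            npz_path,
            cls=state.cls,
            age=state.age,
            E=state.E,
            P=state.P,
            tac=state.tac,
            tacgen=state.tacgen,
            lin=state.lin,
            t=state.t,
        )
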