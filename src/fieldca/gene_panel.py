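"""Gene panel data model and parameter-matrix construction.

A *gene panel* bundles everything the simulator needs to know about the
genes it tracks: which are tumor suppressors and which are oncogenes, how
each carcinogen pushes each gene's expression, which phenotypic actions a
mutated gene modifies, and which genes regulate which.  From the per-gene
annotations the panel derives the weight matrices of the gene-expression
network (``WX``, ``WY``), the gene relationship matrix ``R`` used during
the genetic-instability stage, and the phenotype increment matrices
``U_inc``/``D_inc``.

The default panel is the 10-gene HNSCC panel (TP53, TP73, RB, TP21, TP16,
EGFR, CCDN1, MYC, PIK3CA, RAS) with two carcinogens (alcohol-type and
smoking-type).  Arbitrary panels can be defined in a YAML annotation file
and loaded with :func:`load_panel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "ACTIONS",
    "GeneAnnotation",
    "GenePanel",
    "PanelError",
    "build_panel",
    "build_hnscc_panel",
    "build_wx",
    "build_increment_matrices",
    "build_relationship_matrix",
    "build_wy",
    "load_panel",
    "save_panel",
    "default_panel_path",
]

#: Phenotypic actions, in the fixed order used throughout the package.
ACTIONS = ("proliferation", "quiescence", "apoptosis", "differentiation")

_ACTION_INDEX = {a: i for i, a in enumerate(ACTIONS)}

TUMOR_SUPPRESSOR = 0
ONCOGENE = 1


class PanelError(ValueError):
    """Raised for inconsistent gene-panel definitions."""


@dataclass(frozen=True)
class GeneAnnotation:
    """Annotation of a single gene.

    Parameters
    ----------
    name
        Gene symbol.
    gene_type
        0 for a tumor suppressor, 1 for an oncogene.
    carcinogen_signs
        One entry per carcinogen, each in {-1, 0, +1}; +1 means the
        carcinogen upregulates the gene.
    phenotype_effects
        ``(action, direction)`` pairs describing how the gene, once
        mutated in its cancer-promoting direction, shifts the probability
        of each phenotypic action.  ``direction`` is ``"up"`` or
        ``"down"``.
    activates
        ``(gene_name, direction)`` pairs: genes whose expression this
        gene regulates, with the direction of regulation.
    """

    name: str
    gene_type: int
    carcinogen_signs: tuple[int, ...]
    phenotype_effects: tuple[tuple[str, str], ...] = ()
    activates: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.gene_type not in (TUMOR_SUPPRESSOR, ONCOGENE):
            raise PanelError(f"{self.name}: gene_type must be 0 or 1")
        if any(s not in (-1, 0, 1) for s in self.carcinogen_signs):
            raise PanelError(f"{self.name}: carcinogen signs must be -1, 0 or +1")
        for action, direction in self.phenotype_effects:
            if action not in _ACTION_INDEX:
                raise PanelError(f"{self.name}: unknown phenotypic action {action!r}")
            if direction not in ("up", "down"):
                raise PanelError(f"{self.name}: bad effect direction {direction!r}")
        for gene, direction in self.activates:
            if direction not in ("up", "down"):
                raise PanelError(f"{self.name}: bad regulation direction {direction!r}")


@dataclass(frozen=True)
class GenePanel:
    """A gene panel with all derived parameter matrices.

    Attributes
    ----------
    genes
        Ordered gene annotations (length ``G``).
    carcinogen_names
        Names of the carcinogen inputs, defining the column order of
        ``WX_carc`` (length ``C``).
    T
        Binary gene-type vector, 0 = tumor suppressor, 1 = oncogene.
    R
        Binary ``G x G`` relationship matrix; ``R[i, j] = 1`` means gene
        ``i`` regulates gene ``j`` during the genetic-instability stage.
        The diagonal is zero (genes cannot modify themselves).
    WX_carc
        Signed ``G x C`` carcinogen-weight block of the input weight
        matrix; the full ``WX`` additionally carries a per-step random-sign
        age column (see :func:`build_wx`).
    WY
        ``G x G`` output weight matrix; entry ``[i, j]`` is the influence
        of gene ``j`` on gene ``i``.
    U_inc, D_inc
        ``4 x G`` phenotype-probability increment matrices applied when a
        gene's expression is above (``U_inc``) or below (``D_inc``) the
        mutation threshold.  ``U_inc == -D_inc`` by construction.
    M_bar
        Mutation threshold on the absolute gene expression.
    Upsilon
        Minimum number of positively mutated genes for a cell to count as
        mutated.
    increment_magnitude
        Magnitude of a single phenotype-probability increment.
    age_weight
        Magnitude of the age column of ``WX``.
    """

    genes: tuple[GeneAnnotation, ...]
    carcinogen_names: tuple[str, ...]
    T: np.ndarray
    R: np.ndarray
    WX_carc: np.ndarray
    WY: np.ndarray
    U_inc: np.ndarray
    D_inc: np.ndarray
    M_bar: float = 0.1
    Upsilon: int = 4
    increment_magnitude: float = 1e-6
    age_weight: float = 1e-7
    name: str = "custom"

    @property
    def G(self) -> int:
        return len(self.genes)

    @property
    def C(self) -> int:
        return len(self.carcinogen_names)

    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    def carcinogen_index(self, name: str) -> int:
        return self.carcinogen_names.index(name)

    @property
    def instability_pairs(self) -> np.ndarray:
        """``(n_pairs, 2)`` array of directed (source, target) gene indices."""
        src, dst = np.nonzero(self.R)
        return np.column_stack([src, dst])


def build_increment_matrices(
    genes: Sequence[GeneAnnotation], increment_magnitude: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Build the phenotype increment matrices ``(U_inc, D_inc)``.

    Each gene's listed phenotype effects (with magnitude
    ``increment_magnitude``) are placed in the matrix that corresponds to
    the gene's cancer-promoting direction: the ``D_inc`` column for a
    tumor suppressor (promoted when downregulated), the ``U_inc`` column
    for an oncogene (promoted when upregulated).  The other matrix is the
    negation, so ``U_inc + D_inc == 0`` holds exactly.
    """
    G = len(genes)
    U = np.zeros((4, G))
    for j, gene in enumerate(genes):
        col = np.zeros(4)
        for action, direction in gene.phenotype_effects:
            col[_ACTION_INDEX[action]] = (
                increment_magnitude if direction == "up" else -increment_magnitude
            )
        if gene.gene_type == ONCOGENE:
            U[:, j] = col
        else:
            U[:, j] = -col
    return U, -U


def build_relationship_matrix(genes: Sequence[GeneAnnotation]) -> np.ndarray:
    """Build the binary gene relationship matrix ``R`` from annotations.

    ``R[i, j] = 1`` when gene ``i`` lists gene ``j`` among the genes it
    regulates.  The diagonal is forced to zero so that a gene never
    modifies itself during the genetic-instability stage.
    """
    G = len(genes)
    index = {g.name: i for i, g in enumerate(genes)}
    R = np.zeros((G, G), dtype=np.int8)
    for i, gene in enumerate(genes):
        for target, _direction in gene.activates:
            if target not in index:
                raise PanelError(f"{gene.name} regulates unknown gene {target!r}")
            j = index[target]
            if j != i:
                R[i, j] = 1
    return R


def build_wy(genes: Sequence[GeneAnnotation]) -> np.ndarray:
    """Build the output weight matrix ``WY`` from the regulation lists.

    Each diagonal entry starts from a default weight of 0.1 and gains 0.1
    for every gene the diagonal gene regulates.  Off-diagonal entry
    ``[i, j]`` is +0.01 when gene ``j`` upregulates gene ``i`` and -0.01
    when it downregulates it.
    """
    G = len(genes)
    index = {g.name: i for i, g in enumerate(genes)}
    WY = np.zeros((G, G))
    for j, gene in enumerate(genes):
        WY[j, j] = 0.1 * (1 + len(gene.activates))
        for target, direction in gene.activates:
            i = index[target]
            if i == j:
                continue
            WY[i, j] = 0.01 if direction == "up" else -0.01
    return WY


def build_panel(
    genes: Sequence[GeneAnnotation],
    carcinogen_names: Sequence[str],
    *,
    M_bar: float = 0.1,
    Upsilon: int = 4,
    increment_magnitude: float = 1e-6,
    age_weight: float = 1e-7,
    name: str = "custom",
) -> GenePanel:
    """Assemble a :class:`GenePanel` from per-gene annotations."""
    genes = tuple(genes)
    C = len(carcinogen_names)
    for g in genes:
        if len(g.carcinogen_signs) != C:
            raise PanelError(
                f"{g.name}: expected {C} carcinogen signs, got {len(g.carcinogen_signs)}"
            )
    T = np.array([g.gene_type for g in genes], dtype=np.int8)
    WX_carc = np.array([g.carcinogen_signs for g in genes], dtype=float)
    U_inc, D_inc = build_increment_matrices(genes, increment_magnitude)
    return GenePanel(
        genes=genes,
        carcinogen_names=tuple(carcinogen_names),
        T=T,
        R=build_relationship_matrix(genes),
        WX_carc=WX_carc,
        WY=build_wy(genes),
        U_inc=U_inc,
        D_inc=D_inc,
        M_bar=M_bar,
        Upsilon=Upsilon,
        increment_magnitude=increment_magnitude,
        age_weight=age_weight,
        name=name,
    )


def build_wx(panel: GenePanel, age_signs: np.ndarray) -> np.ndarray:
    """Assemble the full ``G x (C+1)`` input weight matrix.

    The first ``C`` columns are the static carcinogen signs; the last
    column is the age weight with the supplied per-gene random signs,
    which model replication errors accumulating in either direction as a
    cell ages.

    Parameters
    ----------
    panel
        The gene panel.
    age_signs
        Vector of length ``G`` with entries in {-1, +1}, freshly drawn
        each time-step.
    """
    age_signs = np.asarray(age_signs)
    if age_signs.shape != (panel.G,):
        raise PanelError(
            f"age_signs must have shape ({panel.G},), got {age_signs.shape}"
        )
    if not np.all(np.isin(age_signs, (-1, 1))):
        raise PanelError("age_signs entries must be -1 or +1")
    return np.column_stack([panel.WX_carc, age_signs * panel.age_weight])


# ---------------------------------------------------------------------------
# The default HNSCC panel
# ---------------------------------------------------------------------------

# Carcinogen column order: the alcohol-type carcinogen occupies column 1 and
# the smoking-type carcinogen column 2 (ethanol upregulates TP53, which fixes
# the sign pattern of the first column).  The mapping is carried explicitly
# in `carcinogen_names`, never assumed by position elsewhere.
HNSCC_CARCINOGENS = ("alcohol", "smoking")

_ALL_OTHERS_UP = "__all_up__"  # sentinel: regulates every other gene upward

_HNSCC_TABLE: tuple[dict, ...] = (
    dict(
        name="TP53",
        gene_type=TUMOR_SUPPRESSOR,
        carcinogen_signs=(1, -1),
        effects=(("proliferation", "up"), ("apoptosis", "down"), ("quiescence", "down")),
        activates=_ALL_OTHERS_UP,
    ),
    dict(
        name="TP73",
        gene_type=TUMOR_SUPPRESSOR,
        carcinogen_signs=(0, 0),
        effects=(("apoptosis", "down"),),
        activates=(),
    ),
    dict(
        name="RB",
        gene_type=TUMOR_SUPPRESSOR,
        carcinogen_signs=(0, -1),
        effects=(
            ("proliferation", "up"),
            ("differentiation", "up"),
            ("quiescence", "down"),
        ),
        activates=(("TP53", "up"), ("CCDN1", "up")),
    ),
    dict(
        name="TP21",
        gene_type=TUMOR_SUPPRESSOR,
        carcinogen_signs=(1, -1),
        effects=(("proliferation", "up"),),
        activates=(),
    ),
    dict(
        name="TP16",
        gene_type=TUMOR_SUPPRESSOR,
        carcinogen_signs=(1, 0),
        effects=(("proliferation", "up"),),
        activates=(),
    ),
    dict(
        name="EGFR",
        gene_type=ONCOGENE,
        carcinogen_signs=(1, 1),
        effects=(("proliferation", "up"),),
        activates=(),
    ),
    dict(
        name="CCDN1",
        gene_type=ONCOGENE,
        carcinogen_signs=(1, 1),
        effects=(("apoptosis", "down"),),
        activates=(("TP21", "up"),),
    ),
    dict(
        name="MYC",
        gene_type=ONCOGENE,
        carcinogen_signs=(0, 1),
        effects=(
            ("proliferation", "up"),
            ("differentiation", "up"),
            ("apoptosis", "down"),
        ),
        activates=(("TP21", "down"), ("RAS", "up")),
    ),
    dict(
        name="PIK3CA",
        gene_type=ONCOGENE,
        carcinogen_signs=(0, 1),
        effects=(("apoptosis", "down"),),
        activates=(),
    ),
    dict(
        name="RAS",
        gene_type=ONCOGENE,
        carcinogen_signs=(1, 1),
        effects=(
            ("proliferation", "up"),
            ("differentiation", "up"),
            ("apoptosis", "down"),
        ),
        activates=(("CCDN1", "up"), ("MYC", "up")),
    ),
)


def _hnscc_annotations() -> tuple[GeneAnnotation, ...]:
    names = tuple(row["name"] for row in _HNSCC_TABLE)
    annotations = []
    for row in _HNSCC_TABLE:
        activates = row["activates"]
        if activates == _ALL_OTHERS_UP:
            activates = tuple((n, "up") for n in names if n != row["name"])
        annotations.append(
            GeneAnnotation(
                name=row["name"],
                gene_type=row["gene_type"],
                carcinogen_signs=row["carcinogen_signs"],
                phenotype_effects=row["effects"],
                activates=tuple(activates),
            )
        )
    return tuple(annotations)


def build_hnscc_panel() -> GenePanel:
    """Build the default 10-gene HNSCC panel.

    TP53 is treated as regulating all other genes, which gives it the
    largest output weight (1.0) and makes every gene susceptible to
    instability cascades once TP53 is positively mutated.
    """
    return build_panel(
        _hnscc_annotations(),
        HNSCC_CARCINOGENS,
        M_bar=0.1,
        Upsilon=4,
        increment_magnitude=1e-6,
        age_weight=1e-7,
        name="hnscc-10-gene",
    )


# ---------------------------------------------------------------------------
# Declarative panel files
# ---------------------------------------------------------------------------


def default_panel_path() -> Path:
    """Path of the shipped HNSCC panel definition file."""
    return Path(__file__).parent / "data" / "hnscc_panel.yaml"


def save_panel(panel: GenePanel, path: str | Path) -> None:
    """Write a panel's annotations to a YAML file (derived matrices are
    reconstructed on load, so only annotations are stored)."""
    doc = {
        "name": panel.name,
        "carcinogens": list(panel.carcinogen_names),
        "mutation_threshold": float(panel.M_bar),
        "min_positive_genes": int(panel.Upsilon),
        "increment_magnitude": float(panel.increment_magnitude),
        "age_weight": float(panel.age_weight),
        "genes": [
            {
                "name": g.name,
                "type": "oncogene" if g.gene_type == ONCOGENE else "tumor_suppressor",
                "carcinogen_signs": {
                    c: int(s) for c, s in zip(panel.carcinogen_names, g.carcinogen_signs)
                },
                "phenotype_effects": [
                    {"action": a, "direction": d} for a, d in g.phenotype_effects
                ],
                "activates": [{"gene": t, "direction": d} for t, d in g.activates],
            }
            for g in panel.genes
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_panel(path: str | Path | None = None) -> GenePanel:
    """Load a panel from a YAML annotation file.

    With no argument the shipped HNSCC panel file is loaded.
    """
    if path is None:
        path = default_panel_path()
    doc = yaml.safe_load(Path(path).read_text())
    carcinogens = tuple(doc["carcinogens"])
    genes = []
    for entry in doc["genes"]:
        gene_type = {"tumor_suppressor": TUMOR_SUPPRESSOR, "oncogene": ONCOGENE}[
            entry["type"]
        ]
        signs = tuple(int(entry["carcinogen_signs"].get(c, 0)) for c in carcinogens)
        effects = tuple(
            (e["action"], e["direction"]) for e in entry.get("phenotype_effects", [])
        )
        activates = tuple(
            (a["gene"], a["direction"]) for a in entry.get("activates", [])
        )
        genes.append(
            GeneAnnotation(
                name=entry["name"],
                gene_type=gene_type,
                carcinogen_signs=signs,
                phenotype_effects=effects,
                activates=activates,
            )
        )
    return build_panel(
        genes,
        carcinogens,
        M_bar=float(doc.get("mutation_threshold", 0.1)),
        Upsilon=int(doc.get("min_positive_genes", 4)),
        increment_magnitude=float(doc.get("increment_magnitude", 1e-6)),
        age_weight=float(doc.get("age_weight", 1e-7)),
        name=doc.get("name", "custom"),
    )
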