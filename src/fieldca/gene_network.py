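"""Per-cell gene-expression network.

A small two-layer perceptron maps a cell's carcinogen exposure and age to
the maximum possible change in each gene's expression this time-step.
The input is ``X = [c_1, ..., c_C, age]``; the hidden layer is
``H = gamma(WX @ X)`` and the output ``Y = gamma(WY @ H + b)``, where
``gamma(x) = x / (1 + nu * x**2)`` is an odd, bounded activation and the
bias ``b`` saturates the output for genes that are already mutated.  The
realized expression change of gene ``j`` is ``z_j * Y_j`` with
``z_j ~ Uniform(0, 1)``.

Note that ``gamma`` is non-monotone: it peaks at ``x = 1/sqrt(nu)`` with
value ``1/(2 sqrt(nu))`` and decays for larger inputs.  With the default
``nu = 1e6`` the response to an exposure is therefore strongest where the
weighted input is near ``1e-3``, not where it is largest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_panel import GenePanel, build_wx

__all__ = [
    "NetworkParams",
    "NetworkError",
    "activation",
    "activation_bound",
    "draw_age_signs",
    "forward",
    "update_expression",
    "mutation_bias",
]


class NetworkError(ValueError):
    """Raised on dimension mismatches in the gene network."""


@dataclass(frozen=True)
class NetworkParams:
    """Network hyper-parameters.

    nu
        Activation parameter; bounds the per-step expression change.
    beta
        Bias magnitude applied to genes past the mutation threshold.
    bernoulli_p
        Success probability of the per-gene age-sign flips.
    expression_scale
        Global multiplier on the network output.  With the printed
        ``nu`` the pre-mutation drift is of order 1e-6..1e-4 per step;
        the scale lets a run trade biological realism of the printed
        constants for shorter horizons.  The value used in a run is
        recorded in its metadata.
    """

    nu: float = 1e6
    beta: float = 1e-3
    bernoulli_p: float = 0.5
    expression_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("nu must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.bernoulli_p <= 1.0:
            raise ValueError("bernoulli_p must be in [0, 1]")
        if self.expression_scale <= 0:
            raise ValueError("expression_scale must be positive")


def activation(xi, nu: float):
    """Element-wise activation ``gamma(xi) = xi / (1 + nu * xi**2)``.

    Odd and bounded: ``|gamma(xi)| <= 1/(2 sqrt(nu))`` with the maximum
    attained at ``xi = 1/sqrt(nu)``.
    """
    xi = np.asarray(xi, dtype=float)
    out = xi / (1.0 + nu * xi * xi)
    return out if out.ndim else float(out)


def activation_bound(nu: float) -> float:
    """The analytic supremum of ``|activation(., nu)|``."""
    return 1.0 / (2.0 * np.sqrt(nu))


def draw_age_signs(G: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``G`` independent signs ``2 b - 1`` with ``b ~ Bernoulli(p)``."""
    if G < 1:
        raise NetworkError("G must be >= 1")
    return 2 * (rng.random(G) < p).astype(np.int64) - 1


def forward(
    carcinogen_levels: np.ndarray,
    age: float,
    panel: GenePanel,
    bias: np.ndarray,
    params: NetworkParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Run the network for one cell.

    Draws fresh age signs, assembles ``WX``, and returns the vector of
    maximum expression changes ``delta_bar`` (length ``G``), already
    multiplied by ``params.expression_scale``.

    Parameters
    ----------
    carcinogen_levels
        Nonnegative exposure vector of length ``C`` (previous step).
    age
        Cell age in time-steps (previous step).
    bias
        Per-gene bias vector, entries in ``{-beta, 0, +beta}``; see
        :func:`mutation_bias`.
    """
    c = np.asarray(carcinogen_levels, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if c.shape != (panel.C,):
        raise NetworkError(f"expected {panel.C} carcinogen levels, got {c.shape}")
    if bias.shape != (panel.G,):
        raise NetworkError(f"expected bias of length {panel.G}, got {bias.shape}")
    signs = draw_age_signs(panel.G, params.bernoulli_p, rng)
    WX = build_wx(panel, signs)
    X = np.concatenate([c, [float(age)]])
    H = activation(WX @ X, params.nu)
    Y = activation(panel.WY @ H + bias, params.nu)
    return params.expression_scale * Y


def update_expression(
    E: np.ndarray, delta_bar: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Advance expressions by ``z_j * delta_bar_j`` with ``z_j ~ U(0,1)``.

    Returns a new array; the change of each gene is bounded in magnitude
    by ``|delta_bar_j|`` and shares its sign.
    """
    E = np.asarray(E, dtype=float)
    delta_bar = np.asarray(delta_bar, dtype=float)
    z = rng.random(E.shape)
    return E + z * delta_bar


def mutation_bias(E: np.ndarray, M_bar: float, beta: float) -> np.ndarray:
    """Memoryless bias: ``+beta`` where ``e_j >= M_bar``, ``-beta`` where
    ``e_j <= -M_bar``, zero otherwise.

    Once a gene crosses the mutation threshold the bias pushes the
    network output for that gene to (near) its extreme value, so mutated
    genes keep drifting in the direction of their mutation.
    """
    if M_bar <= 0:
        raise ValueError("M_bar must be positive")
    E = np.asarray(E, dtype=float)
    return np.where(E >= M_bar, beta, np.where(E <= -M_bar, -beta, 0.0))
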