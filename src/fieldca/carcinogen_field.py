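"""Spatial carcinogen concentration fields and exposure schedules.

Fields are static in space over a run; a schedule only gates a field on
or off as a function of the time-step.  The built-in shapes are a
Gaussian centered in the domain (``mu = N/2 - 1``, ``sigma = N/15``) and
a uniform level; custom patterns can be loaded from a plain-text array
file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "CarcinogenField",
    "gaussian_field",
    "uniform_field",
    "field_from_file",
    "always_on",
    "window_schedule",
    "never",
    "exposure_at",
    "exposure_grids",
]


class ConfigError(ValueError):
    """Raised for invalid field parameters."""


def always_on(t: int) -> bool:
    return True


def never(t: int) -> bool:
    return False


def window_schedule(windows: Sequence[tuple[int, int]]) -> Callable[[int], bool]:
    """Schedule active on the half-open step intervals ``[start, end)``."""
    windows = [(int(a), int(b)) for a, b in windows]

    def schedule(t: int) -> bool:
        return any(a <= t < b for a, b in windows)

    return schedule


@dataclass
class CarcinogenField:
    """A named carcinogen field: an ``N x N`` concentration grid plus an
    on/off schedule (default: always active)."""

    name: str
    concentration: np.ndarray
    schedule: Callable[[int], bool] = always_on

    def active(self, t: int) -> bool:
        return bool(self.schedule(t))

    @property
    def N(self) -> int:
        return self.concentration.shape[0]


def gaussian_field(N: int) -> np.ndarray:
    """Gaussian concentration centered in the domain.

    ``c(x, y) = exp(-((x - mu)^2 + (y - mu)^2) / (2 sigma^2))`` with
    ``mu = N/2 - 1`` and ``sigma = N/15``; the peak value is 1 at the
    center.  Coordinates are 0-based with ``(x, y) = (column, row)``.
    """
    if N < 2:
        raise ConfigError("grid size must be at least 2")
    mu = N / 2 - 1
    sigma = N / 15
    x = np.arange(N)
    dx2 = (x - mu) ** 2
    return np.exp(-(dx2[None, :] + dx2[:, None]) / (2 * sigma**2))


def uniform_field(N: int, level: float) -> np.ndarray:
    """Constant concentration ``level`` everywhere, ``0 <= level <= 1``."""
    if N < 2:
        raise ConfigError("grid size must be at least 2")
    if not 0.0 <= level <= 1.0:
        raise ConfigError("uniform level must be in [0, 1]")
    return np.full((N, N), float(level))


def field_from_file(path: str | Path) -> np.ndarray:
    """Load a concentration grid from a whitespace-delimited text file."""
    grid = np.loadtxt(path)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ConfigError("field file must contain a square 2-D array")
    if (grid < 0).any():
        raise ConfigError("concentrations must be nonnegative")
    return grid


def exposure_at(
    fields: Sequence[CarcinogenField], x: int, y: int, t: int
) -> np.ndarray:
    """Exposure vector at lattice site ``(x, y)`` at step ``t``.

    Returns one concentration per field, zeroed while the field's
    schedule is inactive.  Never negative.
    """
    return np.array(
        [f.concentration[y, x] if f.active(t) else 0.0 for f in fields]
    )


def exposure_grids(fields: Sequence[CarcinogenField], t: int) -> np.ndarray:
    """Stacked ``(C, N, N)`` exposure grids at step ``t`` (scheduled)."""
    return np.stack(
        [
            f.concentration if f.active(t) else np.zeros_like(f.concentration)
            for f in fields
        ]
    )
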