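"""Stimulus patterns on the input grid.

The stimulus population is laid out on a square grid (``side x side``;
unit index = row * side + col).  Four built-in filled shapes — square,
circle, pentagon, hexagon — all contain exactly the same number of
active units (a quarter of the grid) so that recall metrics are
comparable across stimuli.  The square is the training stimulus; the
novel shapes are displaced from the grid centre by increasing amounts
so their overlap with the square is ordered
circle > pentagon > hexagon.

Partial cues are the lower portion of a shape (by grid row), which
mimics presenting an incomplete view of the same pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "StimulusPattern",
    "make_stimulus",
    "make_cue",
    "pattern_overlap",
    "stimulus_rates",
    "SHAPE_NAMES",
]

SHAPE_NAMES = ("square", "circle", "pentagon", "hexagon")

# centre displacement of each shape, as a fraction of the grid side
_OFFSETS = {
    "square": (0.0, 0.0),
    "circle": (0.15, 0.0),
    "pentagon": (0.18, 0.09),
    "hexagon": (0.20, 0.11),
}


@dataclass(frozen=True)
class StimulusPattern:
    """A named set of active units on the stimulus grid."""

    name: str
    active_units: frozenset = field(default_factory=frozenset)
    grid_side: int = 64
    role: str = "training"        # "training" | "novel" | "cue"

    def __post_init__(self):
        if len(self.active_units) == 0:
            raise ValueError("StimulusPattern must have active units")
        units = np.fromiter(self.active_units, dtype=np.int64)
        if units.min() < 0 or units.max() >= self.grid_side ** 2:
            raise ValueError("active units outside the stimulus grid")

    @property
    def indices(self) -> np.ndarray:
        """Sorted active unit indices."""
        return np.sort(np.fromiter(self.active_units, dtype=np.int64))

    def as_grid(self) -> np.ndarray:
        """0/1 integer image of the pattern (row, col)."""
        img = np.zeros((self.grid_side, self.grid_side), dtype=np.int8)
        idx = self.indices
        img[idx // self.grid_side, idx % self.grid_side] = 1
        return img

    def __len__(self) -> int:
        return len(self.active_units)


def _polygon_radius(theta: np.ndarray, k: int, phase: float) -> np.ndarray:
    """Boundary radius of a regular k-gon with unit circumradius."""
    a = np.mod(theta - phase, 2 * np.pi / k)
    return np.cos(np.pi / k) / np.cos(a - np.pi / k)


def _shape_field(name: str, side: int) -> np.ndarray:
    """Generalized radial distance of every grid cell to the shape centre.

    Ranking cells by this field and keeping the smallest ``n`` yields a
    filled shape of exactly ``n`` units.
    """
    off = _OFFSETS[name]
    cx = side / 2.0 + off[0] * side
    cy = side / 2.0 + off[1] * side
    rows, cols = np.mgrid[0:side, 0:side]
    dx = cols + 0.5 - cx
    dy = rows + 0.5 - cy
    if name == "square":
        return np.maximum(np.abs(dx), np.abs(dy))
    r = np.hypot(dx, dy)
    if name == "circle":
        return r
    theta = np.arctan2(dy, dx)
    k = {"pentagon": 5, "hexagon": 6}[name]
    # flat side down for the hexagon, vertex up for the pentagon
    phase = {"pentagon": -np.pi / 2, "hexagon": np.pi / 6}[name]
    return r / _polygon_radius(theta, k, phase)


def make_stimulus(name: str, grid_side: int = 64,
                  custom_units: Optional[Iterable[int]] = None,
                  role: Optional[str] = None) -> StimulusPattern:
    """Deterministically rasterize a named stimulus.

    Built-in shapes cover one quarter of the grid each.  ``custom``
    patterns take their units from ``custom_units``.
    """
    if name == "custom":
        if custom_units is None:
            raise ValueError("custom stimulus requires custom_units")
        return StimulusPattern("custom", frozenset(int(u) for u in custom_units),
                               grid_side, role or "novel")
    if name not in SHAPE_NAMES:
        raise ValueError(f"unknown stimulus shape: {name!r}")
    n_units = grid_side * grid_side // 4
    fld = _shape_field(name, grid_side)
    rows, cols = np.mgrid[0:grid_side, 0:grid_side]
    # deterministic tie-break on (field, row, col)
    order = np.lexsort((cols.ravel(), rows.ravel(), fld.ravel()))
    chosen = order[:n_units]
    if role is None:
        role = "training" if name == "square" else "novel"
    return StimulusPattern(name, frozenset(int(u) for u in chosen),
                           grid_side, role)


def make_cue(stim: StimulusPattern, cue_fraction: float) -> StimulusPattern:
    """Partial cue: the lower portion of the shape by grid row.

    Contains ``round(cue_fraction * |stim|)`` units drawn from the
    bottom rows of the pattern (ties broken by column).
    """
    if not 0.0 < cue_fraction <= 1.0:
        raise ValueError("cue_fraction must lie in (0, 1]")
    idx = stim.indices
    n = int(round(cue_fraction * len(idx)))
    n = max(n, 1)
    rows = idx // stim.grid_side
    cols = idx % stim.grid_side
    order = np.lexsort((cols, -rows))       # bottom rows first
    chosen = idx[order[:n]]
    return StimulusPattern(f"{stim.name}_cue",
                           frozenset(int(u) for u in chosen),
                           stim.grid_side, "cue")


def pattern_overlap(a: StimulusPattern, b: StimulusPattern) -> float:
    """|a ∩ b| as a fraction of the (training) pattern ``a``."""
    return len(a.active_units & b.active_units) / len(a.active_units)


def stimulus_rates(active: Optional[StimulusPattern], n_stim: int,
                   nu_bg: float, nu_stim: float) -> np.ndarray:
    """Per-stimulus-neuron Poisson rate vector (Hz).

    Members of the active pattern fire at ``nu_stim``; everybody else
    (and everybody, when no pattern is active) fires at ``nu_bg``.
    """
    rates = np.full(n_stim, nu_bg, dtype=np.float64)
    if active is not None:
        idx = active.indices
        if idx.max() >= n_stim:
            raise ValueError("pattern does not fit the stimulus population")
        rates[idx] = nu_stim
    return rates
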