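"""The habitat lattice: suitability mask, occupancy, and neighborhoods.

Space is a ``width`` x ``height`` grid of cells (default 100 x 100) with
absorbing boundaries: positions off the grid simply do not exist, and
seeds proposed there are lost.  A fraction ``phi`` of cells is suitable
for occupancy; each suitable cell holds at most one established plant.
Coordinates are 0-based integer ``(x, y)`` = (column, row).

Distances are Euclidean between cell centers by default; a Chebyshev
variant is available for sensitivity checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["Landscape", "generate_landscape", "cells_within", "upgrade_suitability", "disc_offsets"]


@lru_cache(maxsize=32)
def disc_offsets(radius: float, metric: str = "euclidean") -> np.ndarray:
    """Integer (dx, dy) offsets of all cells within ``radius`` of the origin.

    Includes (0, 0).  Cached: the same disc is reused every generation.
    """
    r = int(np.floor(radius))
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    if metric == "euclidean":
        mask = dx * dx + dy * dy <= radius * radius
    elif metric == "chebyshev":
        mask = np.maximum(np.abs(dx), np.abs(dy)) <= radius
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return np.stack([dx[mask], dy[mask]], axis=1)


class Landscape:
    """Boolean suitability mask plus occupancy over a rectangular lattice."""

    def __init__(self, suitable: np.ndarray):
        suitable = np.asarray(suitable, dtype=bool)
        if suitable.ndim != 2:
            raise ValueError("suitability mask must be 2-D")
        self.suitable = suitable
        self.occupied = np.zeros_like(suitable)

    @property
    def height(self) -> int:
        return self.suitable.shape[0]

    @property
    def width(self) -> int:
        return self.suitable.shape[1]

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())

    @property
    def phi(self) -> float:
        return self.n_suitable / self.suitable.size

    def on_grid(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x >= 0) & (x < self.width) & (y >= 0) & (y < self.height)

    def free_suitable_cells(self) -> np.ndarray:
        """(k, 2) array of (x, y) for suitable, unoccupied cells."""
        ys, xs = np.nonzero(self.suitable & ~self.occupied)
        return np.stack([xs, ys], axis=1)

    # -- plain-text round trip for reproducible fixtures ------------------
    def to_mask_csv(self, path) -> None:
        np.savetxt(path, self.suitable.astype(int), fmt="%d", delimiter=",")

    @classmethod
    def from_mask_csv(cls, path) -> "Landscape":
        return cls(np.loadtxt(path, delimiter=",", dtype=int).astype(bool))


def generate_landscape(width: int, height: int, phi: float, rng: np.random.Generator) -> Landscape:
    """Uniform-random suitability mask with exactly round(phi * cells) suitable cells."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must lie in [0, 1], got {phi}")
    n_cells = width * height
    n_suitable = int(round(phi * n_cells))
    flat = np.zeros(n_cells, dtype=bool)
    flat[rng.choice(n_cells, size=n_suitable, replace=False)] = True
    return Landscape(flat.reshape(height, width))


def upgrade_suitability(landscape: Landscape, phi_new: float, rng: np.random.Generator) -> Landscape:
    """Convert uniformly chosen unsuitable cells to suitable until the fraction is phi_new.

    Existing suitable cells and all occupants are untouched.  Raises if
    ``phi_new`` is below the current fraction (habitat is never removed).
    """
    if not 0.0 <= phi_new <= 1.0:
        raise ValueError(f"phi_new must lie in [0, 1], got {phi_new}")
    target = int(round(phi_new * landscape.suitable.size))
    deficit = target - landscape.n_suitable
    if deficit < 0:
        raise ValueError(
            f"phi_new={phi_new} below current suitable fraction {landscape.phi:.4f}"
        )
    if deficit > 0:
        ys, xs = np.nonzero(~landscape.suitable)
        pick = rng.choice(len(xs), size=deficit, replace=False)
        landscape.suitable[ys[pick], xs[pick]] = True
    return landscape


def cells_within(
    origin: tuple[int, int],
    radius: float,
    landscape: Landscape,
    include_origin: bool = False,
    metric: str = "euclidean",
) -> np.ndarray:
    """On-grid cells within ``radius`` of ``origin`` (center-to-center distance).

    ``include_origin=False`` is the pollen-donor search convention (a
    plant is not its own neighbor); ``include_origin=True`` is the seed
    dispersal convention.  Off-grid positions are clipped away
    (absorbing boundary).  Returns an (k, 2) array of (x, y).
    """
    x0, y0 = origin
    if not landscape.on_grid(np.array(x0), np.array(y0)):
        raise ValueError(f"origin {origin} is off-grid")
    offs = disc_offsets(radius, metric)
    xs = x0 + offs[:, 0]
    ys = y0 + offs[:, 1]
    keep = landscape.on_grid(xs, ys)
    if not include_origin:
        keep &= ~((xs == x0) & (ys == y0))
    return np.stack([xs[keep], ys[keep]], axis=1)
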