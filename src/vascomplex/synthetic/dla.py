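"""On-lattice diffusion-limited aggregation (DLA).

Particles launched from a circle around the cluster perform lattice
random walks and freeze on first contact with the aggregate, producing
the classic branched statistical fractal.  Growth stops when the cluster
radius reaches a stated fraction of the smaller half-extent of the grid
(so the cluster never touches the boundary) or when the particle budget
is exhausted.

Two standard accelerations keep the walk exact but fast: walkers far
outside the launch circle jump inward along a circle of radius equal to
their slack distance (a random walk exiting a circle is equally likely
to cross it anywhere), and walkers beyond the kill radius are relaunched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["DLAConfig", "generate_dla", "generate_dla_geometry"]


@dataclass(frozen=True)
class DLAConfig:
    """Parameters of a lattice DLA growth run.

    ``sticking`` is the adjacency used for freezing contact (4 or 8);
    ``stop_fraction`` stops growth once the cluster radius reaches that
    fraction of the smaller half-extent.
    """

    height: int = 512
    width: int = 512
    seed_pos: tuple[int, int] | None = None  # default: grid center
    budget: int = 200_000
    stop_fraction: float = 0.45
    launch_margin: float = 5.0
    kill_factor: float = 3.0
    sticking: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.budget < 1:
            raise ValueError("budget must be >= 1")
        if not 0.0 < self.stop_fraction < 0.5:
            raise ValueError("stop_fraction must lie in (0, 0.5)")
        if self.sticking not in (4, 8):
            raise ValueError("sticking adjacency must be 4 or 8")
        cy, cx = self._seed()
        if not (0 <= cy < self.height and 0 <= cx < self.width):
            raise ValueError("seed position outside grid")

    def _seed(self) -> tuple[int, int]:
        if self.seed_pos is None:
            return self.height // 2, self.width // 2
        return self.seed_pos


@njit(cache=True)
def _grow(grid, cy, cx, budget, stop_radius, launch_margin, kill_factor, eight, seed):
    np.random.seed(seed)
    h, w = grid.shape
    grid[cy, cx] = 1
    rmax = 0.0
    frozen = 1
    for _ in range(budget - 1):  # budget counts frozen particles incl. the seed
        if rmax >= stop_radius:
            break
        launch_r = rmax + launch_margin
        kill_r = kill_factor * launch_r

        theta = np.random.random() * 2.0 * np.pi
        y = cy + launch_r * np.sin(theta)
        x = cx + launch_r * np.cos(theta)
        while True:
            dy = y - cy
            dx = x - cx
            d = np.sqrt(dy * dy + dx * dx)
            if d > kill_r:
                theta = np.random.random() * 2.0 * np.pi
                y = cy + launch_r * np.sin(theta)
                x = cx + launch_r * np.cos(theta)
                continue
            if d > launch_r + 2.0:
                # jump inward: step by the slack distance in a random direction
                step = d - launch_r - 1.0
                phi = np.random.random() * 2.0 * np.pi
                y += step * np.sin(phi)
                x += step * np.cos(phi)
                continue

            iy = int(np.floor(y + 0.5))
            ix = int(np.floor(x + 0.5))
            if iy < 1 or iy >= h - 1 or ix < 1 or ix >= w - 1 or grid[iy, ix] == 1:
                # out of play: relaunch
                theta = np.random.random() * 2.0 * np.pi
                y = cy + launch_r * np.sin(theta)
                x = cx + launch_r * np.cos(theta)
                continue

            # contact check at the current lattice site
            touch = (
                grid[iy - 1, ix] == 1
                or grid[iy + 1, ix] == 1
                or grid[iy, ix - 1] == 1
                or grid[iy, ix + 1] == 1
            )
            if not touch and eight:
                touch = (
                    grid[iy - 1, ix - 1] == 1
                    or grid[iy - 1, ix + 1] == 1
                    or grid[iy + 1, ix - 1] == 1
                    or grid[iy + 1, ix + 1] == 1
                )
            if touch:
                grid[iy, ix] = 1
                frozen += 1
                dd = np.sqrt((iy - cy) ** 2 + (ix - cx) ** 2)
                if dd > rmax:
                    rmax = dd
                break

            # one lattice step
            r4 = np.random.randint(0, 4)
            if r4 == 0:
                y = iy - 1.0
                x = float(ix)
            elif r4 == 1:
                y = iy + 1.0
                x = float(ix)
            elif r4 == 2:
                y = float(iy)
                x = ix - 1.0
            else:
                y = float(iy)
                x = ix + 1.0
    return frozen


def generate_dla(config: DLAConfig | None = None, **overrides) -> np.ndarray:
    """Grow a DLA cluster; returns a (H, W) uint8 binary image.

    Deterministic for a fixed ``rng_seed``.  ``overrides`` are applied
    on top of ``config`` (or the defaults) for convenience.
    """
    if config is None:
        config = DLAConfig(**overrides)
    elif overrides:
        from dataclasses import replace

        config = replace(config, **overrides)
    grid = np.zeros((config.height, config.width), dtype=np.uint8)
    cy, cx = config._seed()
    # radius threshold: a fraction of the smaller half-extent, so the
    # default 0.45 leaves a wide empty margin around the cluster
    stop_radius = config.stop_fraction * (min(config.height, config.width) / 2.0)
    _grow(
        grid,
        cy,
        cx,
        config.budget,
        stop_radius,
        config.launch_margin,
        config.kill_factor,
        1 if config.sticking == 8 else 0,
        config.rng_seed % (2**31),
    )
    return grid


def generate_dla_geometry(geometry: str, rng_seed: int, **overrides) -> np.ndarray:
    """DLA raster for one of the study geometries.

    ``"512x512"`` grows directly on a 512x512 grid.  ``"364x436"`` (the
    in-vivo matrix, width x height) grows on 436x436 and center-crops
    the width to 364, so the same cluster morphology populates both
    geometries and only the matrix size differs.
    """
    if geometry == "512x512":
        return generate_dla(DLAConfig(height=512, width=512, rng_seed=rng_seed, **overrides))
    if geometry == "364x436":
        img = generate_dla(DLAConfig(height=436, width=436, rng_seed=rng_seed, **overrides))
        lo = (436 - 364) // 2
        return img[:, lo : lo + 364].copy()
    raise ValueError(f"unknown geometry {geometry!r}; use '512x512' or '364x436'")
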