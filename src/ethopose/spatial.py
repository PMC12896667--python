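"""Enclosure-use heat maps from 15-second tracking points.

Spatial use is summarised by binning blueprint coordinates of the
tracking points into a regular grid, smoothing the histogram with a
Gaussian kernel, and normalising to unit mass, so each cell holds the
fraction of recorded positions attributable to it.  Period-difference
maps subtract two normalised grids and therefore sum to zero; positive
cells mark areas used more in the first period.

A histogram-plus-smoothing estimator (rather than a full kernel density
estimate) keeps mass control exact and is fast at any point count; the
reflect boundary rule conserves mass at the enclosure walls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

DEFAULT_GRID = (64, 36)  # cells across a 1920x1080 blueprint -> 30 px cells


@dataclass
class HeatmapGrid:
    """Normalised 2-D density of tracking points on the blueprint.

    ``values`` has shape (ny, nx), rows indexing y (top to bottom, the
    image convention), and sums to 1.
    """

    width: float
    height: float
    nx: int
    ny: int
    values: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.ny, self.nx):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with grid {(self.ny, self.nx)}"
            )

    @property
    def cell_size(self) -> tuple[float, float]:
        return self.width / self.nx, self.height / self.ny

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cw, ch = self.cell_size
        xs = (np.arange(self.nx) + 0.5) * cw
        ys = (np.arange(self.ny) + 0.5) * ch
        return xs, ys

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values).to_csv(path, index=False, header=False)


def sample_points(
    positions: pd.DataFrame, interval_s: int = 15, origin_s: int | None = None
) -> pd.DataFrame:
    """One tracking point per interval start at which the animal is visible.

    ``positions`` has one row per second the animal was visible, with
    columns ``time_s, x, y`` (plus optional ``individual``/``period``
    passed through).  Points are taken at ``origin_s, origin_s +
    interval_s, ...`` (origin defaults to the first observed second);
    invisible interval starts are skipped, never interpolated.
    """
    if interval_s < 1:
        raise ValueError("interval_s must be >= 1")
    if len(positions) == 0:
        return positions.copy()
    t = positions["time_s"].astype(int)
    start = int(t.min()) if origin_s is None else int(origin_s)
    keep = (t >= start) & ((t - start) % interval_s == 0)
    return positions.loc[keep.to_numpy()].reset_index(drop=True)


def heatmap(
    points: pd.DataFrame,
    width: float = 1920.0,
    height: float = 1080.0,
    nx: int = DEFAULT_GRID[0],
    ny: int = DEFAULT_GRID[1],
    sigma_px: float | None = None,
) -> HeatmapGrid:
    """Smoothed, normalised density grid of tracking points.

    ``sigma_px`` is the Gaussian smoothing bandwidth in blueprint
    pixels (default: 2 cell widths); out-of-range points are clipped to
    the edge cells.  Raises ``ValueError`` on an empty point set — an
    all-zero map cannot be normalised and would be misleading.
    """
    x = np.asarray(points["x"], dtype=float)
    y = np.asarray(points["y"], dtype=float)
    if len(x) == 0:
        raise ValueError("cannot build a heat map from zero points")
    cw, ch = width / nx, height / ny
    if sigma_px is None:
        sigma_px = 2.0 * cw
    eps = 1e-9
    x = np.clip(x, 0.0, width - eps)
    y = np.clip(y, 0.0, height - eps)
    hist, _, _ = np.histogram2d(
        y, x, bins=(ny, nx), range=((0.0, height), (0.0, width))
    )
    if sigma_px > 0:
        # reflect boundaries conserve total mass under a symmetric kernel
        hist = gaussian_filter(hist, sigma=(sigma_px / ch, sigma_px / cw), mode="reflect")
    values = hist / hist.sum()
    return HeatmapGrid(
        width=width, height=height, nx=nx, ny=ny, values=values, n_points=len(x)
    )


def difference_map(a: HeatmapGrid, b: HeatmapGrid) -> np.ndarray:
    """Signed cell-wise difference of two normalised grids (sums to ~0).

    Positive cells were denser in ``a``; antisymmetric in its arguments.
    """
    if (a.nx, a.ny, a.width, a.height) != (b.nx, b.ny, b.width, b.height):
        raise ValueError("difference_map requires identical grid specifications")
    return a.values / a.values.sum() - b.values / b.values.sum()


def peak_location(values: np.ndarray, grid: HeatmapGrid) -> tuple[float, float]:
    """Blueprint (x, y) of the maximum cell's center."""
    iy, ix = np.unravel_index(int(np.argmax(values)), values.shape)
    xs, ys = grid.cell_centers()
    return float(xs[ix]), float(ys[iy])


def render_heatmap(
    values: np.ndarray,
    grid: HeatmapGrid,
    path: str | Path,
    diverging: bool = False,
    title: str = "",
) -> None:
    """Render a density or difference grid to PNG.

    Densities use a low-to-high blue-to-red ramp; difference maps a
    diverging palette centered at zero.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.2))
    if diverging:
        vmax = float(np.abs(values).max()) or 1.0
        im = ax.imshow(
            values, cmap="coolwarm", vmin=-vmax, vmax=vmax,
            extent=(0, grid.width, grid.height, 0), aspect="equal",
        )
    else:
        im = ax.imshow(
            values, cmap="turbo",
            extent=(0, grid.width, grid.height, 0), aspect="equal",
        )
    ax.set_xlabel("x (blueprint px)")
    ax.set_ylabel("y (blueprint px)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8, label="density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
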