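"""Core data containers for uniformly sampled series and spatio-temporal fields.

Missing values are represented as NaN throughout; a value is "valid" iff it is
finite. Times are floats in arbitrary (but consistent) units — the synthetic
models use years for the 1D systems and days for the spatial systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class UniformSeries:
    """A uniformly sampled scalar time series with NaN-coded missing values."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1D arrays of equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
                raise ValueError("sampling is not uniform")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need at least two samples to define a step")
        return float(self.times[1] - self.times[0])

    @property
    def mask(self) -> np.ndarray:
        """Boolean validity mask (True where the value is finite)."""
        return np.isfinite(self.values)

    def __len__(self) -> int:
        return len(self.times)

    def copy(self) -> "UniformSeries":
        return UniformSeries(self.times.copy(), self.values.copy())


@dataclass
class SpatioTemporalField:
    """Flattened spatial snapshots: ``data`` has shape (n_space, n_time).

    ``grid_shape`` records the (ny, nx) geometry; ``valid_cells`` flags grid
    cells that carry data (rows of ``data`` correspond to valid cells in
    row-major order).
    """

    times: np.ndarray
    data: np.ndarray
    grid_shape: tuple[int, int]
    valid_cells: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        ny, nx = self.grid_shape
        if self.valid_cells is None:
            self.valid_cells = np.ones((ny, nx), dtype=bool)
        self.valid_cells = np.asarray(self.valid_cells, dtype=bool)
        if self.valid_cells.shape != (ny, nx):
            raise ValueError("valid_cells shape must match grid_shape")
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (n_space, n_time)")
        if self.data.shape[0] != int(self.valid_cells.sum()):
            raise ValueError("data row count must equal number of valid cells")
        if self.data.shape[1] != len(self.times):
            raise ValueError("data column count must equal number of times")

    @property
    def n_space(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need at least two snapshots to define a step")
        return float(self.times[1] - self.times[0])

    @classmethod
    def from_cube(
        cls,
        times: np.ndarray,
        cube: np.ndarray,
        valid_cells: np.ndarray | None = None,
    ) -> "SpatioTemporalField":
        """Build from a (n_time, ny, nx) cube, flattening valid cells row-major."""
        cube = np.asarray(cube, dtype=float)
        nt, ny, nx = cube.shape
        if valid_cells is None:
            valid_cells = np.ones((ny, nx), dtype=bool)
        flat = cube.reshape(nt, ny * nx)[:, np.asarray(valid_cells, bool).ravel()]
        return cls(np.asarray(times, float), flat.T, (ny, nx), valid_cells)

    def to_cube(self) -> np.ndarray:
        """Return a (n_time, ny, nx) cube with NaN outside valid cells."""
        ny, nx = self.grid_shape
        cube = np.full((self.n_time, ny * nx), np.nan)
        cube[:, self.valid_cells.ravel()] = self.data.T
        return cube.reshape(self.n_time, ny, nx)

    def domain_mean(self) -> UniformSeries:
        """Spatial mean over valid cells at each snapshot."""
        with np.errstate(all="ignore"):
            m = np.nanmean(self.data, axis=0)
        return UniformSeries(self.times, m)

    def map_to_grid(self, row_values: np.ndarray) -> np.ndarray:
        """Scatter a length-n_space vector back onto the (ny, nx) grid (NaN elsewhere)."""
        row_values = np.asarray(row_values)
        ny, nx = self.grid_shape
        out = np.full(ny * nx, np.nan, dtype=row_values.dtype if
                      np.issubdtype(row_values.dtype, np.floating) else float)
        out[self.valid_cells.ravel()] = row_values
        return out.reshape(ny, nx)

    def copy(self) -> "SpatioTemporalField":
        return SpatioTemporalField(
            self.times.copy(), self.data.copy(), self.grid_shape, self.valid_cells.copy()
        )
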