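"""Fixed wavelength grid shared by every stage of the pipeline.

All spectra live on an integer-nanometre grid from 400 to 1710 nm
inclusive (1311 points, 1 nm step). The grid is fixed once; every
container and transform validates against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class WavelengthGrid:
    """Regular wavelength grid in nanometres."""

    start: float = 400.0
    stop: float = 1710.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0 or self.stop <= self.start:
            raise ValueError("grid must be strictly increasing")
        n = (self.stop - self.start) / self.step + 1
        if abs(n - round(n)) > 1e-9:
            raise ValueError("step must divide the wavelength span")

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    def validate(self, values: np.ndarray) -> np.ndarray:
        """Return ``values`` as a float array after checking grid length."""
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or arr.size != self.n_points:
            raise ValueError(
                f"expected {self.n_points} grid points, got shape {arr.shape}"
            )
        return arr


#: The instrument grid: 400-1710 nm at 1 nm resolution, 1311 samples.
DEFAULT_GRID = WavelengthGrid()
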