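"""Chromophore absorption library.

Absorption-coefficient tables (cm^-1 at reference concentration) for the
six tissue chromophores the inverse model unmixes: deoxygenated and
oxygenated hemoglobin, beta-carotene, fat (lipid), water and collagen.
The blood reference is whole blood at 150 g hemoglobin per litre, i.e. a
``blood_fraction`` of 1.0 means 100 % blood.

The shipped tables are SYNTHETIC band models: smooth sums of Gaussian
bands placed at the well-established absorption features of each
chromophore (hemoglobin Soret and Q bands; water overtones at 970, 1190
and 1450 nm; lipid CH overtones at 930, 1210 and 1725 nm; the carotenoid
band near 460 nm; collagen NIR bands), with magnitudes on the scale of
the published compilations. They are not digitised literature curves.
Because the forward model and the inverse fit share one library, every
round-trip and recovery guarantee in this package is independent of that
substitution; only the absolute physiological scale of fitted
concentrations on real instrument data would be affected.

``data/manifest.json`` records the library version, units and synthetic
provenance; tests pin the version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .grid import DEFAULT_GRID, WavelengthGrid

CHROMOPHORES = ("hb", "hbo2", "beta_carotene", "fat", "water", "collagen")

#: grams of hemoglobin per litre of whole blood at blood_fraction = 1.0
BLOOD_REFERENCE_G_PER_L = 150.0


def _gauss(wl: np.ndarray, centre: float, amplitude: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


def band_model(name: str, wl: np.ndarray) -> np.ndarray:
    """Synthetic absorption band model for one chromophore, cm^-1.

    These functions generated the shipped CSV tables and are kept so the
    tables can be regenerated from source.
    """
    wl = np.asarray(wl, dtype=float)
    if name == "hbo2":
        # whole blood, 150 g Hb/L: Soret ~414 nm, Q bands 542/576 nm,
        # shallow NIR rise toward the 900-1000 nm hump
        return (
            _gauss(wl, 414, 2600, 16)
            + _gauss(wl, 542, 290, 12)
            + _gauss(wl, 576, 310, 10)
            + _gauss(wl, 950, 5.5, 120)
            + 1.2
        )
    if name == "hb":
        # deoxygenated: Soret ~432 nm, single Q band 556 nm, 760 nm band
        return (
            _gauss(wl, 432, 2200, 18)
            + _gauss(wl, 556, 280, 16)
            + _gauss(wl, 760, 7.5, 28)
            + _gauss(wl, 910, 4.0, 100)
            + 1.5
        )
    if name == "beta_carotene":
        # carotenoid pi-conjugation band, vibronic structure 420-500 nm;
        # reference unit chosen so a value of 1.0 is a high adipose level
        return (
            _gauss(wl, 462, 22, 28)
            + _gauss(wl, 488, 15, 22)
            + _gauss(wl, 434, 12, 22)
            + _gauss(wl, 350, 8, 60)  # UV tail
        )
    if name == "fat":
        # pure lipid: CH overtones
        return (
            _gauss(wl, 930, 0.13, 25)
            + _gauss(wl, 1040, 0.06, 30)
            + _gauss(wl, 1210, 0.55, 35)
            + _gauss(wl, 1392, 0.22, 30)
            + _gauss(wl, 1725, 7.0, 48)
            + 0.005
        )
    if name == "water":
        # pure water: OH overtones, steep rise into the 1450 nm band
        return (
            _gauss(wl, 970, 0.45, 35)
            + _gauss(wl, 1190, 1.0, 48)
            + _gauss(wl, 1450, 29.0, 56)
            + _gauss(wl, 1930, 120.0, 90)
            + 0.002
        )
    if name == "collagen":
        # dry collagen: broad NIR features, small visible baseline
        return (
            _gauss(wl, 1200, 0.55, 60)
            + _gauss(wl, 1510, 1.6, 80)
            + _gauss(wl, 1700, 2.5, 60)
            + 0.12
        )
    raise KeyError(f"unknown chromophore {name!r}")


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Immutable per-chromophore absorption tables on the pipeline grid."""

    tables: dict[str, np.ndarray]
    version: str
    grid: WavelengthGrid = field(default=DEFAULT_GRID)

    def __post_init__(self) -> None:
        for name in CHROMOPHORES:
            if name not in self.tables:
                raise ValueError(f"library missing chromophore {name!r}")
            tab = self.grid.validate(self.tables[name])
            if np.any(tab < 0) or not np.all(np.isfinite(tab)):
                raise ValueError(f"table {name!r} must be finite and non-negative")
            tab.flags.writeable = False
            self.tables[name] = tab

    def __getitem__(self, name: str) -> np.ndarray:
        return self.tables[name]


def load_default_library(grid: WavelengthGrid = DEFAULT_GRID) -> ChromophoreLibrary:
    """Load the packaged synthetic tables, interpolated once to the grid."""
    pkg = resources.files("nervespec") / "data"
    manifest = json.loads((pkg / "manifest.json").read_text())
    tables = {}
    for name in CHROMOPHORES:
        fname = manifest["files"][name]
        raw = np.loadtxt(str(pkg / fname), delimiter=",", skiprows=1)
        wl, coef = raw[:, 0], raw[:, 1]
        tables[name] = np.interp(grid.wavelengths, wl, coef)
    return ChromophoreLibrary(tables=tables, version=manifest["version"], grid=grid)
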