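"""Inverse spectral model: bounded nonlinear least squares of the
diffusion forward model against a measured spectrum.

The interface follows the Model/Results convention of statistical
modelling packages: build a :class:`DiffuseReflectanceModel` from a
spectrum (or a dataset row), call :meth:`fit`, and read estimates,
diagnostics and a ``summary()`` table off the returned
:class:`DiffuseReflectanceResults`.

The optimiser is a trust-region reflective least-squares solve over the
12-parameter vector. Nuisance parameters (calibration amplitude/offset,
vessel diameter) are bounded tightly so they cannot absorb
physiological contrast, and any of them can be frozen via
:class:`FitConfig`. Residuals are unweighted by default; relative
(divide-by-model) weighting is available as a config option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .chromophores import ChromophoreLibrary, load_default_library
from .grid import DEFAULT_GRID, WavelengthGrid
from .optics import (
    NUISANCE_PARAMS,
    ProbeGeometry,
    TissueOpticalParams,
    forward_spectrum,
)
from .spectra import SpectraDataset, Spectrum

logger = logging.getLogger(__name__)

#: Missing marker for derived fractions whose denominator is zero.
UNDEFINED = float("nan")

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "blood_fraction": (0.0, 0.2),
    "sto2": (0.0, 1.0),
    "beta_carotene": (0.0, 2.0),
    "fat_fraction": (0.0, 1.0),
    "water_fraction": (0.0, 1.0),
    "collagen_fraction": (0.0, 1.0),
    "s800": (1.0, 40.0),
    "mie_slope": (0.0, 4.0),
    "f_mie": (0.0, 1.0),
    # nuisance: tight so they cannot soak up physiological contrast
    "vessel_diameter_mm": (0.0, 1.0),
    "amplitude": (0.9, 1.1),
    "offset": (-1e-3, 1e-3),
}

_DEFAULT_START = TissueOpticalParams(
    blood_fraction=0.01, sto2=0.6, beta_carotene=0.4, fat_fraction=0.3,
    water_fraction=0.4, collagen_fraction=0.15, s800=10.0, mie_slope=0.8,
    f_mie=0.7, vessel_diameter_mm=0.1, amplitude=1.0, offset=0.0,
)

#: characteristic scales used by the trust-region solver
_X_SCALE = {
    "blood_fraction": 0.01, "sto2": 0.3, "beta_carotene": 0.3,
    "fat_fraction": 0.3, "water_fraction": 0.3, "collagen_fraction": 0.1,
    "s800": 5.0, "mie_slope": 0.5, "f_mie": 0.3,
    "vessel_diameter_mm": 0.05, "amplitude": 0.05, "offset": 5e-4,
}


@dataclass
class FitConfig:
    """Controls for the bounded least-squares solve."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS))
    start: TissueOpticalParams = field(default_factory=lambda: _DEFAULT_START)
    frozen: dict[str, float] = field(default_factory=dict)
    relative_weighting: bool = False
    tol: float = 1e-12
    max_iterations: int = 500
    multi_start: int = 0          # extra random restarts beyond the fixed start
    restart_seed: int = 12345


def derived_fractions(params: TissueOpticalParams) -> tuple[float, float]:
    """(StO2, fat-to-water fraction F/(W+F)).

    StO2 is carried directly as a fit parameter but becomes undefined
    (NaN) when there is no blood at all; F/(W+F) is undefined when fat
    and water are both zero. Undefined is a missing marker, never 0 or 1.
    """
    sto2 = params.sto2 if params.blood_fraction > 0 else UNDEFINED
    fw = params.fat_fraction + params.water_fraction
    fat_to_water = params.fat_fraction / fw if fw > 0 else UNDEFINED
    return sto2, fat_to_water


class DiffuseReflectanceModel:
    """Forward/inverse diffusion-reflectance model for one spectrum.

    Parameters
    ----------
    spectrum : array or Spectrum
        Calibrated reflectance on the 1311-point grid.
    geom, lib, grid
        Probe geometry, chromophore library and wavelength grid; defaults
        are the packaged ones.
    """

    def __init__(self, spectrum, geom: ProbeGeometry | None = None,
                 lib: ChromophoreLibrary | None = None,
                 grid: WavelengthGrid = DEFAULT_GRID):
        if isinstance(spectrum, Spectrum):
            self.endog = spectrum.intensities
            self.location_id = spectrum.location_id
        else:
            self.endog = grid.validate(spectrum)
            self.location_id = None
        if np.all(self.endog == 0):
            raise ValueError("all-zero spectrum cannot be fitted")
        self.geom = geom or ProbeGeometry()
        self.lib = lib or load_default_library(grid)
        self.grid = grid

    @classmethod
    def from_dataset(cls, dataset: SpectraDataset, location_id: str,
                     **kw) -> "DiffuseReflectanceModel":
        for s in dataset:
            if s.location_id == location_id:
                return cls(s, grid=dataset.grid, **kw)
        raise KeyError(f"no spectrum with location_id {location_id!r}")

    # -- solve ---------------------------------------------------------

    def _residuals(self, x_free: np.ndarray, free_names: list[str],
                   fixed: dict[str, float]) -> np.ndarray:
        values = dict(fixed)
        values.update(zip(free_names, x_free))
        params = TissueOpticalParams(**values)
        model = forward_spectrum(params, self.geom, self.lib, self.grid)
        res = model - self.endog
        return res / np.maximum(model, 1e-12) if self._relative else res

    def fit(self, config: FitConfig | None = None) -> "DiffuseReflectanceResults":
        """Bounded trust-region least squares; never raises on
        non-convergence — the result carries a ``converged`` flag."""
        config = config or FitConfig()
        self._relative = config.relative_weighting
        all_names = list(TissueOpticalParams.names())
        fixed = dict(config.frozen)
        free_names = [n for n in all_names if n not in fixed]
        lo = np.array([config.bounds[n][0] for n in free_names])
        hi = np.array([config.bounds[n][1] for n in free_names])
        scale = np.array([_X_SCALE[n] for n in free_names])

        def solve(x0):
            x0 = np.clip(x0, lo, hi)
            return least_squares(
                self._residuals, x0, bounds=(lo, hi),
                args=(free_names, fixed), method="trf", x_scale=scale,
                ftol=config.tol, xtol=config.tol, gtol=config.tol,
                max_nfev=config.max_iterations * (len(free_names) + 1),
            )

        start = np.array([getattr(config.start, n) for n in free_names])
        best = solve(start)
        if config.multi_start > 0:
            rng = np.random.default_rng(config.restart_seed)
            for _ in range(config.multi_start):
                x0 = lo + (hi - lo) * rng.random(len(free_names))
                sol = solve(x0)
                if sol.cost < best.cost:
                    best = sol
        values = dict(fixed)
        values.update(zip(free_names, best.x))
        params = TissueOpticalParams(**values)
        converged = best.status > 0
        if not converged:
            logger.warning("fit did not converge (%s): %s",
                           self.location_id, best.message)
        return DiffuseReflectanceResults(
            model=self, params=params,
            residual_norm=float(np.sqrt(2.0 * best.cost)),
            n_iterations=int(best.nfev), converged=converged,
            config=config,
        )


@dataclass
class DiffuseReflectanceResults:
    """Estimates and diagnostics from one inverse solve."""

    model: DiffuseReflectanceModel
    params: TissueOpticalParams
    residual_norm: float
    n_iterations: int
    converged: bool
    config: FitConfig

    @property
    def sto2(self) -> float:
        return derived_fractions(self.params)[0]

    @property
    def fat_to_water(self) -> float:
        return derived_fractions(self.params)[1]

    def fittedvalues(self) -> np.ndarray:
        return forward_spectrum(self.params, self.model.geom,
                                self.model.lib, self.model.grid)

    def resid(self) -> np.ndarray:
        return self.fittedvalues() - self.model.endog

    def to_row(self) -> dict:
        row = dict(zip(self.params.names(), self.params.to_array()))
        row["sto2_derived"] = self.sto2
        row["fat_to_water"] = self.fat_to_water
        row["residual_norm"] = self.residual_norm
        row["converged"] = self.converged
        return row

    def summary(self) -> str:
        lines = ["Diffuse reflectance fit", "=" * 44]
        if self.model.location_id:
            lines.append(f"location:       {self.model.location_id}")
        lines += [
            f"converged:      {self.converged}",
            f"residual norm:  {self.residual_norm:.4e}",
            f"fn evals:       {self.n_iterations}",
            "-" * 44,
        ]
        for name in self.params.names():
            tag = " (nuisance)" if name in NUISANCE_PARAMS else ""
            lines.append(f"{name:20s} {getattr(self.params, name):12.6g}{tag}")
        lines.append("-" * 44)
        lines.append(f"{'StO2 (derived)':20s} {self.sto2:12.6g}")
        lines.append(f"{'F/(W+F)':20s} {self.fat_to_water:12.6g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Measured vs fitted spectrum."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        wl = self.model.grid.wavelengths
        ax.plot(wl, self.model.endog, label="measured", lw=0.8)
        ax.plot(wl, self.fittedvalues(), label="fit", lw=0.8)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("calibrated reflectance")
        ax.legend()
        return ax


def fit_spectrum(spectrum, lib: ChromophoreLibrary | None = None,
                 geom: ProbeGeometry | None = None,
                 config: FitConfig | None = None,
                 grid: WavelengthGrid = DEFAULT_GRID) -> DiffuseReflectanceResults:
    """Functional wrapper: fit one spectrum, return the results object."""
    return DiffuseReflectanceModel(spectrum, geom=geom, lib=lib, grid=grid).fit(config)


def fit_dataset(dataset: SpectraDataset, lib: ChromophoreLibrary | None = None,
                geom: ProbeGeometry | None = None,
                config: FitConfig | None = None) -> pd.DataFrame:
    """Fit every spectrum; returns a table keyed by location_id.

    Individual failures are recorded (converged=False / error logged),
    never abort the batch. Results do not depend on dataset order.
    """
    lib = lib or load_default_library(dataset.grid)
    geom = geom or ProbeGeometry()
    rows = {}
    for i, spec in enumerate(dataset):
        try:
            res = DiffuseReflectanceModel(spec, geom=geom, lib=lib,
                                          grid=dataset.grid).fit(config)
            rows[spec.location_id] = res.to_row()
        except Exception as exc:  # pragma: no cover - defensive batch guard
            logger.error("fit failed for %s: %s", spec.location_id, exc)
            rows[spec.location_id] = {"converged": False, "error": str(exc)}
        if (i + 1) % 50 == 0:
            logger.info("fitted %d / %d spectra", i + 1, len(dataset))
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "location_id"
    return df
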