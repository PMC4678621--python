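"""Calibrated spectra: data model, calibration arithmetic, replicate
averaging and dataset (de)serialisation.

A raw measurement is calibrated against a background and a white
reflectance standard as ``(S - B) / (W - B)``; the background is
subtracted from the white response as well, which is the standard
integrating-probe convention. Typically ~10 replicate spectra per needle
location are averaged into one data point.

Datasets are stored as plain CSV: one row per averaged location with
``specimen_id,area,tissue_class,location_id,w400,...,w1710`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DEFAULT_GRID, WavelengthGrid

logger = logging.getLogger(__name__)

AREAS = ("cervical", "forearm")
TISSUE_CLASSES = ("fascicular_nerve", "muscle", "sliding_fat", "subcutaneous_fat")
#: The class the classifiers must detect ("positive" in every confusion matrix).
POSITIVE_CLASS = "fascicular_nerve"


class CalibrationError(ValueError):
    """White-minus-background is non-positive somewhere on the grid."""


@dataclass
class Spectrum:
    """One calibrated reflectance curve plus provenance metadata."""

    intensities: np.ndarray
    specimen_id: str
    area: str
    tissue_class: str
    location_id: str
    grid: WavelengthGrid = field(default=DEFAULT_GRID, repr=False)
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.intensities = self.grid.validate(self.intensities)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError(f"non-finite intensities in {self.location_id!r}")
        if self.area not in AREAS:
            raise ValueError(f"unknown area {self.area!r}; expected one of {AREAS}")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"unknown tissue class {self.tissue_class!r}; "
                f"expected one of {TISSUE_CLASSES}"
            )

    @property
    def is_positive(self) -> bool:
        return self.tissue_class == POSITIVE_CLASS


def calibrate(
    raw: np.ndarray,
    background: np.ndarray,
    white_reference: np.ndarray,
    grid: WavelengthGrid = DEFAULT_GRID,
    clip_negative: bool = True,
) -> np.ndarray:
    """Calibrate raw counts to dimensionless reflectance.

    Computes ``(raw - background) / (white_reference - background)``
    elementwise. Negative calibrated values (detector noise around zero
    signal) are clipped to 0; spectra with more than 1 % clipped points
    are logged as suspect.

    Raises
    ------
    CalibrationError
        If the white-minus-background denominator is non-positive
        anywhere; the message names the offending wavelength range.
    """
    raw = grid.validate(raw)
    background = grid.validate(background)
    white_reference = grid.validate(white_reference)
    denom = white_reference - background
    bad = denom <= 0
    if np.any(bad):
        wl = grid.wavelengths[bad]
        raise CalibrationError(
            "white reference does not exceed background between "
            f"{wl.min():.0f} and {wl.max():.0f} nm ({bad.sum()} points)"
        )
    out = (raw - background) / denom
    if clip_negative:
        neg = out < 0
        if np.any(neg):
            frac = neg.mean()
            level = logging.WARNING if frac > 0.01 else logging.DEBUG
            logger.log(level, "clipped %.2f%% negative calibrated points", 100 * frac)
            out = np.where(neg, 0.0, out)
    return out


def average_replicates(replicates: list[np.ndarray] | np.ndarray,
                       grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """Pointwise arithmetic mean of replicate calibrated spectra."""
    reps = list(replicates)
    if len(reps) == 0:
        raise ValueError("need at least one replicate")
    stacked = np.vstack([grid.validate(r) for r in reps])
    return stacked.mean(axis=0)


@dataclass
class SpectraDataset:
    """Labelled collection of spectra; the unit of cross-validation is
    the specimen, so grouping metadata is first-class here."""

    spectra: list[Spectrum]
    grid: WavelengthGrid = field(default=DEFAULT_GRID, repr=False)

    def __post_init__(self) -> None:
        for s in self.spectra:
            if s.grid != self.grid:
                raise ValueError(f"grid mismatch for {s.location_id!r}")
        ids = [s.location_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate location_ids in dataset")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def specimen_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.specimen_id, None)
        return list(seen)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in TISSUE_CLASSES}
        for s in self.spectra:
            counts[s.tissue_class] += 1
        return counts

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, 1311) array in dataset order."""
        return np.vstack([s.intensities for s in self.spectra])

    def labels(self) -> np.ndarray:
        """Binary labels: 1 for fascicular nerve, 0 otherwise."""
        return np.array([int(s.is_positive) for s in self.spectra])

    def location_ids(self) -> list[str]:
        return [s.location_id for s in self.spectra]

    def subset(self, keep) -> "SpectraDataset":
        """New dataset with the spectra for which ``keep(spectrum)`` holds."""
        return SpectraDataset([s for s in self.spectra if keep(s)], grid=self.grid)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"w{int(w)}" for w in self.grid.wavelengths]
        df = pd.DataFrame(self.intensity_matrix(), columns=cols)
        meta = pd.DataFrame(
            {
                "specimen_id": [s.specimen_id for s in self.spectra],
                "area": [s.area for s in self.spectra],
                "tissue_class": [s.tissue_class for s in self.spectra],
                "location_id": [s.location_id for s in self.spectra],
            }
        )
        return pd.concat([meta, df], axis=1)


def write_dataset(dataset: SpectraDataset, path) -> None:
    """Write the dataset in the spectra CSV dialect (full float precision)."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_dataset(path, grid: WavelengthGrid = DEFAULT_GRID) -> SpectraDataset:
    """Read a spectra CSV; validates header, grid length and class labels."""
    df = pd.read_csv(path, dtype={"specimen_id": str, "location_id": str})
    meta_cols = ["specimen_id", "area", "tissue_class", "location_id"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"missing required column {c!r}")
    wave_cols = [c for c in df.columns if c.startswith("w") and c[1:].isdigit()]
    expected = [f"w{int(w)}" for w in grid.wavelengths]
    if wave_cols != expected:
        raise ValueError(
            f"wavelength columns do not match the {grid.n_points}-point grid "
            f"(got {len(wave_cols)} columns)"
        )
    spectra = []
    for i, row in df.iterrows():
        cls = row["tissue_class"]
        if cls not in TISSUE_CLASSES:
            raise ValueError(f"row {i}: unknown tissue class label {cls!r}")
        if row["area"] not in AREAS:
            raise ValueError(f"row {i}: unknown area label {row['area']!r}")
        spectra.append(
            Spectrum(
                intensities=row[wave_cols].to_numpy(dtype=float),
                specimen_id=str(row["specimen_id"]),
                area=row["area"],
                tissue_class=cls,
                location_id=str(row["location_id"]),
                grid=grid,
            )
        )
    return SpectraDataset(spectra, grid=grid)
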