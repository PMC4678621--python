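"""Synthetic cohort generator.

Emulates the structure of the ex-vivo cadaver study this pipeline is
designed for: 19 specimens, two anatomical areas (cervical in every
specimen, forearm in ten of them), four tissue classes with per-area
location counts of 702/223/164/185 (cervical) and 107/76/46/60
(forearm) for nerve/muscle/sliding fat/subcutaneous fat, and ~10
replicate raw spectra per location averaged into one data point.

Per-class parameter priors are truncated normals whose means encode the
physiological contrasts that make the classes separable: adipose
tissues carry high fat and beta-carotene; muscle carries the most blood
at the lowest oxygen saturation; muscle and nerve carry the most
collagen; the Mie slope differs across all four classes. The numeric
values are configuration defaults chosen to be physiologically
plausible, not fitted to any measured dataset, and all generated
outputs are labelled synthetic.

A per-specimen log-normal random effect multiplies every parameter mean
so that spectra from one specimen are correlated — this is what makes
leave-one-specimen-out validation genuinely harder than a random split.
Measurement noise is per-wavelength multiplicative Gaussian plus a
small additive floor, applied to each replicate before averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chromophores import ChromophoreLibrary
from .grid import DEFAULT_GRID, WavelengthGrid
from .optics import ProbeGeometry, TissueOpticalParams, forward_spectrum
from .spectra import TISSUE_CLASSES, SpectraDataset, Spectrum, average_replicates

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParamPrior:
    """Truncated-normal prior for one parameter."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, scale: float = 1.0) -> float:
        """One draw with the mean multiplied by a specimen effect."""
        m = min(max(self.mean * scale, self.lo), self.hi)
        if self.sd == 0:
            return m
        a, b = (self.lo - m) / self.sd, (self.hi - m) / self.sd
        if a >= b:
            raise ValueError(f"empty truncation support for prior {self}")
        return float(stats.truncnorm.rvs(a, b, loc=m, scale=self.sd,
                                         random_state=rng))


# Class-conditional priors. Orderings encoded:
#   fat, beta-carotene : subcutaneous > sliding > nerve > muscle
#   blood              : muscle > nerve > adipose
#   StO2               : muscle lowest
#   collagen           : nerve, muscle > adipose
#   mie slope b        : distinct in all four classes
DEFAULT_PRIORS: dict[str, dict[str, ParamPrior]] = {
    "fascicular_nerve": {
        "blood_fraction": ParamPrior(0.010, 0.003, 0.0, 0.2),
        "sto2": ParamPrior(0.65, 0.08, 0.0, 1.0),
        "beta_carotene": ParamPrior(0.30, 0.10, 0.0, 2.0),
        "fat_fraction": ParamPrior(0.15, 0.05, 0.0, 1.0),
        "water_fraction": ParamPrior(0.55, 0.06, 0.0, 1.0),
        "collagen_fraction": ParamPrior(0.30, 0.06, 0.0, 1.0),
        "s800": ParamPrior(12.0, 1.5, 1.0, 40.0),
        "mie_slope": ParamPrior(1.20, 0.12, 0.0, 4.0),
        "f_mie": ParamPrior(0.80, 0.06, 0.0, 1.0),
    },
    "muscle": {
        "blood_fraction": ParamPrior(0.025, 0.007, 0.0, 0.2),
        "sto2": ParamPrior(0.35, 0.08, 0.0, 1.0),
        "beta_carotene": ParamPrior(0.05, 0.03, 0.0, 2.0),
        "fat_fraction": ParamPrior(0.03, 0.02, 0.0, 1.0),
        "water_fraction": ParamPrior(0.70, 0.05, 0.0, 1.0),
        "collagen_fraction": ParamPrior(0.25, 0.05, 0.0, 1.0),
        "s800": ParamPrior(8.0, 1.2, 1.0, 40.0),
        "mie_slope": ParamPrior(0.70, 0.10, 0.0, 4.0),
        "f_mie": ParamPrior(0.55, 0.08, 0.0, 1.0),
    },
    "sliding_fat": {
        "blood_fraction": ParamPrior(0.004, 0.002, 0.0, 0.2),
        "sto2": ParamPrior(0.70, 0.08, 0.0, 1.0),
        "beta_carotene": ParamPrior(0.80, 0.20, 0.0, 2.0),
        "fat_fraction": ParamPrior(0.55, 0.08, 0.0, 1.0),
        "water_fraction": ParamPrior(0.25, 0.06, 0.0, 1.0),
        "collagen_fraction": ParamPrior(0.06, 0.03, 0.0, 1.0),
        "s800": ParamPrior(12.0, 1.5, 1.0, 40.0),
        "mie_slope": ParamPrior(0.50, 0.08, 0.0, 4.0),
        "f_mie": ParamPrior(0.90, 0.04, 0.0, 1.0),
    },
    "subcutaneous_fat": {
        "blood_fraction": ParamPrior(0.003, 0.0015, 0.0, 0.2),
        "sto2": ParamPrior(0.70, 0.08, 0.0, 1.0),
        "beta_carotene": ParamPrior(1.00, 0.25, 0.0, 2.0),
        "fat_fraction": ParamPrior(0.65, 0.08, 0.0, 1.0),
        "water_fraction": ParamPrior(0.20, 0.05, 0.0, 1.0),
        "collagen_fraction": ParamPrior(0.05, 0.03, 0.0, 1.0),
        "s800": ParamPrior(11.0, 1.5, 1.0, 40.0),
        "mie_slope": ParamPrior(0.35, 0.07, 0.0, 4.0),
        "f_mie": ParamPrior(0.65, 0.07, 0.0, 1.0),
    },
}

#: Nuisance priors shared across classes: vessel packaging near 0.1 mm,
#: per-location calibration amplitude within a few percent of 1, no offset.
DEFAULT_NUISANCE_PRIORS: dict[str, ParamPrior] = {
    "vessel_diameter_mm": ParamPrior(0.10, 0.0, 0.0, 1.0),
    "amplitude": ParamPrior(1.0, 0.03, 0.9, 1.1),
    "offset": ParamPrior(0.0, 0.0, -1e-3, 1e-3),
}

#: Location counts of the study design, per area and tissue class.
STUDY_COUNTS = {
    "cervical": {"fascicular_nerve": 702, "muscle": 223,
                 "sliding_fat": 164, "subcutaneous_fat": 185},
    "forearm": {"fascicular_nerve": 107, "muscle": 76,
                "sliding_fat": 46, "subcutaneous_fat": 60},
}
N_SPECIMENS = 19
#: Forearm measurements were taken in ten of the nineteen specimens.
N_FOREARM_SPECIMENS = 10


def scaled_counts(fraction: float) -> dict[str, dict[str, int]]:
    """Study counts scaled down (rounded, floor 1 per class per area)."""
    return {
        area: {cls: max(1, round(n * fraction)) for cls, n in counts.items()}
        for area, counts in STUDY_COUNTS.items()
    }


@dataclass
class CohortConfig:
    """Fully determines one synthetic cohort draw."""

    n_specimens: int = N_SPECIMENS
    n_forearm_specimens: int = N_FOREARM_SPECIMENS
    counts: dict = field(default_factory=lambda: {a: dict(c) for a, c in STUDY_COUNTS.items()})
    replicates_per_location: int = 10
    specimen_effect_sd: float = 0.10     # log-normal sd of per-specimen multipliers
    noise_multiplicative_sd: float = 0.02
    noise_additive_sd: float = 1e-4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 2:
            raise ValueError("need at least two specimens")
        if self.n_forearm_specimens > self.n_specimens:
            raise ValueError("forearm specimens cannot exceed total specimens")
        if self.replicates_per_location < 1:
            raise ValueError("need at least one replicate per location")
        for area, counts in self.counts.items():
            for cls, n in counts.items():
                if n < 1:
                    raise ValueError(f"count for {area}/{cls} must be >= 1")

    @classmethod
    def desk_profile(cls, rng_seed: int = 0) -> "CohortConfig":
        """Reduced-size profile: all 19 specimens (LOSO keeps 19 folds)
        at ~15 % of the per-class location counts."""
        return cls(counts=scaled_counts(0.15), rng_seed=rng_seed)


def sample_tissue_params(
    tissue_class: str,
    specimen_effects: dict[str, float],
    rng: np.random.Generator,
    priors: dict[str, dict[str, ParamPrior]] | None = None,
    nuisance_priors: dict[str, ParamPrior] | None = None,
) -> TissueOpticalParams:
    """Draw one parameter vector for a location of the given class."""
    priors = priors or DEFAULT_PRIORS
    nuisance = nuisance_priors or DEFAULT_NUISANCE_PRIORS
    values = {}
    for name, prior in priors[tissue_class].items():
        values[name] = prior.sample(rng, scale=specimen_effects.get(name, 1.0))
    for name, prior in nuisance.items():
        values[name] = prior.sample(rng)
    return TissueOpticalParams(**values)


def _specimen_effects(rng: np.random.Generator, sd: float,
                      param_names) -> dict[str, float]:
    if sd == 0:
        return {n: 1.0 for n in param_names}
    sigma = np.sqrt(np.log1p(sd ** 2))  # log-normal with unit mean
    return {n: float(rng.lognormal(-0.5 * sigma ** 2, sigma)) for n in param_names}


def generate_cohort(
    config: CohortConfig,
    geom: ProbeGeometry | None = None,
    lib: ChromophoreLibrary | None = None,
    priors: dict[str, dict[str, ParamPrior]] | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> tuple[SpectraDataset, pd.DataFrame]:
    """Generate a full synthetic cohort and its ground-truth table.

    Per-area totals are distributed as evenly as possible over the
    specimens measured in that area. Returns the averaged dataset and a
    DataFrame of true parameters keyed by ``location_id``.
    """
    from .chromophores import load_default_library

    geom = geom or ProbeGeometry()
    lib = lib or load_default_library(grid)
    priors = priors or DEFAULT_PRIORS
    rng = np.random.default_rng(config.rng_seed)

    specimens = [f"S{i + 1:02d}" for i in range(config.n_specimens)]
    forearm_set = set(specimens[: config.n_forearm_specimens])
    effects = {
        sp: _specimen_effects(rng, config.specimen_effect_sd,
                              priors["muscle"].keys())
        for sp in specimens
    }

    spectra: list[Spectrum] = []
    truth_rows: list[dict] = []
    counter = 0
    for area, class_counts in config.counts.items():
        area_specimens = (specimens if area == "cervical"
                          else [s for s in specimens if s in forearm_set])
        if not area_specimens:
            continue  # area not measured in this cohort
        for cls in TISSUE_CLASSES:
            total = class_counts[cls]
            # even split with the remainder spread over the first specimens
            base, extra = divmod(total, len(area_specimens))
            for k, sp in enumerate(area_specimens):
                n_here = base + (1 if k < extra else 0)
                for _ in range(n_here):
                    counter += 1
                    loc = f"L{counter:05d}"
                    params = sample_tissue_params(cls, effects[sp], rng, priors)
                    clean = forward_spectrum(params, geom, lib, grid)
                    reps = []
                    for _ in range(config.replicates_per_location):
                        mult = 1.0 + config.noise_multiplicative_sd * rng.standard_normal(grid.n_points)
                        add = config.noise_additive_sd * rng.standard_normal(grid.n_points)
                        reps.append(np.maximum(clean * mult + add, 0.0))
                    avg = average_replicates(reps, grid)
                    spectra.append(Spectrum(avg, sp, area, cls, loc, grid=grid))
                    row = {"location_id": loc, "specimen_id": sp,
                           "area": area, "tissue_class": cls}
                    row.update(dict(zip(params.names(), params.to_array())))
                    truth_rows.append(row)
    dataset = SpectraDataset(spectra, grid=grid)
    truth = pd.DataFrame(truth_rows).set_index("location_id")
    logger.info("generated synthetic cohort: %d locations, %d specimens",
                len(dataset), len(dataset.specimen_ids))
    return dataset, truth
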