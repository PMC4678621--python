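"""Forward optics: reduced scattering, chromophore absorption, and the
diffusion-approximation diffuse reflectance for a two-fiber needle probe.

Model summary
-------------
Reduced scattering follows a Mie/Rayleigh mixture,

    mu_s'(lambda) = S800 * [ Fmie (lambda/800)^(-b) + (1-Fmie) (lambda/800)^(-4) ]

with ``S800`` the reduced scattering amplitude (cm^-1) at the 800 nm
normalisation wavelength, ``b`` the Mie slope and ``Fmie`` the
Mie-to-total fraction.

Absorption is a linear mixture of the chromophore library scaled by the
tissue composition; the blood term carries an optional pigment-packaging
correction for blood confined to vessels of finite diameter.

Reflectance uses the steady-state Farrell-Patterson-Wilson diffusion
approximation for a semi-infinite medium with an extrapolated boundary
(tissue refractive index fixed at 1.4), evaluated at the probe's
source-detector separation. A multiplicative amplitude and an additive
offset absorb residual calibration error; together with the vessel
diameter they are the three nuisance parameters that bring the fit
vector to 12 parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

from .chromophores import ChromophoreLibrary
from .grid import DEFAULT_GRID, WavelengthGrid

LAMBDA_0_NM = 800.0
TISSUE_REFRACTIVE_INDEX = 1.4


@dataclass(frozen=True)
class ProbeGeometry:
    """Two-fiber needle probe; separation is centre-to-centre in mm."""

    fiber_separation_mm: float = 0.85
    fiber_core_diameter_um: float = 200.0

    def __post_init__(self) -> None:
        if self.fiber_separation_mm <= 0:
            raise ValueError("fiber separation must be positive")

    @property
    def separation_cm(self) -> float:
        return self.fiber_separation_mm / 10.0


@dataclass
class TissueOpticalParams:
    """The 12-parameter vector the inverse model estimates.

    Nine physiological/scattering parameters plus three nuisance
    parameters (vessel diameter for pigment packaging, calibration
    amplitude and offset).
    """

    blood_fraction: float = 0.01   # 1.0 == 150 g Hb/L whole blood
    sto2: float = 0.6              # HbO2 / (Hb + HbO2)
    beta_carotene: float = 0.3     # library reference units
    fat_fraction: float = 0.2      # volume fraction
    water_fraction: float = 0.5    # volume fraction
    collagen_fraction: float = 0.15
    s800: float = 12.0             # cm^-1, reduced scattering at 800 nm
    mie_slope: float = 1.0         # b
    f_mie: float = 0.7             # Mie-to-total fraction
    vessel_diameter_mm: float = 0.1
    amplitude: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sto2", "fat_fraction", "water_fraction",
                     "collagen_fraction", "f_mie"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.blood_fraction < 0 or self.beta_carotene < 0:
            raise ValueError("concentrations must be non-negative")
        if self.s800 <= 0:
            raise ValueError("s800 must be positive")
        if self.mie_slope < 0:
            raise ValueError("mie_slope must be non-negative")
        if self.vessel_diameter_mm < 0:
            raise ValueError("vessel diameter must be non-negative")

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names()])

    @classmethod
    def from_array(cls, values) -> "TissueOpticalParams":
        return cls(**dict(zip(cls.names(), map(float, values))))

    def replace(self, **kw) -> "TissueOpticalParams":
        return replace(self, **kw)


#: Parameters that are nuisance (calibration / packaging), not physiology.
NUISANCE_PARAMS = ("vessel_diameter_mm", "amplitude", "offset")


def reduced_scattering(lam_nm, s800: float, b: float, f_mie: float) -> np.ndarray:
    """Mie/Rayleigh mixture reduced scattering coefficient, cm^-1."""
    lam = np.asarray(lam_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    if not 0.0 <= f_mie <= 1.0:
        raise ValueError("f_mie outside [0, 1]")
    x = lam / LAMBDA_0_NM
    return s800 * (f_mie * x ** (-b) + (1.0 - f_mie) * x ** (-4.0))


def _packaging_factor(mu_a_blood: np.ndarray, vessel_diameter_mm: float) -> np.ndarray:
    """Pigment-packaging correction for blood confined to vessels.

    C(lambda) = (1 - exp(-2 mu_a_bl R)) / (2 mu_a_bl R) with R the vessel
    radius in cm; tends to 1 as the diameter goes to 0 (homogeneous blood).
    """
    radius_cm = vessel_diameter_mm / 2.0 / 10.0
    x = 2.0 * mu_a_blood * radius_cm
    out = np.ones_like(mu_a_blood)
    nz = x > 1e-12
    out[nz] = -np.expm1(-x[nz]) / x[nz]
    return out


def absorption(params: TissueOpticalParams, lib: ChromophoreLibrary,
               grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """Total absorption coefficient mu_a(lambda) in cm^-1 on the grid."""
    mu_blood = params.sto2 * lib["hbo2"] + (1.0 - params.sto2) * lib["hb"]
    pack = _packaging_factor(mu_blood, params.vessel_diameter_mm)
    return (
        params.blood_fraction * pack * mu_blood
        + params.beta_carotene * lib["beta_carotene"]
        + params.fat_fraction * lib["fat"]
        + params.water_fraction * lib["water"]
        + params.collagen_fraction * lib["collagen"]
    )


def _boundary_parameter(n: float = TISSUE_REFRACTIVE_INDEX) -> float:
    """Internal-reflection parameter A for the extrapolated boundary.

    Uses the Groenhuis empirical effective reflection coefficient
    r_d = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n, A = (1+r_d)/(1-r_d).
    """
    r_d = -1.440 * n ** -2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


def farrell_reflectance(mu_a, mu_s_prime, rho_cm: float) -> np.ndarray:
    """Steady-state spatially resolved diffuse reflectance R(rho), cm^-2.

    Semi-infinite homogeneous medium, isotropic point source buried at
    one transport mean free path, extrapolated-boundary image source:

        R = a'/(4 pi) [ z0 (mu_eff + 1/r1) exp(-mu_eff r1)/r1^2
                      + (z0 + 2 zb)(mu_eff + 1/r2) exp(-mu_eff r2)/r2^2 ]

    with mu_t' = mu_a + mu_s', a' = mu_s'/mu_t', z0 = 1/mu_t',
    mu_eff = sqrt(3 mu_a mu_t'), D = 1/(3 mu_t'), zb = 2 A D,
    r1^2 = z0^2 + rho^2, r2^2 = (z0 + 2 zb)^2 + rho^2.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_s_prime <= 0):
        raise ValueError("diffusion model requires mu_s' > 0 everywhere")
    if np.any(mu_a < 0):
        raise ValueError("mu_a must be non-negative")
    mu_t = mu_a + mu_s_prime
    albedo = mu_s_prime / mu_t
    z0 = 1.0 / mu_t
    mu_eff = np.sqrt(3.0 * mu_a * mu_t)
    diffusion = 1.0 / (3.0 * mu_t)
    zb = 2.0 * _boundary_parameter() * diffusion
    r1 = np.sqrt(z0 ** 2 + rho_cm ** 2)
    z2 = z0 + 2.0 * zb
    r2 = np.sqrt(z2 ** 2 + rho_cm ** 2)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1 ** 2
    term2 = z2 * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2 ** 2
    return albedo / (4.0 * np.pi) * (term1 + term2)


def diffuse_reflectance(params: TissueOpticalParams, geom: ProbeGeometry,
                        lib: ChromophoreLibrary,
                        grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """Farrell reflectance at the probe separation for every grid wavelength."""
    mu_a = absorption(params, lib, grid)
    mu_s = reduced_scattering(grid.wavelengths, params.s800,
                              params.mie_slope, params.f_mie)
    return farrell_reflectance(mu_a, mu_s, geom.separation_cm)


def forward_spectrum(params: TissueOpticalParams, geom: ProbeGeometry,
                     lib: ChromophoreLibrary,
                     grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """Model spectrum including the calibration nuisance terms:
    amplitude * R(lambda) + offset."""
    return params.amplitude * diffuse_reflectance(params, geom, lib, grid) + params.offset
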