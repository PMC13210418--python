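"""X-ray source spectrum, attenuation tables, and Beer–Lambert transmission.

The forward model works on a polychromatic incident spectrum ``I0(E)`` that is
attenuated pixel-by-pixel through two basis materials (aluminum as the
bone-equivalent basis, PMMA as the soft-tissue-equivalent basis):

    I(E) = I0(E) * exp(-mu_Al(E) * x_Al - mu_PMMA(E) * x_PMMA)

Attenuation tables are bundled as CSV on a 15–174 keV, 1 keV grid (linear
attenuation per mm; see ``tools/make_fixtures.py`` for provenance).  The
spectrum fixture is a 120 kVp filtered tungsten spectrum; its absolute
normalization is set so that the total open-beam fluence per native 0.1 mm
detector pixel follows the linear photons↔mAs model anchored at 1e7 photons
= 7.5 mAs.  (Per 1.0 mm macro-pixel the open beam is 100x that, i.e. 1e9
photons at 7.5 mAs.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: open-beam photons per native 0.1 mm detector pixel per mAs (dose anchor)
PHOTONS_PER_MAS = 1.0e7 / 7.5

#: native detector pixel pitch the dose anchor refers to, mm
DOSE_PIXEL_PITCH_MM = 0.1

#: reference exposure at which Spectrum.fluence sums to the anchor count
REFERENCE_EXPOSURE_MAS = 7.5

DENSITY_G_CM3 = {"Al": 2.699, "PMMA": 1.18, "CdTe": 5.85}

_FIXTURES = {"Al": "mu_al.csv", "PMMA": "mu_pmma.csv", "CdTe": "mu_cdte.csv"}


@dataclass(frozen=True)
class AttenuationTable:
    """Linear attenuation coefficient of one material on a keV grid."""

    material: str
    energies: np.ndarray  # keV, strictly increasing
    mu: np.ndarray        # per mm
    density: float        # g/cm^3

    def __post_init__(self) -> None:
        if np.any(self.mu <= 0):
            raise ValueError("attenuation coefficients must be positive")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")

    def __call__(self, energy_kev: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of mu (per mm) at the requested energies."""
        return np.interp(energy_kev, self.energies, self.mu)

    @property
    def mass_attenuation(self) -> np.ndarray:
        """mu/rho in cm^2/g on the table grid."""
        return self.mu * 10.0 / self.density


@dataclass
class Spectrum:
    """Photon fluence per 1 keV bin per native detector pixel at a reference exposure."""

    energies: np.ndarray          # keV, 1 keV spacing
    fluence: np.ndarray           # photons per bin per native pixel
    reference_exposure: float = REFERENCE_EXPOSURE_MAS  # mAs

    def __post_init__(self) -> None:
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")
        if self.fluence.sum() <= 0:
            raise ValueError("spectrum carries no photons")

    @property
    def total_photons(self) -> float:
        return float(self.fluence.sum())

    @property
    def mean_energy(self) -> float:
        return float((self.energies * self.fluence).sum() / self.fluence.sum())

    def copy(self) -> "Spectrum":
        return Spectrum(self.energies.copy(), self.fluence.copy(),
                        self.reference_exposure)


def _read_fixture(name: str) -> np.ndarray:
    path = resources.files("pcdspect.data").joinpath(name)
    with path.open("rb") as fh:
        return np.loadtxt(fh, delimiter=",", comments="#", skiprows=2)


def load_attenuation(material: str) -> AttenuationTable:
    """Load the bundled attenuation table for ``Al``, ``PMMA`` or ``CdTe``.

    Tables are on the 15–174 keV 1 keV grid; off-grid energies interpolate
    linearly via calling the returned table.
    """
    if material not in _FIXTURES:
        raise ValueError(f"unknown material {material!r}; expected one of "
                         f"{sorted(_FIXTURES)}")
    data = _read_fixture(_FIXTURES[material])
    return AttenuationTable(material=material, energies=data[:, 0],
                            mu=data[:, 1], density=DENSITY_G_CM3[material])


def load_spectrum(kvp: float = 120.0, al_filtration_mm: float = 2.0) -> Spectrum:
    """Load the bundled 120 kVp tungsten spectrum.

    The fixture already includes 2.0 mm external Al filtration (plus inherent
    filtration); requesting more than 2.0 mm applies the extra Al by
    Beer–Lambert, less is not supported.  Fluence is normalized so that the
    total equals ``PHOTONS_PER_MAS * reference_exposure`` photons per
    native 0.1 mm detector pixel.
    """
    if kvp != 120.0:
        raise ValueError("only the bundled 120 kVp spectrum is available")
    data = _read_fixture("spectrum_120kvp.csv")
    energies, rel = data[:, 0], data[:, 1]
    if al_filtration_mm < 2.0:
        raise ValueError("fixture includes 2.0 mm Al; cannot remove filtration")
    if al_filtration_mm > 2.0:
        mu_al = load_attenuation("Al")
        rel = rel * np.exp(-mu_al(energies) * (al_filtration_mm - 2.0))
    fluence = rel / rel.sum() * PHOTONS_PER_MAS * REFERENCE_EXPOSURE_MAS
    return Spectrum(energies=energies, fluence=fluence)


def transmit(spectrum: Spectrum, x_al: float, x_pmma: float,
             mu_al: AttenuationTable | None = None,
             mu_pmma: AttenuationTable | None = None) -> Spectrum:
    """Beer–Lambert transmission through x_al mm of Al and x_pmma mm of PMMA."""
    if x_al < 0 or x_pmma < 0:
        raise ValueError("thicknesses must be non-negative")
    mu_al = mu_al if mu_al is not None else load_attenuation("Al")
    mu_pmma = mu_pmma if mu_pmma is not None else load_attenuation("PMMA")
    factor = np.exp(-mu_al(spectrum.energies) * x_al
                    - mu_pmma(spectrum.energies) * x_pmma)
    return Spectrum(energies=spectrum.energies, fluence=spectrum.fluence * factor,
                    reference_exposure=spectrum.reference_exposure)


def photons_to_mas(n_photons: float) -> float:
    """Convert open-beam photons per native detector pixel to tube mAs."""
    if n_photons <= 0:
        raise ValueError("photon count must be positive")
    return n_photons / PHOTONS_PER_MAS


def mas_to_photons(mas: float) -> float:
    """Inverse of :func:`photons_to_mas`."""
    if mas <= 0:
        raise ValueError("exposure must be positive")
    return mas * PHOTONS_PER_MAS
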