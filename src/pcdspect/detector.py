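"""Parametric CdTe photon-counting detector model.

The acquisition chain is, in order: Beer–Lambert transmission of the
polychromatic spectrum, spectral redistribution through a detector response
function (DRF) matrix, threshold binning, a 3x3 spatial charge-sharing
convolution applied to the *mean* bin images, independent per-pixel Poisson
sampling, and 10x10 rebinning from the native 0.1 mm pitch to 1.0 mm
macro-pixels.

The DRF here is an analytic surrogate with the qualitative structure of a
Monte-Carlo-derived CdTe response: for incident energy E a photopeak carrying
the un-shared fraction of the interaction probability, a charge-sharing tail
spread uniformly over (0, E], optional Cd/Te K-fluorescence escape lines, and
Gaussian spectral broadening from electronic noise plus Fano statistics,

    sigma(E) = sqrt(sigma_el^2 + F * eps * E)        [keV]

with F the Fano factor and eps the pair-creation energy in keV.  The
charge-sharing fraction is the geometric probability that an isotropic
Gaussian charge cloud, centered uniformly within a pixel, loses charge across
a pixel border; the same model yields the 3x3 spatial kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import norm

from .physics import AttenuationTable, Spectrum, load_attenuation

INCIDENT_GRID_KEV = np.arange(15, 175, dtype=float)   # rows of the DRF
DETECTED_GRID_KEV = np.arange(1, 175, dtype=float)    # columns of the DRF

# K-shell binding and mean K-fluorescence energies, keV
CD_K_EDGE_KEV, CD_K_FLUOR_KEV = 26.711, 23.17
TE_K_EDGE_KEV, TE_K_FLUOR_KEV = 31.814, 27.47


@dataclass(frozen=True)
class DetectorConfig:
    """Physical parameters of the CdTe sensor and readout."""

    cdte_thickness: float = 1.0          # mm
    pixel_pitch: float = 0.1             # mm, native
    charge_cloud_sigma: float = 0.025    # mm, Gaussian cloud std
    electronic_noise_sigma: float = 2.0  # keV
    fano_factor: float = 0.089
    pair_creation_energy: float = 4.43e-3  # keV per e-h pair
    escape_model_on: bool = True
    escape_fraction_cd: float = 0.04     # photopeak fraction lost to Cd K escape
    escape_fraction_te: float = 0.04     # ... and to Te K escape

    def __post_init__(self) -> None:
        for name in ("cdte_thickness", "pixel_pitch", "charge_cloud_sigma",
                     "electronic_noise_sigma", "fano_factor",
                     "pair_creation_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def incident_grid(self) -> np.ndarray:
        return INCIDENT_GRID_KEV


@dataclass
class DRFMatrix:
    """Incident→detected energy redistribution R[i, j]."""

    R: np.ndarray
    incident_energies: np.ndarray
    detected_energies: np.ndarray

    def __post_init__(self) -> None:
        if self.R.shape != (len(self.incident_energies),
                            len(self.detected_energies)):
            raise ValueError("DRF shape does not match its energy grids")
        if np.any(self.R < 0):
            raise ValueError("DRF must be non-negative")

    def to_csv(self, path: str) -> None:
        header = "incident_keV," + ",".join(
            f"{e:.0f}" for e in self.detected_energies)
        rows = np.column_stack([self.incident_energies, self.R])
        np.savetxt(path, rows, delimiter=",", header=header, comments="")


@dataclass(frozen=True)
class ThresholdConfig:
    """M strictly increasing keV thresholds; bin k = [T_k, T_{k+1}), last open."""

    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if not 2 <= len(t) <= 6:
            raise ValueError("between 2 and 6 thresholds are supported")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if t[0] < DETECTED_GRID_KEV[0] or t[-1] > DETECTED_GRID_KEV[-1]:
            raise ValueError("thresholds must lie within the detected grid")

    @property
    def n_bins(self) -> int:
        return len(self.thresholds)

    @classmethod
    def equally_spaced(cls, m: int, lo: float = 20.0, hi: float = 100.0
                       ) -> "ThresholdConfig":
        """M thresholds at lo + (hi-lo)*k/M, k=0..M-1 (e.g. M=2 -> {20, 60})."""
        return cls(tuple(lo + (hi - lo) * k / m for k in range(m)))

    def bin_detected(self, detected_counts: np.ndarray) -> np.ndarray:
        """Sum per-keV detected counts (last axis on DETECTED_GRID_KEV) into bins."""
        edges = list(self.thresholds) + [np.inf]
        out = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            sel = (DETECTED_GRID_KEV >= lo) & (DETECTED_GRID_KEV < hi)
            out.append(detected_counts[..., sel].sum(axis=-1))
        return np.stack(out, axis=0)


@dataclass(frozen=True)
class SharingKernel:
    """Normalized 3x3 charge-sharing convolution weights."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.weights.shape != (3, 3) or np.any(self.weights < 0):
            raise ValueError("kernel must be a non-negative 3x3 array")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("kernel weights must sum to 1")


@dataclass
class BinnedCountImage:
    """Stack of per-bin count images plus the matching open-beam reference.

    ``counts`` has shape (M, H, W).  ``open_beam`` is the per-bin open-beam
    count for a single pixel at the same pitch and exposure (the beam is
    uniform, so a vector suffices).
    """

    counts: np.ndarray
    pitch: float
    exposure_mas: float
    thresholds: ThresholdConfig
    is_noisy: bool
    open_beam: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be (bins, H, W)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.is_noisy and not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("noisy stacks must be integer-valued")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for k in range(self.n_bins):
                fh.create_dataset(f"bin_{k}", data=self.counts[k])
            fh.create_dataset("open_beam", data=self.open_beam)
            fh.attrs["pitch_mm"] = self.pitch
            fh.attrs["exposure_mAs"] = self.exposure_mas
            fh.attrs["thresholds_keV"] = list(self.thresholds.thresholds)
            fh.attrs["is_noisy"] = self.is_noisy
            fh.attrs["seed"] = -1 if self.seed is None else self.seed


# ---------------------------------------------------------------------------
# charge-sharing geometry

def _collection_profile(sigma: float, pitch: float, n_centers: int = 801
                        ) -> np.ndarray:
    """Expected 1D charge fraction collected in pixel offsets -1, 0, +1.

    The cloud center is uniform over the central pixel [0, p); the charge in
    pixel k (spanning [k p, (k+1) p)) for a center at c is
    Phi(((k+1)p - c)/sigma) - Phi((k p - c)/sigma), averaged over c.
    """
    c = (np.arange(n_centers) + 0.5) / n_centers * pitch
    out = np.empty(3)
    for i, k in enumerate((-1, 0, 1)):
        mass = (norm.cdf(((k + 1) * pitch - c) / sigma)
                - norm.cdf((k * pitch - c) / sigma))
        out[i] = mass.mean()
    return out


def fit_sharing_kernel(config: DetectorConfig) -> SharingKernel:
    """3x3 kernel from the Gaussian charge-cloud model (separable in x/y)."""
    if config.charge_cloud_sigma <= 0:
        raise ValueError("charge_cloud_sigma must be positive")
    w1 = _collection_profile(config.charge_cloud_sigma, config.pixel_pitch)
    w = np.outer(w1, w1)
    return SharingKernel(weights=w / w.sum())


def charge_sharing_fraction(config: DetectorConfig) -> float:
    """Probability that a photon's charge is not fully collected in its pixel."""
    w1 = _collection_profile(config.charge_cloud_sigma, config.pixel_pitch)
    return float(1.0 - w1[1] ** 2)


# ---------------------------------------------------------------------------
# DRF

def _broadening_matrix(config: DetectorConfig) -> np.ndarray:
    """B[j_dep, j_det]: Gaussian spread of deposited energy, mass-preserving."""
    e = DETECTED_GRID_KEV
    sigma = np.sqrt(config.electronic_noise_sigma ** 2
                    + config.fano_factor * config.pair_creation_energy * e)
    diff = e[None, :] - e[:, None]
    b = np.exp(-0.5 * (diff / sigma[:, None]) ** 2)
    return b / b.sum(axis=1, keepdims=True)


def build_drf(config: DetectorConfig,
              mu_cdte: AttenuationTable | None = None) -> DRFMatrix:
    """Build the analytic CdTe detector response matrix.

    Each incident-energy row integrates to the interaction probability
    1 - exp(-mu_CdTe(E) d); charge sharing moves a fraction of it into a
    uniform low-energy tail, K-fluorescence escape (optional) shifts part of
    the photopeak down by the fluorescence energy, and everything is smeared
    by the energy-resolution Gaussian.
    """
    mu = mu_cdte if mu_cdte is not None else load_attenuation("CdTe")
    s = charge_sharing_fraction(config)
    n_in, n_det = len(INCIDENT_GRID_KEV), len(DETECTED_GRID_KEV)
    raw = np.zeros((n_in, n_det))
    for i, e_in in enumerate(INCIDENT_GRID_KEV):
        eff = 1.0 - np.exp(-mu(e_in) * config.cdte_thickness)
        j_peak = int(e_in) - 1  # detected grid starts at 1 keV
        peak_mass = eff * (1.0 - s)
        if config.escape_model_on:
            for edge, fluor, frac in (
                    (CD_K_EDGE_KEV, CD_K_FLUOR_KEV, config.escape_fraction_cd),
                    (TE_K_EDGE_KEV, TE_K_FLUOR_KEV, config.escape_fraction_te)):
                if e_in > edge:
                    moved = eff * (1.0 - s) * frac
                    peak_mass -= moved
                    j_esc = int(round(e_in - fluor)) - 1
                    if j_esc >= 0:
                        raw[i, j_esc] += moved
        raw[i, j_peak] += peak_mass
        # sharing tail: uniform in deposited energy over (0, E]
        raw[i, :j_peak + 1] += eff * s / (j_peak + 1)
    blur = _broadening_matrix(config)
    return DRFMatrix(R=raw @ blur, incident_energies=INCIDENT_GRID_KEV.copy(),
                     detected_energies=DETECTED_GRID_KEV.copy())


# ---------------------------------------------------------------------------
# forward projection

def _detected_spectrum(fluence_on_incident_grid: np.ndarray,
                       drf: DRFMatrix) -> np.ndarray:
    return fluence_on_incident_grid @ drf.R


def _embed_on_incident_grid(spectrum: Spectrum) -> np.ndarray:
    out = np.zeros(len(INCIDENT_GRID_KEV))
    idx = np.searchsorted(INCIDENT_GRID_KEV, spectrum.energies)
    ok = (idx < len(INCIDENT_GRID_KEV)) & np.isclose(
        INCIDENT_GRID_KEV[np.minimum(idx, len(INCIDENT_GRID_KEV) - 1)],
        spectrum.energies)
    if not np.all(ok):
        raise ValueError("spectrum energies do not lie on the incident grid")
    out[idx] = spectrum.fluence
    return out


def expected_bin_counts(maps, spectrum: Spectrum, drf: DRFMatrix,
                        thresholds: ThresholdConfig, exposure_mas: float,
                        mu_al: AttenuationTable | None = None,
                        mu_pmma: AttenuationTable | None = None
                        ) -> BinnedCountImage:
    """Noise-free expected counts per micro-pixel per energy bin.

    The transmitted spectrum is computed once per unique (x_Al, x_PMMA) pair
    and broadcast, so cost scales with the number of distinct thickness
    combinations rather than with pixels.  The spectrum normalization is per
    native detector pixel; counts scale with the pixel-area ratio.
    """
    from .physics import DOSE_PIXEL_PITCH_MM, REFERENCE_EXPOSURE_MAS

    mu_al = mu_al if mu_al is not None else load_attenuation("Al")
    mu_pmma = mu_pmma if mu_pmma is not None else load_attenuation("PMMA")
    if exposure_mas <= 0:
        raise ValueError("exposure must be positive")

    pairs = np.stack([maps.al_map.ravel(), maps.pmma_map.ravel()], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)

    area_ratio = (maps.pitch / DOSE_PIXEL_PITCH_MM) ** 2
    scale = area_ratio * exposure_mas / REFERENCE_EXPOSURE_MAS

    att_al = np.exp(-np.outer(uniq[:, 0], mu_al(spectrum.energies)))
    att_pm = np.exp(-np.outer(uniq[:, 1], mu_pmma(spectrum.energies)))
    base = _embed_on_incident_grid(spectrum)
    # transmitted fluence per unique pair, embedded on the incident grid
    fl = np.zeros((len(uniq), len(INCIDENT_GRID_KEV)))
    idx = np.searchsorted(INCIDENT_GRID_KEV, spectrum.energies)
    fl[:, idx] = spectrum.fluence * att_al * att_pm
    binned_uniq = thresholds.bin_detected(_detected_spectrum(fl, drf)) * scale

    m = thresholds.n_bins
    h, w = maps.shape
    counts = binned_uniq[:, inverse].reshape(m, h, w)

    open_beam = thresholds.bin_detected(
        _detected_spectrum(base, drf)) * scale
    return BinnedCountImage(counts=counts, pitch=maps.pitch,
                            exposure_mas=exposure_mas, thresholds=thresholds,
                            is_noisy=False, open_beam=open_beam)


def apply_sharing(image: BinnedCountImage, kernel: SharingKernel
                  ) -> BinnedCountImage:
    """Convolve each mean bin image with the 3x3 kernel (reflect boundaries).

    Sharing is part of the mean detector response; applying it to sampled
    (noisy) stacks is an error.
    """
    if image.is_noisy:
        raise ValueError("charge sharing applies to noise-free means only")
    out = np.empty_like(image.counts)
    for k in range(image.n_bins):
        out[k] = ndimage.convolve(image.counts[k], kernel.weights,
                                  mode="reflect")
    return BinnedCountImage(counts=out, pitch=image.pitch,
                            exposure_mas=image.exposure_mas,
                            thresholds=image.thresholds, is_noisy=False,
                            open_beam=image.open_beam.copy())


def sample_poisson(image: BinnedCountImage, seed: int) -> BinnedCountImage:
    """Independent Poisson draw per pixel per bin; reproducible given seed."""
    if np.any(image.counts < 0):
        raise ValueError("Poisson means must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(image.counts).astype(np.int64)
    return BinnedCountImage(counts=counts, pitch=image.pitch,
                            exposure_mas=image.exposure_mas,
                            thresholds=image.thresholds, is_noisy=True,
                            open_beam=image.open_beam.copy(), seed=seed)


def rebin(image: BinnedCountImage, factor: int = 10) -> BinnedCountImage:
    """Block-sum each bin image by ``factor`` in both dimensions."""
    m, h, w = image.counts.shape
    if h % factor or w % factor:
        raise ValueError("image dimensions must be divisible by the factor")
    c = image.counts.reshape(m, h // factor, factor, w // factor, factor)
    counts = c.sum(axis=(2, 4))
    return BinnedCountImage(counts=counts, pitch=image.pitch * factor,
                            exposure_mas=image.exposure_mas,
                            thresholds=image.thresholds,
                            is_noisy=image.is_noisy,
                            open_beam=image.open_beam * factor ** 2,
                            seed=image.seed)
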