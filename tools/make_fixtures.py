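"""Regenerate the bundled spectrum and attenuation fixtures under src/pcdspect/data/.

The package ships plain-CSV physics tables so that nothing is downloaded at
build or test time.  This script documents exactly how they were produced:

* ``mu_al.csv``, ``mu_pmma.csv`` — NIST mass-attenuation anchor tables
  (total attenuation with coherent scattering, cm²/g) log-log interpolated
  to the 15–174 keV 1 keV grid and converted to linear attenuation per mm
  with densities 2.699 (Al) and 1.18 (PMMA) g/cm³.
* ``mu_cdte.csv`` — photoelectric component from Cromer–Liberman f″
  (via gemmi) mass-weighted over Cd/Te, plus Klein–Nishina incoherent
  scattering; density 5.85 g/cm³.  Coherent scattering is neglected
  (photoabsorption dominates below ~120 keV in CdTe).
* ``spectrum_120kvp.csv`` — filtered 120 kVp tungsten bremsstrahlung:
  Kramers fluence ∝ (kVp/E − 1) attenuated by 3.0 mm Al-equivalent total
  filtration (2.0 mm stated external + 1.0 mm inherent), plus tungsten
  K-characteristic lines carrying 9% of the total filtered fluence.
  Stored as relative per-keV-bin fluence; absolute normalization (photons
  per macro-pixel per mAs) is applied by the loader.

Requires gemmi (pre-installed) only for the CdTe table.
"""

from __future__ import annotations

import pathlib

import numpy as np

R_E_CM = 2.8179403262e-13  # classical electron radius
N_A = 6.02214076e23
HC_KEV_ANGSTROM = 12.398419843
GRID_KEV = np.arange(15, 175, dtype=float)

# NIST mass attenuation anchors, cm^2/g (total, with coherent)
NIST_MU_RHO = {
    "Al": [(15, 7.955), (20, 3.441), (30, 1.128), (40, 0.5685), (50, 0.3681),
           (60, 0.2778), (80, 0.2018), (100, 0.1704), (150, 0.1378), (200, 0.1223)],
    "PMMA": [(15, 1.101), (20, 0.5714), (30, 0.3032), (40, 0.2350), (50, 0.2074),
             (60, 0.1924), (80, 0.1751), (100, 0.1641), (150, 0.1456), (200, 0.1328)],
}
DENSITY = {"Al": 2.699, "PMMA": 1.18, "CdTe": 5.85}

DATA_DIR = pathlib.Path(__file__).resolve().parents[1] / "src" / "pcdspect" / "data"


def loglog_interp(anchors: list[tuple[float, float]], e_kev: np.ndarray) -> np.ndarray:
    e, v = np.array(anchors).T
    return np.exp(np.interp(np.log(e_kev), np.log(e), np.log(v)))


def klein_nishina_cm2_per_electron(e_kev: np.ndarray) -> np.ndarray:
    k = e_kev / 510.99895
    s = ((1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - np.log(1 + 2 * k) / k)
         + np.log(1 + 2 * k) / (2 * k) - (1 + 3 * k) / (1 + 2 * k) ** 2)
    return 2 * np.pi * R_E_CM**2 * s


def photo_mass_atten(z: int, atomic_mass: float, e_kev: np.ndarray) -> np.ndarray:
    import gemmi

    out = np.empty_like(e_kev)
    for i, e in enumerate(e_kev):
        _, fpp = gemmi.cromer_liberman(z=z, energy=float(e) * 1e3)
        lam_cm = HC_KEV_ANGSTROM / e * 1e-8
        out[i] = 2.0 * R_E_CM * lam_cm * fpp * N_A / atomic_mass
    return out


def cdte_mu_rho(e_kev: np.ndarray) -> np.ndarray:
    m_cd, m_te = 112.414, 127.60
    w_cd, w_te = m_cd / (m_cd + m_te), m_te / (m_cd + m_te)
    photo = (w_cd * photo_mass_atten(48, m_cd, e_kev)
             + w_te * photo_mass_atten(52, m_te, e_kev))
    electrons_per_g = N_A * (w_cd * 48 / m_cd + w_te * 52 / m_te)
    return photo + klein_nishina_cm2_per_electron(e_kev) * electrons_per_g


def write_attenuation() -> None:
    for mat in ("Al", "PMMA", "CdTe"):
        if mat == "CdTe":
            mu_rho = cdte_mu_rho(GRID_KEV)
        else:
            mu_rho = loglog_interp(NIST_MU_RHO[mat], GRID_KEV)
        mu_per_mm = mu_rho * DENSITY[mat] / 10.0
        path = DATA_DIR / f"mu_{mat.lower()}.csv"
        with open(path, "w") as fh:
            fh.write(f"# linear attenuation of {mat}, density {DENSITY[mat]} g/cm^3\n")
            fh.write("energy_keV,mu_per_mm\n")
            for e, mu in zip(GRID_KEV, mu_per_mm):
                fh.write(f"{e:.0f},{mu:.6e}\n")
        print("wrote", path)


# Tungsten K lines (keV, relative intensity): Ka2, Ka1, Kb3+Kb1, Kb2
W_LINES = [(57.982, 57.6), (59.318, 100.0), (67.2, 33.8), (69.067, 8.3)]


def write_spectrum(kvp: float = 120.0, total_filtration_mm_al: float = 3.0,
                   char_fraction: float = 0.09) -> None:
    e = np.arange(15.0, kvp + 1.0)
    fluence = np.maximum(kvp / e - 1.0, 0.0)  # Kramers, per keV bin
    mu_al = loglog_interp(NIST_MU_RHO["Al"], e) * DENSITY["Al"] / 10.0
    fluence *= np.exp(-mu_al * total_filtration_mm_al)
    brem_total = fluence.sum()
    weights = np.array([w for _, w in W_LINES])
    weights = weights / weights.sum()
    for (line_e, _), w in zip(W_LINES, weights):
        idx = int(round(line_e)) - 15
        fluence[idx] += char_fraction / (1.0 - char_fraction) * brem_total * w
    fluence /= fluence.sum()
    path = DATA_DIR / "spectrum_120kvp.csv"
    with open(path, "w") as fh:
        fh.write("# 120 kVp tungsten, 3.0 mm Al-equivalent total filtration; "
                 "relative fluence per 1 keV bin\n")
        fh.write("energy_keV,photons_per_bin\n")
        for ei, fi in zip(e, fluence):
            fh.write(f"{ei:.0f},{fi:.8e}\n")
    print("wrote", path, "mean energy %.2f keV" % ((e * fluence).sum() / fluence.sum()))


if __name__ == "__main__":
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    write_attenuation()
    write_spectrum()
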