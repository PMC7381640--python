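"""Physical constants, photon line library and default coefficient tables.

The dose and hazard coefficients are the standard UNSCEAR/OECD values used
throughout environmental radiometry: a dose-rate-to-effective-dose conversion
of 0.7 Sv Gy^-1, indoor/outdoor occupancies of 0.8/0.2, and the linear
soil-activity-to-dose-rate model

    D_soil [nGy h^-1] = 0.43 A_U + 0.666 A_Th + 0.042 A_K   (A in Bq kg^-1).

The photon line library lists, per natural decay series, the gamma lines that
a 3-in NaI(Tl) field spectrometer resolves on a soil spectrum together with
nominal emission probabilities (photons per decay, secular equilibrium
assumed).  The library doubles as the generator's source term and as the
source of the unfolding coefficient tables, so the forward and inverse sides
of the package share one self-consistent physics.
"""

from __future__ import annotations

ELECTRON_REST_MASS_MEV = 0.511

# --- annual effective dose -------------------------------------------------
DOSE_CONVERSION_SV_PER_GY = 0.7
OCCUPANCY_OUTDOOR = 0.2
OCCUPANCY_INDOOR = 0.8
HOURS_PER_YEAR = 8760.0

# D_soil = 0.43 A_U + 0.666 A_Th + 0.042 A_K  (nGy h^-1 per Bq kg^-1)
SOIL_DOSE_COEFF = {"U": 0.43, "Th": 0.666, "K": 0.042}

# Ra_eq = A_U + 1.43 A_Th + 0.077 A_K  (Bq kg^-1)
RA_EQ_WEIGHTS = {"U": 1.0, "Th": 1.43, "K": 0.077}

# H_ex = A_U/370 + A_Th/259 + A_K/4810 <= 1
H_EX_DENOMINATORS = {"U": 370.0, "Th": 259.0, "K": 4810.0}
H_EX_LIMIT = 1.0

# IAEA existing-exposure reference band for total AED, mSv year^-1
REFERENCE_LEVEL_BAND_MSV = (1.0, 20.0)

# --- NaI(Tl) line library ---------------------------------------------------
# (energy MeV, emission probability per decay of the series head, nuclide tag)
NAI_LINE_LIBRARY = {
    "U": (  # 238U series via 214Pb / 214Bi progeny
        (0.352, 0.356, "Pb-214"),
        (0.609, 0.455, "Bi-214"),
        (1.120, 0.149, "Bi-214"),
        (1.765, 0.154, "Bi-214"),
        (2.204, 0.049, "Bi-214"),
        (2.448, 0.0155, "Bi-214"),
    ),
    "Th": (  # 232Th series via 228Ac / 208Tl progeny
        (0.583, 0.304, "Tl-208"),
        (0.911, 0.262, "Ac-228"),
        (0.969, 0.158, "Ac-228"),
        (2.615, 0.356, "Tl-208"),
    ),
    "K": ((1.464, 0.1067, "K-40"),),
}

# Calibration anchor lines for the NaI energy scale
CALIBRATION_LINES_MEV = {"K-40": 1.464, "Tl-208": 2.615}

# Cosmic-ray estimation window (terrestrial gammas end at the 208Tl line)
COSMIC_WINDOW_MEV = (3.0, 3.2)

# --- HPGe soil-assay peak list ----------------------------------------------
# nuclide -> (energy keV, emission probability, series)
HPGE_PEAKS = {
    "Pb-214": (351.9, 0.356, "U"),
    "Bi-214": (609.3, 0.455, "U"),
    "Ac-228": (911.2, 0.262, "Th"),
    "K-40": (1460.8, 0.1067, "K"),
}

# Certified multi-nuclide volume-source lines used for HPGe efficiency
# calibration (keV); the nine-nuclide set standard for U-8 geometry sources.
EFFICIENCY_SOURCE_LINES_KEV = (
    88.0,    # Cd-109
    122.1,   # Co-57
    165.9,   # Ce-139
    320.1,   # Cr-51
    514.0,   # Sr-85
    661.7,   # Cs-137
    834.8,   # Mn-54
    898.0,   # Y-88
    1173.2,  # Co-60
    1332.5,  # Co-60
    1836.1,  # Y-88
)

SERIES = ("U", "Th", "K")


def compton_edge_mev(energy_mev: float) -> float:
    """Compton edge of a photon line: E * 2E/m / (1 + 2E/m)."""
    k = 2.0 * energy_mev / ELECTRON_REST_MASS_MEV
    return energy_mev * k / (1.0 + k)
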