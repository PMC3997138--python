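"""Physical constants and element data used across the package.

Element entries carry atomic number Z, standard atomic weight A (g/mol),
K-edge energy (MeV) and K-shell fluorescence yield omega_K -- everything the
interaction-coefficient model and the kerma bookkeeping need.
"""

from __future__ import annotations

ELECTRON_REST_MEV = 0.510_998_95
"""Electron rest energy m_e c^2 (MeV)."""

CLASSICAL_ELECTRON_RADIUS_CM = 2.817_940_3e-13
"""Classical electron radius r_e (cm)."""

R_E2_BARN = CLASSICAL_ELECTRON_RADIUS_CM**2 * 1e24
"""r_e^2 expressed in barn (1 barn = 1e-24 cm^2)."""

AVOGADRO = 6.022_140_76e23

BARN_CM2 = 1e-24

HBARC_MEV_CM = 1.973_269_80e-11
"""hbar*c in MeV*cm, for photon momentum-transfer computations."""

BOHR_RADIUS_CM = 0.529_177_21e-8

# symbol -> (Z, A, K-edge MeV, K fluorescence yield)
ELEMENTS: dict[str, tuple[int, float, float, float]] = {
    "H": (1, 1.008, 0.0000136, 0.0),
    "C": (6, 12.011, 0.000284, 0.0026),
    "N": (7, 14.007, 0.000410, 0.0043),
    "O": (8, 15.999, 0.000543, 0.0069),
    "Na": (11, 22.990, 0.001072, 0.023),
    "Mg": (12, 24.305, 0.001305, 0.030),
    "Si": (14, 28.085, 0.001839, 0.050),
    "P": (15, 30.974, 0.002146, 0.063),
    "S": (16, 32.06, 0.002472, 0.078),
    "Cl": (17, 35.45, 0.002822, 0.097),
    "Ar": (18, 39.948, 0.003206, 0.118),
    "K": (19, 39.098, 0.003608, 0.140),
    "Ca": (20, 40.078, 0.004038, 0.163),
    "Cr": (24, 51.996, 0.005989, 0.275),
    "Mn": (25, 54.938, 0.006539, 0.308),
    "Fe": (26, 55.845, 0.007112, 0.340),
    "Ni": (28, 58.693, 0.008333, 0.406),
    "Mo": (42, 95.95, 0.020000, 0.765),
    "Ir": (77, 192.217, 0.076111, 0.958),
}

# name -> (density g/cm^3, {element: mass fraction})
# Tissue compositions follow the ICRU-44 reference adult values; steel is
# AISI 316L, the usual microSelectron capsule alloy.
MATERIALS: dict[str, tuple[float, dict[str, float]]] = {
    "water": (1.000, {"H": 0.111894, "O": 0.888106}),
    "cortical_bone": (
        1.920,
        {
            "H": 0.034, "C": 0.155, "N": 0.042, "O": 0.435,
            "Na": 0.001, "Mg": 0.002, "P": 0.103, "S": 0.003, "Ca": 0.225,
        },
    ),
    "inflated_lung": (
        0.260,
        {
            "H": 0.103, "C": 0.105, "N": 0.031, "O": 0.749,
            "Na": 0.002, "P": 0.002, "S": 0.003, "Cl": 0.003, "K": 0.002,
        },
    ),
    "polystyrene": (1.040, {"H": 0.077418, "C": 0.922582}),
    "stainless_steel": (
        8.000,
        {"Fe": 0.655, "Cr": 0.17, "Ni": 0.12, "Mo": 0.025, "Mn": 0.02, "Si": 0.01},
    ),
    "iridium": (22.420, {"Ir": 1.0}),
    "dry_air": (
        1.205e-3,
        {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012828},
    ),
}
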