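"""Published summary values of the passive-vs-active proton study.

These constants are the *inputs* the re-analysis operates on: the
linear-quadratic fit parameters of the clonogenic survival curves (with
their printed standard errors and R^2), the dose-averaged LET per particle
species at each position/mode, the neutron-class fractions from the
beam-line Monte Carlo, and the beam configuration. Positions: 1 = 2 cm
depth (entrance plateau), 2 = 23.6 cm (Bragg peak); modes: PBS (active
scanning) and DS (passive double scattering); reference radiation Co-60.
"""

from __future__ import annotations

from .beam import BeamConfig
from .survival import SurvivalCurveFit

#: Published LQ parameters: alpha, sigma_alpha (Gy^-1), beta, sigma_beta
#: (Gy^-2), R^2. Covariances were not published and are taken as zero.
REFERENCE_LQ: dict[str, SurvivalCurveFit] = {
    "Co60": SurvivalCurveFit(0.17, 0.03, 3.25e-2, 9.99e-3, 0.0, 0.99, "Co60"),
    "PBS1": SurvivalCurveFit(0.26, 0.05, 1.13e-3, 2.77e-2, 0.0, 1.00, "PBS1"),
    "PBS2": SurvivalCurveFit(0.20, 0.11, 3.95e-4, 1.27e-2, 0.0, 1.00, "PBS2"),
    "DS1": SurvivalCurveFit(0.13, 0.06, 2.87e-2, 9.49e-3, 0.0, 1.00, "DS1"),
    "DS2": SurvivalCurveFit(0.12, 0.10, 1.21e-2, 4.99e-3, 0.0, 1.00, "DS2"),
}

#: Dose-averaged LET (keV/um) per species, by (mode, position).
LETD_TARGETS: dict[tuple[str, int], dict[str, float]] = {
    ("PBS", 1): {
        "protons": 0.45,
        "electrons": 0.28,
        "positrons": 0.19,
        "deuterons": 5.74,
        "tritons": 7.54,
        "helions": 32.00,
        "alphas": 51.79,
    },
    ("DS", 1): {
        "protons": 0.45,
        "electrons": 0.28,
        "positrons": 0.19,
        "deuterons": 5.57,
        "tritons": 8.27,
        "helions": 32.80,
        "alphas": 51.76,
    },
    ("PBS", 2): {
        "protons": 3.17,
        "electrons": 0.19,
        "positrons": 0.18,
        "deuterons": 8.68,
        "tritons": 8.08,
        "helions": 59.73,
        "alphas": 102.58,
    },
    ("DS", 2): {
        "protons": 3.43,
        "electrons": 0.19,
        "positrons": 0.18,
        "deuterons": 7.40,
        "tritons": 11.16,
        "helions": 42.79,
        "alphas": 103.00,
    },
}

#: Published all-particles dose-averaged LET (keV/um) by (mode, position).
LETD_ALL_PARTICLES: dict[tuple[str, int], float] = {
    ("PBS", 1): 0.44,
    ("DS", 1): 0.44,
    ("PBS", 2): 3.11,
    ("DS", 2): 3.34,
}

#: Neutron-class percentages of the total production (classes <=1, 1-50,
#: >=50 MeV) by (mode, position), as printed in the beam-line summaries.
NEUTRON_CLASS_PCT: dict[tuple[str, int], tuple[float, float, float]] = {
    ("PBS", 1): (1.00e2, 5.99e-6, 1.56e-6),
    ("DS", 1): (1.00e2, 6.03e-6, 1.24e-6),
    ("PBS", 2): (1.00e2, 4.52e-5, 9.09e-6),
    ("DS", 2): (1.00e2, 4.61e-5, 9.27e-6),
}


def neutron_class_fractions(mode: str, position: int) -> tuple[float, ...]:
    """Neutron class fractions (normalized to sum 1) for a mode/position."""
    pct = NEUTRON_CLASS_PCT[(mode, position)]
    total = sum(pct)
    return tuple(p / total for p in pct)


#: Beam configurations: the active-scanning beam energy pairs with the
#: passive mode's 23.9 g/cm^2 clinical range; the passive mode used a
#: 1.5 g/cm^2 modulation.
PBS_BEAM = BeamConfig(nominal_energy=190.6, mode="PBS")
DS_RANGE_G_CM2 = 23.9
DS_MODULATION_G_CM2 = 1.5

#: Sample depths in water (cm) of the two irradiation positions.
POSITION_DEPTH_CM: dict[int, float] = {1: 2.0, 2: 23.6}

#: Doses (Gy) applied with the proton beams and with the Co-60 reference.
PROTON_DOSES_GY = (1.0, 3.0, 5.0)
CO60_DOSES_GY = (1.0, 2.0, 3.0, 4.0, 5.0)
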