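"""Simplified analytic proton-beam physics in water.

A pedagogical stand-in for a Monte Carlo transport calculation, covering
only the pieces the analysis pipeline needs:

* Bragg-Kleeman range-energy relation R = a * E**p with water constants
  a = 0.0022 cm MeV^-p, p = 1.77, which pairs a 190.6 MeV beam with a
  23.9 g/cm^2 clinical range;
* its inverse for the residual energy at depth;
* the Bethe electronic stopping power of protons in water (mean excitation
  energy I = 75 eV, no shell or density corrections) as an unrestricted
  LET proxy;
* a continuous-slowing-down depth-dose curve convolved with Gaussian range
  straggling, reproducing the plateau-vs-peak shape of a pristine Bragg
  curve.

No nuclear interactions, secondary-particle buildup, lateral profiles or
scattering-nozzle modelling are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

# Bragg-Kleeman water constants
BK_A = 0.0022  # cm MeV^-p
BK_P = 1.77

# Bethe formula constants
_K = 0.307075  # MeV cm^2 / mol
_ME_C2 = 0.51099895  # MeV
_MP_C2 = 938.27208  # MeV
_Z_OVER_A_WATER = 0.55509  # mol/g
_I_WATER = 75.0e-6  # MeV
_RHO_WATER = 1.0  # g/cm^3

ENERGY_WINDOW = (1.0, 250.0)  # MeV validity window for the Bethe proxy


def bragg_kleeman_range(energy):
    """CSDA range in water (cm) of a proton of the given energy (MeV)."""
    e = np.asarray(energy, dtype=float)
    if np.any(e < 0):
        raise ValueError("energy must be non-negative")
    r = BK_A * e**BK_P
    return float(r) if r.ndim == 0 else r


def energy_at_depth(energy0: float, depth) -> float | np.ndarray:
    """Residual proton energy (MeV) at a water depth (cm).

    Inverse Bragg-Kleeman: E(z) = ((R - z)/a)**(1/p). Decreasing in depth,
    with E(0) = energy0 and E(R) = 0.
    """
    r = bragg_kleeman_range(energy0)
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    if np.any(z > r * (1 + 1e-12)):
        raise ValueError(f"depth exceeds range {r:.4g} cm")
    e = (np.clip(r - z, 0.0, None) / BK_A) ** (1.0 / BK_P)
    return float(e) if e.ndim == 0 else e


def stopping_power_water(energy):
    """Electronic stopping power of protons in water, in keV/um.

    Bethe formula with I = 75 eV, valid for 1-250 MeV; used as the
    unrestricted-LET proxy. Monotone decreasing over the window.
    """
    e = np.asarray(energy, dtype=float)
    lo, hi = ENERGY_WINDOW
    if np.any((e < lo) | (e > hi)):
        raise ValueError(f"energy outside Bethe validity window {ENERGY_WINDOW} MeV")
    gamma = 1.0 + e / _MP_C2
    beta2 = 1.0 - 1.0 / gamma**2
    arg = 2.0 * _ME_C2 * beta2 * gamma**2 / _I_WATER
    s = _K * _Z_OVER_A_WATER * _RHO_WATER / beta2 * (np.log(arg) - beta2)
    s_kev_um = s * 0.1  # MeV/cm -> keV/um
    return float(s_kev_um) if s_kev_um.ndim == 0 else s_kev_um


def default_straggling_sigma(range_cm: float) -> float:
    """Gaussian range-straggling width (cm): 0.012 * R**0.935."""
    return 0.012 * range_cm**0.935


@dataclass(frozen=True)
class BeamConfig:
    """A delivery-mode beam: nominal energy with its derived water range."""

    nominal_energy: float  # MeV
    mode: str = "PBS"
    modulation: float = 0.0  # g/cm^2, metadata only

    def __post_init__(self) -> None:
        if self.nominal_energy <= 0:
            raise ValueError("nominal_energy must be positive")

    @property
    def range_water(self) -> float:
        return bragg_kleeman_range(self.nominal_energy)


@dataclass(frozen=True)
class DepthDoseCurve:
    """Percentage depth-dose curve on a regular depth grid (max = 100)."""

    depth: np.ndarray  # cm
    dose: np.ndarray  # %, max normalized to 100
    positions: tuple[float, ...] = ()  # marked sample depths, cm

    @property
    def peak_depth(self) -> float:
        return float(self.depth[np.argmax(self.dose)])

    def at(self, z: float) -> float:
        return float(np.interp(z, self.depth, self.dose))


def depth_dose_curve(
    energy0: float,
    grid_step: float = 0.01,
    straggling_sigma: float | None = None,
    positions: tuple[float, ...] = (),
) -> DepthDoseCurve:
    """Pristine Bragg depth-dose curve by CSDA deposition + range straggling.

    The energy lost in each depth bin, E(z_i) - E(z_i+1), gives the raw
    CSDA dose profile (finite even at the stopping point); convolution with
    a Gaussian of width `straggling_sigma` (default 0.012 * R**0.935 cm)
    models range straggling. Normalized to max 100%.
    """
    if energy0 <= 0:
        raise ValueError("energy0 must be positive")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    r = bragg_kleeman_range(energy0)
    sigma = default_straggling_sigma(r) if straggling_sigma is None else straggling_sigma
    if sigma < 0:
        raise ValueError("straggling_sigma must be >= 0")
    zmax = r + max(4.0 * sigma, 10 * grid_step)
    edges = np.arange(0.0, zmax + grid_step, grid_step)
    e_edges = (np.clip(r - edges, 0.0, None) / BK_A) ** (1.0 / BK_P)
    dose = e_edges[:-1] - e_edges[1:]  # energy deposited per bin
    if sigma > 0:
        dose = gaussian_filter1d(dose, sigma / grid_step, mode="constant")
    centers = 0.5 * (edges[:-1] + edges[1:])
    dose = 100.0 * dose / dose.max()
    return DepthDoseCurve(depth=centers, dose=dose, positions=tuple(positions))


def let_vs_depth(energy0: float, depths) -> np.ndarray:
    """Unrestricted-LET proxy (keV/um) of the primary beam at given depths.

    Residual energies below the Bethe window are clipped to its lower edge,
    so the last fraction of a millimetre before the stopping point is
    reported at the 1 MeV stopping power; depths beyond the range are
    clipped to the stopping point.
    """
    r = bragg_kleeman_range(energy0)
    z = np.clip(np.atleast_1d(np.asarray(depths, dtype=float)), 0.0, r)
    e = np.atleast_1d(energy_at_depth(energy0, z))
    e = np.clip(e, ENERGY_WINDOW[0], ENERGY_WINDOW[1])
    return stopping_power_water(e)
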