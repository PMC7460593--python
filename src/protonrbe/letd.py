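"""Dose-averaged LET over particle spectra and ICRP-103 neutron weighting.

A charged-particle field at a point in a phantom is summarized by, per
species, a list of (LET value, dose weight) pairs. The dose-averaged LET is
the dose-weighted mean of the component LET values,

    LET_d = sum_i LET_i * D_i / sum_i D_i,

which is invariant to the overall scale of the weights and bounded by the
component extremes. Neutrons carry no LET; they are instead categorized by
energy (<=1, 1-50, >=50 MeV) and weighted by the ICRP Publication 103
continuous radiation weighting factor w_R(E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SPECIES = (
    "protons",
    "electrons",
    "positrons",
    "deuterons",
    "tritons",
    "helions",
    "alphas",
)

ALL_PARTICLES = "all particles"

#: Neutron energy class boundaries in MeV; intervals are half-open
#: [0,1), [1,50), [50,inf) — boundary atoms go to the lower class.
NEUTRON_CLASS_EDGES = (1.0, 50.0)
NEUTRON_CLASS_LABELS = ("<=1 MeV", "1-50 MeV", ">=50 MeV")


@dataclass(frozen=True)
class LETSpectrum:
    """Per-species LET spectrum: component LET values with dose weights."""

    species: str
    let: np.ndarray  # keV/um, > 0
    dose_weight: np.ndarray  # arbitrary dose units, >= 0
    position: int | None = None
    mode: str | None = None

    def __post_init__(self) -> None:
        let = np.atleast_1d(np.asarray(self.let, dtype=float))
        w = np.atleast_1d(np.asarray(self.dose_weight, dtype=float))
        object.__setattr__(self, "let", let)
        object.__setattr__(self, "dose_weight", w)
        if let.shape != w.shape:
            raise ValueError("let and dose_weight must have equal length")
        if let.size == 0:
            raise ValueError("spectrum must have at least one component")
        if np.any(let <= 0):
            raise ValueError("LET values must be positive")
        if np.any(w < 0):
            raise ValueError("dose weights must be non-negative")

    @property
    def total_dose(self) -> float:
        return float(self.dose_weight.sum())


@dataclass(frozen=True)
class LETdResult:
    """Dose-averaged LET for one species (or the combined field)."""

    species: str
    letd: float  # keV/um
    position: int | None = None
    mode: str | None = None


def dose_average_let(spectrum: LETSpectrum) -> LETdResult:
    """Dose-averaged LET of one spectrum: sum(LET_i D_i) / sum(D_i)."""
    total = spectrum.dose_weight.sum()
    if total <= 0:
        raise ValueError("all dose weights are zero")
    letd = float(np.dot(spectrum.let, spectrum.dose_weight) / total)
    return LETdResult(spectrum.species, letd, spectrum.position, spectrum.mode)


def combine_species(spectra) -> LETdResult:
    """Dose-averaged LET of the combined multi-species field.

    Components are concatenated across species (species with zero total
    weight contribute nothing) and the dose-weighted mean taken over the
    pooled components. All spectra must share position and mode.
    """
    spectra = list(spectra)
    if not spectra:
        raise ValueError("empty spectrum collection")
    tags = {(s.position, s.mode) for s in spectra}
    if len(tags) > 1:
        raise ValueError(f"spectra mix positions/modes: {sorted(tags, key=str)}")
    let = np.concatenate([s.let for s in spectra])
    w = np.concatenate([s.dose_weight for s in spectra])
    pooled = LETSpectrum(
        ALL_PARTICLES, let, w, spectra[0].position, spectra[0].mode
    )
    return dose_average_let(pooled)


def icrp103_neutron_wr(energy):
    """ICRP-103 continuous neutron radiation weighting factor w_R(E).

    Piecewise log-Gaussian in energy E (MeV):

        E < 1:        2.5 + 18.2 exp(-(ln E)^2 / 6)
        1 <= E <= 50: 5.0 + 17.0 exp(-(ln 2E)^2 / 6)
        E > 50:       2.5 + 3.25 exp(-(ln 0.04E)^2 / 6)

    Continuous at the branch points, bounded in [2.5, ~20.7], and tending
    to 2.5 in both the thermal and the ultra-relativistic limits.
    """
    e = np.asarray(energy, dtype=float)
    scalar = e.ndim == 0
    e = np.atleast_1d(e)
    if np.any(e <= 0):
        raise ValueError("neutron energy must be positive (MeV)")
    wr = np.empty_like(e)
    lo = e < 1.0
    hi = e > 50.0
    mid = ~(lo | hi)
    wr[lo] = 2.5 + 18.2 * np.exp(-np.log(e[lo]) ** 2 / 6.0)
    wr[mid] = 5.0 + 17.0 * np.exp(-np.log(2.0 * e[mid]) ** 2 / 6.0)
    wr[hi] = 2.5 + 3.25 * np.exp(-np.log(0.04 * e[hi]) ** 2 / 6.0)
    return float(wr[0]) if scalar else wr


@dataclass(frozen=True)
class NeutronSpectrum:
    """Neutron energy/weight histogram at one position and mode."""

    energy: np.ndarray  # MeV, > 0
    weight: np.ndarray  # relative counts, >= 0
    position: int | None = None
    mode: str | None = None

    def __post_init__(self) -> None:
        e = np.atleast_1d(np.asarray(self.energy, dtype=float))
        w = np.atleast_1d(np.asarray(self.weight, dtype=float))
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "weight", w)
        if e.shape != w.shape:
            raise ValueError("energy and weight must have equal length")
        if e.size == 0:
            raise ValueError("neutron spectrum is empty")
        if np.any(e <= 0):
            raise ValueError("neutron energies must be positive")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class NeutronClassification:
    """Per-class neutron totals, percentages and mean weighting factor."""

    counts: dict = field(default_factory=dict)  # label -> summed weight
    percentages: dict = field(default_factory=dict)  # label -> % of total
    total: float = 0.0
    mean_wr: float = 0.0
    position: int | None = None
    mode: str | None = None


def classify_neutrons(spectrum: NeutronSpectrum) -> NeutronClassification:
    """Categorize a neutron spectrum into the three ICRP-103 energy classes.

    Returns summed weights and percentages per class ([0,1), [1,50),
    [50,inf) MeV; boundary values to the lower class) and the
    weight-averaged w_R of the whole spectrum.
    """
    total = float(spectrum.weight.sum())
    if total <= 0:
        raise ValueError("neutron spectrum has zero total weight")
    # np.digitize(right=True): e <= 1 -> 0, 1 < e <= 50 -> 1, e > 50 -> 2
    idx = np.digitize(spectrum.energy, NEUTRON_CLASS_EDGES, right=True)
    counts = {}
    for k, label in enumerate(NEUTRON_CLASS_LABELS):
        counts[label] = float(spectrum.weight[idx == k].sum())
    pct = {lab: 100.0 * c / total for lab, c in counts.items()}
    mean_wr = float(
        np.average(icrp103_neutron_wr(spectrum.energy), weights=spectrum.weight)
    )
    return NeutronClassification(
        counts=counts,
        percentages=pct,
        total=total,
        mean_wr=mean_wr,
        position=spectrum.position,
        mode=spectrum.mode,
    )
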