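"""Synthetic generators for every input the analysis pipeline consumes.

Real counterparts of these data are colony counts from 6-well clonogenic
plates, flow-cytometry apoptosis percentages, micronucleus scores in
binucleated cells, per-nucleus gammaH2AX focus counts, and Monte-Carlo
particle spectra. The generators reproduce their first- and second-moment
structure under simple, documented noise families (Poisson counting noise,
binomial percentages), deterministically under a seed, so the downstream
statistics can be exercised and calibrated without any external data.

Distributional choices, defaults and what is deliberately *not* emulated
(cell-cycle effects, repair kinetics, imaging artefacts, true Monte-Carlo
spectral shapes) are laid out in the methods documentation.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import EndpointKind, ExperimentDesign, Mode, TrueLQ, condition_label
from .letd import LETSpectrum, NeutronSpectrum

__all__ = [
    "generate_colony_counts",
    "generate_reference_colony_counts",
    "generate_endpoint_data",
    "generate_mn_cell_counts",
    "generate_let_spectrum",
    "solve_dose_shares",
    "generate_neutron_spectrum",
    "DEFAULT_NEUTRON_CLASS_RANGES",
    "DEFAULT_HEAVY_SHARES",
]

COLONY_COLUMNS = ["mode", "position", "dose_gy", "run", "well", "seeded", "colonies"]
ENDPOINT_COLUMNS = [
    "endpoint",
    "mode",
    "position",
    "dose_gy",
    "time_h",
    "run",
    "replicate",
    "value",
]


def generate_colony_counts(
    design: ExperimentDesign,
    truth: Mapping[str, TrueLQ],
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate per-well colony counts for every condition of a design.

    Colony counts are Poisson around
    ``seeded * PE_run * exp(-alpha*D - beta*D^2)`` and clipped at the
    seeded cell number; every run includes 0 Gy control wells. With
    ``design.pe_jitter_sigma > 0`` each run's plating efficiency gets an
    independent multiplicative log-normal factor (median 1).

    Parameters
    ----------
    truth : mapping
        Condition label (e.g. ``"PBS1"``) -> :class:`TrueLQ`. A missing
        condition raises.
    seed : int, optional
        Overrides ``design.seed``.

    Returns
    -------
    DataFrame with columns ``mode, position, dose_gy, run, well, seeded,
    colonies``; byte-identical for identical (design, truth, seed).
    """
    for mode in design.modes:
        for position in design.positions:
            if condition_label(mode, position) not in truth:
                raise KeyError(
                    f"no LQ truth for condition {condition_label(mode, position)}"
                )
    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for mode in design.modes:
        for position in design.positions:
            lq = truth[condition_label(mode, position)]
            for run in range(1, design.runs + 1):
                pe = design.plating_efficiency
                if design.pe_jitter_sigma > 0:
                    pe *= rng.lognormal(0.0, design.pe_jitter_sigma)
                pe = min(pe, 1.0)
                for dose in design.all_doses():
                    seeded = design.seeded_for(dose)
                    mean = seeded * pe * float(lq.survival(dose))
                    counts = np.minimum(
                        rng.poisson(mean, size=design.wells_per_condition), seeded
                    )
                    for well, c in enumerate(counts, start=1):
                        rows.append(
                            (
                                Mode(mode).value,
                                int(position),
                                float(dose),
                                run,
                                well,
                                seeded,
                                int(c),
                            )
                        )
    return pd.DataFrame(rows, columns=COLONY_COLUMNS)


def generate_reference_colony_counts(
    lq: TrueLQ,
    doses: Sequence[float] = (1.0, 2.0, 3.0, 4.0, 5.0),
    runs: int = 2,
    wells_per_condition: int = 6,
    seeded_cells: Mapping[float, int] | int = 2000,
    plating_efficiency: float = 0.30,
    seed: int = 0,
    label: str = "Co60",
) -> pd.DataFrame:
    """Colony counts for a reference radiation without a beam position.

    Same Poisson model as :func:`generate_colony_counts`; the ``mode``
    column carries `label` and ``position`` is 0 (no beam-line depth).
    """
    rng = np.random.default_rng(seed)
    all_doses = tuple(sorted({0.0} | {float(d) for d in doses}))

    def seeded_for(dose: float) -> int:
        if isinstance(seeded_cells, Mapping):
            below = [d for d in seeded_cells if d <= dose]
            key = max(below) if below else min(seeded_cells)
            return int(seeded_cells[key])
        return int(seeded_cells)

    rows = []
    for run in range(1, runs + 1):
        for dose in all_doses:
            seeded = seeded_for(dose)
            mean = seeded * plating_efficiency * float(lq.survival(dose))
            counts = np.minimum(rng.poisson(mean, size=wells_per_condition), seeded)
            for well, c in enumerate(counts, start=1):
                rows.append((label, 0, float(dose), run, well, seeded, int(c)))
    return pd.DataFrame(rows, columns=COLONY_COLUMNS)


#: Default effect-model parameters per endpoint kind. Chosen to sit in the
#: ranges the assays are used for: ~25-35 foci/nucleus at 1 Gy, a few
#: percent baseline apoptosis rising linearly with dose, and an LQ-shaped
#: micronucleus induction read out at 3 and 5 Gy.
DEFAULT_ENDPOINT_PARAMS: dict[EndpointKind, dict[str, float]] = {
    EndpointKind.APOPTOSIS_TOTAL_PCT: {
        "control_pct": 5.0,  # baseline total apoptosis, %
        "slope_pct_per_gy": 2.0,  # excess % per Gy
        "n_cells": 1000,  # cells scored per replicate
    },
    EndpointKind.BNC_WITH_MN_PCT: {
        "p0": 0.01,  # baseline fraction of BNC with >=1 MN
        "a_per_gy": 0.02,
        "b_per_gy2": 0.004,
        "n_bnc": 400,  # BNC scored per replicate
    },
    EndpointKind.MN_FREQUENCY: {
        "lambda0": 0.01,  # background MN per BNC
        "a_per_gy": 0.03,
        "b_per_gy2": 0.006,
        "n_bnc": 400,
    },
    EndpointKind.FOCI_PER_NUCLEUS: {
        "background": 0.5,  # spontaneous foci per nucleus
        "per_gy": 30.0,  # foci per nucleus per Gy (25-35 at 1 Gy)
        "n_nuclei": 500,
    },
}

#: Time points (h) at which apoptosis is scored; other endpoints use 0.
APOPTOSIS_TIME_POINTS = (24.0, 48.0, 96.0)


def _endpoint_mean(kind: EndpointKind, dose: float, p: Mapping[str, float]) -> float:
    if kind is EndpointKind.APOPTOSIS_TOTAL_PCT:
        return p["control_pct"] + p["slope_pct_per_gy"] * dose
    if kind is EndpointKind.BNC_WITH_MN_PCT:
        return 100.0 * min(p["p0"] + p["a_per_gy"] * dose + p["b_per_gy2"] * dose**2, 1.0)
    if kind is EndpointKind.MN_FREQUENCY:
        return p["lambda0"] + p["a_per_gy"] * dose + p["b_per_gy2"] * dose**2
    if kind is EndpointKind.FOCI_PER_NUCLEUS:
        return p["background"] + p["per_gy"] * dose
    raise ValueError(f"unknown endpoint kind: {kind!r}")


def generate_endpoint_data(
    design: ExperimentDesign,
    kind: EndpointKind | str,
    params: Mapping[str, float] | None = None,
    doses: Sequence[float] | None = None,
    replicates: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate replicate-level endpoint measurements.

    Noise families by kind:

    * percentages (apoptosis, %BNC-with-MN): binomial over the number of
      scored cells, reported as 100 * k/n;
    * counts (MN frequency, foci per nucleus): Poisson per cell, reported
      as the per-cell mean over the scored population.

    Doses default to ``(0,) + design.doses`` except for foci (0 and 1 Gy,
    matching the single-dose use of that assay) and micronuclei (0, 3 and
    5 Gy). Apoptosis is generated at each of the 24/48/96 h time points.
    """
    kind = EndpointKind(kind)
    p = dict(DEFAULT_ENDPOINT_PARAMS[kind])
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown parameters for {kind.value}: {sorted(unknown)}")
        p.update(params)
    if any(v < 0 for v in p.values()):
        raise ValueError("endpoint model parameters must be non-negative")
    if doses is None:
        if kind is EndpointKind.FOCI_PER_NUCLEUS:
            doses = (0.0, 1.0)
        elif kind in (EndpointKind.MN_FREQUENCY, EndpointKind.BNC_WITH_MN_PCT):
            doses = (0.0, 3.0, 5.0)
        else:
            doses = design.all_doses()
    times = APOPTOSIS_TIME_POINTS if kind is EndpointKind.APOPTOSIS_TOTAL_PCT else (0.0,)

    rng = np.random.default_rng(design.seed if seed is None else seed)
    rows = []
    for mode in design.modes:
        for position in design.positions:
            for dose in doses:
                for t in times:
                    mean = _endpoint_mean(kind, float(dose), p)
                    for run in range(1, design.runs + 1):
                        for rep in range(1, replicates + 1):
                            if kind in (
                                EndpointKind.APOPTOSIS_TOTAL_PCT,
                                EndpointKind.BNC_WITH_MN_PCT,
                            ):
                                n = int(p["n_cells" if kind is EndpointKind.APOPTOSIS_TOTAL_PCT else "n_bnc"])
                                prob = min(mean / 100.0, 1.0)
                                value = 100.0 * rng.binomial(n, prob) / n
                            else:
                                n = int(p["n_bnc" if kind is EndpointKind.MN_FREQUENCY else "n_nuclei"])
                                value = float(rng.poisson(mean, size=n).mean())
                            rows.append(
                                (
                                    kind.value,
                                    Mode(mode).value,
                                    int(position),
                                    float(dose),
                                    float(t),
                                    run,
                                    rep,
                                    float(value),
                                )
                            )
    return pd.DataFrame(rows, columns=ENDPOINT_COLUMNS)


def generate_mn_cell_counts(
    dose: float,
    n_bnc: int = 400,
    params: Mapping[str, float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-binucleated-cell micronucleus counts, Poisson with LQ-in-dose mean."""
    p = dict(DEFAULT_ENDPOINT_PARAMS[EndpointKind.MN_FREQUENCY])
    if params:
        p.update(params)
    if n_bnc < 1:
        raise ValueError("n_bnc must be >= 1")
    mean = p["lambda0"] + p["a_per_gy"] * dose + p["b_per_gy2"] * dose**2
    return np.random.default_rng(seed).poisson(mean, size=n_bnc)


#: Dose shares assigned to the rare species when constructing a
#: multi-species LET field; the proton/electron split is then solved so
#: the combined dose-averaged LET hits the all-particles target.
DEFAULT_HEAVY_SHARES: Mapping[str, float] = {
    "positrons": 2e-3,
    "deuterons": 1e-3,
    "tritons": 5e-4,
    "helions": 2e-4,
    "alphas": 1e-4,
}


def solve_dose_shares(
    species_letd: Mapping[str, float],
    target_all: float,
    heavy_shares: Mapping[str, float] = DEFAULT_HEAVY_SHARES,
) -> dict[str, float]:
    """Dose shares per species whose weighted LET mean equals `target_all`.

    Shares of every species except protons and electrons are fixed (small,
    from `heavy_shares`); the proton/electron split absorbs the remainder
    and is solved in closed form. Raises if the required split leaves
    either share negative (target infeasible for these component values).
    """
    if "protons" not in species_letd or "electrons" not in species_letd:
        raise ValueError("need at least proton and electron LET_d values")
    fixed = {
        s: heavy_shares.get(s, 0.0)
        for s in species_letd
        if s not in ("protons", "electrons")
    }
    rest = 1.0 - sum(fixed.values())
    heavy_term = sum(species_letd[s] * w for s, w in fixed.items())
    lp, le = species_letd["protons"], species_letd["electrons"]
    if lp == le:
        we = rest / 2.0
    else:
        # target = lp*(rest - we) + le*we + heavy_term
        we = (lp * rest + heavy_term - target_all) / (lp - le)
    wp = rest - we
    if we < 0 or wp < 0:
        raise ValueError(
            f"all-particles target {target_all} infeasible for the given "
            f"per-species LET_d values"
        )
    return {"protons": wp, "electrons": we, **fixed}


def generate_let_spectrum(
    targets: Mapping[str, float],
    dose_shares: Mapping[str, float],
    n_components: int = 50,
    spread: float = 0.25,
    seed: int = 0,
    position: int | None = None,
    mode: str | None = None,
    tol: float = 5e-3,
) -> dict[str, LETSpectrum]:
    """Construct per-species LET spectra with prescribed dose-averaged LET.

    Each species gets `n_components` log-normally scattered LET lines
    (geometric spread ``exp(spread)``) with log-normal dose weights, then a
    single multiplicative rescale of the LET axis pins the dose-averaged
    LET exactly to the target; total dose weight equals the species' share.

    Parameters
    ----------
    targets : mapping species -> LET_d target (keV/um), > 0
    dose_shares : mapping species -> share of total dose, summing to 1
    tol : verification tolerance on the achieved dose average (relative)
    """
    if any(t <= 0 for t in targets.values()):
        raise ValueError("LET_d targets must be positive")
    share_sum = sum(dose_shares.values())
    if not np.isclose(share_sum, 1.0, atol=1e-9):
        raise ValueError(f"dose shares must sum to 1 (got {share_sum})")
    if set(targets) - set(dose_shares):
        raise ValueError("every target species needs a dose share")
    rng = np.random.default_rng(seed)
    spectra = {}
    for species in targets:
        target = targets[species]
        let = target * rng.lognormal(0.0, spread, size=n_components)
        w = rng.lognormal(0.0, 0.5, size=n_components)
        achieved = float(np.dot(let, w) / w.sum())
        let *= target / achieved  # pin the dose average exactly
        w *= dose_shares[species] / w.sum()
        spec = LETSpectrum(species, let, w, position=position, mode=mode)
        got = float(np.dot(spec.let, spec.dose_weight) / spec.dose_weight.sum())
        if abs(got - target) > tol * target:  # pragma: no cover - construction guard
            raise RuntimeError(f"spectrum construction missed target for {species}")
        spectra[species] = spec
    return spectra


#: Energy sampling range (MeV) per ICRP class. The lowest class is sampled
#: in the thermal-to-epithermal region, reflecting beam-line neutron fields
#: whose low-energy component is overwhelmingly thermalized (w_R ~ 2.5);
#: only the class fractions are externally constrained.
DEFAULT_NEUTRON_CLASS_RANGES: tuple[tuple[float, float], ...] = (
    (1e-9, 1e-3),
    (1.0, 50.0),
    (50.0, 200.0),
)


def generate_neutron_spectrum(
    fractions: Sequence[float],
    n: int,
    seed: int = 0,
    class_ranges: Sequence[tuple[float, float]] = DEFAULT_NEUTRON_CLASS_RANGES,
    position: int | None = None,
    mode: str | None = None,
) -> NeutronSpectrum:
    """Sample a neutron energy spectrum with prescribed ICRP-class fractions.

    Class membership is multinomial with the given fractions; energies are
    log-uniform within each class's sampling range. Weights are unit counts.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.size != len(class_ranges):
        raise ValueError(f"expected {len(class_ranges)} class fractions")
    if np.any(fr < 0):
        raise ValueError("fractions must be non-negative")
    if fr.sum() <= 0:
        raise ValueError("fractions must not all be zero")
    if n < 1:
        raise ValueError("n must be >= 1")
    fr = fr / fr.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, fr)
    energies = []
    for (lo, hi), k in zip(class_ranges, counts):
        if k == 0:
            continue
        if not 0 < lo < hi:
            raise ValueError("class ranges must satisfy 0 < lo < hi")
        energies.append(np.exp(rng.uniform(np.log(lo), np.log(hi), size=k)))
    e = np.concatenate(energies)
    return NeutronSpectrum(e, np.ones_like(e), position=position, mode=mode)
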