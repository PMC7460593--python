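"""Experiment-design and ground-truth domain types.

The study layout emulated here is an in vitro comparison of two proton
delivery modes — pencil beam scanning (PBS, active) and double scattering
(DS, passive) — with cell samples irradiated at two depths along the Bragg
curve: the entrance plateau (position 1) and the Bragg peak (position 2).
Clonogenic survival is assayed in 6-well plates across two independent
experimental runs, with reference curves from a Co-60 gamma source.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping


class Mode(str, enum.Enum):
    """Proton delivery mode: active scanning (PBS) or passive scattering (DS)."""

    PBS = "PBS"
    DS = "DS"


class Position(enum.IntEnum):
    """Sample depth along the Bragg curve."""

    PLATEAU = 1
    PEAK = 2


class EndpointKind(str, enum.Enum):
    """Biological endpoints scored alongside clonogenic survival."""

    APOPTOSIS_TOTAL_PCT = "apoptosis_total_pct"
    BNC_WITH_MN_PCT = "bnc_with_mn_pct"
    MN_FREQUENCY = "mn_frequency"
    FOCI_PER_NUCLEUS = "foci_per_nucleus"


def condition_label(mode: Mode | str, position: int) -> str:
    """Compact condition label, e.g. ``PBS1`` for PBS at the plateau.

    Position 0 labels a reference radiation without a beam-line position
    (e.g. ``Co60``), in which case the mode string alone is the label.
    """
    try:
        m = Mode(mode).value
    except ValueError:
        m = str(mode)
    p = int(position)
    return m if p == 0 else f"{m}{p}"


@dataclass(frozen=True)
class TrueLQ:
    """Generative linear-quadratic survival parameters.

    Survival after dose ``D`` (Gy) is ``exp(-alpha*D - beta*D**2)``.

    Parameters
    ----------
    alpha : float
        Linear coefficient, Gy^-1. Must be >= 0.
    beta : float
        Quadratic coefficient, Gy^-2. Must be >= 0.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")

    def survival(self, dose):
        import numpy as np

        d = np.asarray(dose, dtype=float)
        return np.exp(-self.alpha * d - self.beta * d * d)


#: Default per-dose seeding, chosen so that the expected colony count stays
#: in a countable range (~100 per well) as survival drops with dose —
#: mirroring seeding "according to the expected cell survival".
DEFAULT_SEEDED: Mapping[float, int] = {0.0: 330, 1.0: 500, 3.0: 1500, 5.0: 5000}


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of the clonogenic irradiation experiment.

    Parameters
    ----------
    modes, positions : tuples
        Conditions crossed in the design (default: both modes x both
        positions).
    doses : tuple of float
        Absorbed doses in Gy, excluding the 0 Gy controls which every run
        always contains.
    runs : int
        Independent experimental repeats.
    wells_per_condition : int
        Wells per 6-well plate condition.
    seeded_cells : int or mapping dose -> int
        Cells seeded per well; a mapping allows dose-adaptive seeding.
    plating_efficiency : float
        Fraction of seeded unirradiated cells that form colonies.
    seed : int
        Base RNG seed; identical designs + seed reproduce identical data.
    pe_jitter_sigma : float
        Log-normal sigma of an optional per-run multiplicative plating
        efficiency factor (0 disables; default off).
    """

    modes: tuple[Mode, ...] = (Mode.PBS, Mode.DS)
    positions: tuple[int, ...] = (1, 2)
    doses: tuple[float, ...] = (1.0, 3.0, 5.0)
    runs: int = 2
    wells_per_condition: int = 6
    seeded_cells: int | Mapping[float, int] = field(
        default_factory=lambda: dict(DEFAULT_SEEDED)
    )
    plating_efficiency: float = 0.30
    seed: int = 0
    pe_jitter_sigma: float = 0.0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.wells_per_condition < 1:
            raise ValueError("wells_per_condition must be >= 1")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not 0 < self.plating_efficiency <= 1:
            raise ValueError("plating_efficiency must be in (0, 1]")
        if self.pe_jitter_sigma < 0:
            raise ValueError("pe_jitter_sigma must be >= 0")
        for d in self.all_doses():
            if self.seeded_for(d) < 1:
                raise ValueError(f"seeded cell count for dose {d} must be >= 1")

    def seeded_for(self, dose: float) -> int:
        """Cells seeded per well at `dose`, resolving dose-adaptive maps."""
        if isinstance(self.seeded_cells, Mapping):
            try:
                return int(self.seeded_cells[float(dose)])
            except KeyError:
                # fall back to the largest configured dose not above `dose`
                below = [d for d in self.seeded_cells if d <= dose]
                key = max(below) if below else min(self.seeded_cells)
                return int(self.seeded_cells[key])
        return int(self.seeded_cells)

    def all_doses(self) -> tuple[float, ...]:
        """Doses including the implicit 0 Gy controls."""
        ds = {0.0} | {float(d) for d in self.doses}
        return tuple(sorted(ds))
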