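"""Validated pipeline configuration (pydantic models + JSON loading)."""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import reference
from .design import ExperimentDesign, Mode, TrueLQ

VALID_LABELS = ("PBS1", "PBS2", "DS1", "DS2", "Co60")


class DesignSection(BaseModel):
    """Clonogenic experiment layout (proton conditions)."""

    model_config = ConfigDict(extra="forbid")

    doses_gy: tuple[float, ...] = reference.PROTON_DOSES_GY
    runs: int = Field(2, ge=1)
    wells_per_condition: int = Field(6, ge=1)
    plating_efficiency: float = Field(0.30, gt=0, le=1)
    seeded_cells: dict[float, int] | int = Field(
        default_factory=lambda: {0.0: 330, 1.0: 500, 3.0: 1500, 5.0: 5000}
    )
    pe_jitter_sigma: float = Field(0.0, ge=0)

    @field_validator("doses_gy")
    @classmethod
    def _doses_nonneg(cls, v):
        if any(d < 0 for d in v):
            raise ValueError("doses must be non-negative")
        return v


class TruthSection(BaseModel):
    """Generative LQ parameters for one condition."""

    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(ge=0)
    beta: float = Field(ge=0)


class BeamSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    energy_mev: float = Field(190.6, gt=0)
    grid_step_cm: float = Field(0.01, gt=0)
    straggling_sigma_cm: float | None = Field(None, ge=0)


class AnalysisSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    survival_level: float = Field(0.5, gt=0, lt=1)
    fit_scale: str = "log"
    pooling: str = "wells"
    reference_label: str = "Co60"
    alpha_level: float = Field(0.05, gt=0, lt=1)

    @field_validator("fit_scale")
    @classmethod
    def _scale(cls, v):
        if v not in ("log", "linear"):
            raise ValueError("fit_scale must be 'log' or 'linear'")
        return v

    @field_validator("pooling")
    @classmethod
    def _pooling(cls, v):
        if v not in ("wells", "runs"):
            raise ValueError("pooling must be 'wells' or 'runs'")
        return v


def _default_truth() -> dict[str, TruthSection]:
    return {
        label: TruthSection(alpha=fit.alpha, beta=fit.beta)
        for label, fit in reference.REFERENCE_LQ.items()
    }


class PipelineConfig(BaseModel):
    """Full configuration of the simulate -> analyze -> report pipeline.

    Defaults reproduce the study conditions: 2 runs x 6 wells at
    0/1/3/5 Gy (proton conditions) with plating efficiency 0.30, Co-60
    reference at 1-5 Gy, generative LQ truths at the published fit values,
    a 190.6 MeV beam, and RBE at the 50% survival level.
    """

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    design: DesignSection = Field(default_factory=DesignSection)
    co60_doses_gy: tuple[float, ...] = reference.CO60_DOSES_GY
    truth: dict[str, TruthSection] = Field(default_factory=_default_truth)
    beam: BeamSection = Field(default_factory=BeamSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    neutron_samples: int = Field(20000, ge=1)

    @field_validator("truth")
    @classmethod
    def _labels(cls, v):
        unknown = set(v) - set(VALID_LABELS)
        if unknown:
            raise ValueError(
                f"truth: unknown condition label(s) {sorted(unknown)}; "
                f"valid labels are {VALID_LABELS}"
            )
        return v

    def experiment_design(self, seed: int | None = None) -> ExperimentDesign:
        return ExperimentDesign(
            modes=(Mode.PBS, Mode.DS),
            positions=(1, 2),
            doses=self.design.doses_gy,
            runs=self.design.runs,
            wells_per_condition=self.design.wells_per_condition,
            seeded_cells=self.design.seeded_cells,
            plating_efficiency=self.design.plating_efficiency,
            seed=self.seed if seed is None else seed,
            pe_jitter_sigma=self.design.pe_jitter_sigma,
        )

    def truth_lq(self) -> dict[str, TrueLQ]:
        return {label: TrueLQ(t.alpha, t.beta) for label, t in self.truth.items()}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a JSON config file (or the defaults) with optional overrides."""
    data = {}
    if path is not None:
        data = json.loads(Path(path).read_text())
    data.update(overrides)
    return PipelineConfig.model_validate(data)
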