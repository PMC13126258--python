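"""ICI and TKI therapy: intensity semantics and per-step effects.

Both drug classes are applied from a scheduled start step with an intensity
in [0, 1] that scales the affected interaction channels. Checkpoint
inhibitors (ICI) block PD-L1/PD-1 engagement, gradually restore exhausted
CD8 T cells, and recruit additional immune agents at the boundary of the
space. Tyrosine kinase inhibitors (TKI) suppress tumor duplication and
angiogenesis, discourage CD4 -> Treg differentiation, and unmask the tumor
to dendritic cells (full intensity makes capture certain on contact).
"""

from __future__ import annotations

from typing import Tuple

from pydantic import BaseModel, ConfigDict, field_validator

__all__ = ["ICI", "TKI", "ICI_TKI", "TherapySchedule", "active_intensities",
           "recovered_exhaustion", "tki_duplication_factor"]

ICI = "ICI"
TKI = "TKI"
ICI_TKI = "ICI_TKI"

#: infiltration spawns this kind mix (cd8 : nk : dendritic)
INFILTRATION_MIX = (("cd8", 3), ("nk", 1), ("dendritic", 1))


class TherapySchedule(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    drug: str = ICI_TKI
    start_step: int = 0
    ici_intensity: float = 1.0
    tki_intensity: float = 1.0

    @field_validator("drug")
    @classmethod
    def _known_drug(cls, v: str) -> str:
        if v not in (ICI, TKI, ICI_TKI):
            raise ValueError(f"unknown drug {v!r}")
        return v

    @field_validator("start_step")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("start_step must be >= 0")
        return v

    @field_validator("ici_intensity", "tki_intensity")
    @classmethod
    def _unit(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("intensity must lie in [0, 1]")
        return v


def active_intensities(schedule: TherapySchedule | None, step: int) -> Tuple[float, float]:
    """(ici, tki) intensities in effect at ``step``; zero before the start
    and for the drug channels the schedule does not include."""
    if schedule is None or step < schedule.start_step:
        return 0.0, 0.0
    ici = schedule.ici_intensity if schedule.drug in (ICI, ICI_TKI) else 0.0
    tki = schedule.tki_intensity if schedule.drug in (TKI, ICI_TKI) else 0.0
    return ici, tki


def recovered_exhaustion(exhaustion: float, recover_rate: float, intensity: float) -> float:
    """Linear per-step reawakening of an exhausted T cell, clamped at 0."""
    return max(0.0, exhaustion - recover_rate * intensity)


def tki_duplication_factor(intensity: float, tki_prolif_block: float) -> float:
    """Multiplier applied to tumor duplication probability under TKI."""
    return max(0.0, 1.0 - intensity * tki_prolif_block)


def ici_effects(state, intensity: float, params, rng) -> int:
    """Apply the per-step ICI list to an engine state.

    Reduces every CD8's exhaustion by ``recover_rate * intensity`` and spawns
    a Poisson number of infiltrating immune agents at the boundary (mix
    cd8:nk:dendritic = 3:1:1, scaled by the host's recruitment factor). The
    checkpoint-block factor ``1 - intensity`` is consumed directly inside the
    inhibition-probability formula. Returns the number of agents spawned.
    """
    if intensity <= 0.0:
        return 0
    state.recover_cd8(params.recover_rate * intensity)
    lam = params.infil_rate * intensity * state.recruitment_factor
    n = int(rng.poisson(lam)) if lam > 0 else 0
    if n:
        state.spawn_infiltration(n, rng)
    return n


def tki_effects(state, intensity: float, params, rng) -> None:
    """Record the TKI intensity on an engine state for the step's channels.

    The four channels (duplication block, angiogenesis block, differentiation
    block, DC unmasking) each read this intensity through the shared formula
    helpers; intensity 0 leaves all of them unchanged.
    """
    state.tki_intensity = float(intensity)
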