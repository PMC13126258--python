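"""Learnable simulation parameters with declared bounds.

These are the weights, rates and thresholds the adaptive calibration loop is
allowed to tune against clinical survival outcomes. The duplication weights
``w1``/``w2`` and bias ``b1`` enter the tumor duplication-probability
formula; the rest control interaction success chances, therapy response
channels, genome dynamics and hormone classification cut-offs.
"""

from __future__ import annotations

from typing import Dict, Tuple

from pydantic import BaseModel, ConfigDict

__all__ = ["LearnableParameterSet", "PARAMETER_BOUNDS", "InvalidParameterError"]


class InvalidParameterError(ValueError):
    pass


#: Inclusive (low, high) bounds per learnable parameter.
PARAMETER_BOUNDS: Dict[str, Tuple[float, float]] = {
    "w1": (0.0, 2.0),
    "w2": (0.0, 2.0),
    "b1": (-0.5, 0.5),
    "base_kill": (0.0, 1.0),
    "nk_kill": (0.0, 1.0),
    "base_inhibit": (0.0, 1.0),
    "delta_exh": (0.0, 1.0),
    "treg_suppress": (0.0, 1.0),
    "p_diff": (0.0, 1.0),
    "p_phago": (0.0, 1.0),
    "recover_rate": (0.0, 1.0),
    "infil_rate": (0.0, 5.0),
    "p_angio": (0.0, 1.0),
    "n_half": (1.0, 1000.0),
    "k_expr": (0.0, 5.0),
    "base_mutation_rate": (0.0, 0.05),
    "instability_gain": (0.0, 10.0),
    "e_tg_scale": (0.0, 1.0),
    "d_s": (0.1, 10.0),
    "tki_prolif_block": (0.0, 1.0),
    "neo_gain": (0.0, 5.0),
    "prolif_loss": (0.0, 1.0),
    "apc_gain": (0.0, 2.0),
    "suppressor_apoptosis": (0.0, 0.2),
    "cd8_apoptosis_rate": (0.0, 0.05),
    "vessel_boost": (0.0, 1.0),
    "estrogen_low": (0.01, 1.0),
    "estrogen_high": (1.0, 5.0),
    "testosterone_low": (0.01, 1.0),
    "testosterone_high": (1.0, 5.0),
}


class LearnableParameterSet(BaseModel):
    """Named weights/rates with bounds; the object of adaptive tuning."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    # duplication-probability weights (w1, w2 >= 0; b1 free within bounds)
    w1: float = 1.0
    w2: float = 0.5
    b1: float = 0.0
    # interaction success chances
    base_kill: float = 0.45
    nk_kill: float = 0.25
    base_inhibit: float = 0.5
    delta_exh: float = 0.15
    treg_suppress: float = 0.05
    p_diff: float = 0.01
    p_phago: float = 0.35
    # therapy response
    recover_rate: float = 0.08
    infil_rate: float = 0.6
    tki_prolif_block: float = 0.9
    # environment
    p_angio: float = 0.1
    n_half: float = 100.0
    d_s: float = 3.0
    vessel_boost: float = 0.2
    # genome dynamics
    k_expr: float = 1.0
    base_mutation_rate: float = 0.003
    instability_gain: float = 3.0
    e_tg_scale: float = 0.18
    neo_gain: float = 1.0
    prolif_loss: float = 0.5
    apc_gain: float = 0.3
    suppressor_apoptosis: float = 0.005
    cd8_apoptosis_rate: float = 0.002
    # hormone thresholds (arbitrary units)
    estrogen_low: float = 0.3
    estrogen_high: float = 1.5
    testosterone_low: float = 0.3
    testosterone_high: float = 1.5

    def model_post_init(self, __context) -> None:
        for name, (lo, hi) in PARAMETER_BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise InvalidParameterError(
                    f"{name}={v} outside its bounds [{lo}, {hi}]"
                )

    def replace(self, **updates: float) -> "LearnableParameterSet":
        return LearnableParameterSet(**{**self.model_dump(), **updates})
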