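"""Sex-, hormone- and BMI-dependent initialization and trait modulation.

Sex hormones are represented on an arbitrary unit scale with a three-level
threshold classification (low / normal / high). Each off-normal level
multiplies selected cell traits by a configurable factor; normal levels are
strictly neutral (factor 1). The sex default places the dominant hormone in
the normal band and the non-dominant one in the low band, so sex differences
enter through (a) the low-band modulation factors and (b) sex-specific
initial conditions: CD8 abundance and baseline exhaustion (androgen-driven
dysfunction in males), initial tumor mutation load, and BMI-driven adipocyte
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "Sex",
    "HostProfile",
    "HormoneThresholds",
    "ModulationMap",
    "HostState",
    "ConfigurationError",
    "classify_hormone",
    "modulate_trait",
    "hormone_trait_factor",
    "initialize_host_state",
    "default_thresholds",
    "default_modulation_map",
    "default_counts",
    "adipocyte_count",
    "TRAITS",
]

FEMALE = "female"
MALE = "male"
Sex = str

LOW, NORMAL, HIGH = "low", "normal", "high"

TRAITS = (
    "cd8_activation",
    "cd8_apoptosis",
    "cd8_kill",
    "antigen_recognition_threshold",
    "immune_recruitment",
    "cd8_exhaustion_gain",
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class HostProfile:
    sex: Sex
    bmi: float = 25.0
    estrogen: float | None = None      # arbitrary units; None -> sex default
    testosterone: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.bmi <= 0:
            raise ConfigurationError("bmi must be positive")
        for h in (self.estrogen, self.testosterone):
            if h is not None and h < 0:
                raise ConfigurationError("hormone levels must be non-negative")

    def hormone_levels(self) -> Dict[str, float]:
        """Sex-default levels: dominant hormone in the normal band."""
        if self.sex == FEMALE:
            est = 1.0 if self.estrogen is None else self.estrogen
            tst = 0.2 if self.testosterone is None else self.testosterone
        else:
            est = 0.2 if self.estrogen is None else self.estrogen
            tst = 1.0 if self.testosterone is None else self.testosterone
        return {"estrogen": est, "testosterone": tst}


@dataclass(frozen=True)
class HormoneThresholds:
    """(low_cut, high_cut) per hormone; boundary values classify as normal."""

    cuts: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for hormone, (lo, hi) in self.cuts.items():
            if not lo < hi:
                raise ConfigurationError(f"{hormone}: low_cut must be < high_cut")


def default_thresholds() -> HormoneThresholds:
    return HormoneThresholds({"estrogen": (0.3, 1.5), "testosterone": (0.3, 1.5)})


@dataclass(frozen=True)
class ModulationMap:
    """Multiplicative trait factors keyed by (hormone, level, trait).

    Missing keys and all (·, normal, ·) entries are factor 1.
    """

    coefficients: Dict[Tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (hormone, level, trait), f in self.coefficients.items():
            if f <= 0:
                raise ConfigurationError(f"factor for {(hormone, level, trait)} must be > 0")
            if level == NORMAL and f != 1.0:
                raise ConfigurationError("normal-level factors must equal 1")

    def factor(self, hormone: str, level: str, trait: str) -> float:
        return self.coefficients.get((hormone, level, trait), 1.0)


def default_modulation_map() -> ModulationMap:
    """Built-in hormone effects.

    Low estrogen (the male default) dampens CD8 activation and immune
    recruitment; high estrogen is anti-inflammatory and dampens CD8 traits
    instead. Low testosterone (the female default) reduces exhaustion
    accumulation; high testosterone weakens cytotoxicity and accelerates
    exhaustion and CD8 apoptosis.
    """
    return ModulationMap({
        ("estrogen", LOW, "cd8_activation"): 0.9,
        ("estrogen", LOW, "immune_recruitment"): 0.55,
        ("estrogen", HIGH, "cd8_kill"): 0.8,
        ("estrogen", HIGH, "cd8_activation"): 0.8,
        ("testosterone", LOW, "cd8_exhaustion_gain"): 0.8,
        ("testosterone", HIGH, "cd8_kill"): 0.8,
        ("testosterone", HIGH, "cd8_exhaustion_gain"): 1.3,
        ("testosterone", HIGH, "immune_recruitment"): 0.7,
        ("testosterone", HIGH, "cd8_apoptosis"): 1.2,
    })


def classify_hormone(level: float, thresholds: Tuple[float, float]) -> str:
    """Three-level classification; boundary values are normal."""
    lo, hi = thresholds
    if not lo < hi:
        raise ConfigurationError("low_cut must be < high_cut")
    if level < lo:
        return LOW
    if level > hi:
        return HIGH
    return NORMAL


def hormone_trait_factor(levels: Dict[str, float], thresholds: HormoneThresholds,
                         modulation: ModulationMap, trait: str) -> float:
    """Product of per-hormone factors for one trait."""
    if trait not in TRAITS:
        raise ConfigurationError(f"unknown trait {trait!r}")
    factor = 1.0
    for hormone, level in levels.items():
        cls = classify_hormone(level, thresholds.cuts[hormone])
        factor *= modulation.factor(hormone, cls, trait)
    return factor


def modulate_trait(base: float, profile: HostProfile, thresholds: HormoneThresholds,
                   modulation: ModulationMap, trait: str) -> float:
    """Hormone-modulated trait value; all-normal levels return ``base`` exactly."""
    if base < 0:
        raise ValueError("base must be non-negative")
    return base * hormone_trait_factor(profile.hormone_levels(), thresholds, modulation, trait)


def adipocyte_count(bmi: float, slope: float = 2.0, floor: int = 5) -> int:
    """Linear-with-floor BMI -> adipocyte mapping: round(slope*(bmi-18.5))+ + floor."""
    return max(0, round(slope * (bmi - 18.5))) + floor


def default_counts() -> Dict[str, int]:
    return {"tumor": 40, "cd8": 40, "cd4": 20, "treg": 10, "nk": 15, "dendritic": 15}


@dataclass(frozen=True)
class HostState:
    counts: Dict[str, int]
    hormones: Dict[str, float]
    initial_mutation_load: float
    initial_cd8_exhaustion: float
    initial_cd8_activated_fraction: float


def initialize_host_state(profile: HostProfile,
                          defaults: Dict[str, int] | None = None,
                          rng: np.random.Generator | None = None) -> HostState:
    """Sex- and BMI-dependent initial simulation state.

    Males start with a larger, more pre-activated but more exhausted CD8
    compartment and a higher tumor mutation load; females with a smaller,
    fresher one. Adipocyte count grows monotonically with BMI. Deterministic
    for a given profile (``rng`` is accepted for interface symmetry).
    """
    counts = dict(defaults or default_counts())
    counts["adipocyte"] = adipocyte_count(profile.bmi)
    if profile.sex == MALE:
        counts["cd8"] = round(counts.get("cd8", 40) * 1.5)
        load, exhaustion, activated = 0.015, 0.35, 0.7
    else:
        load, exhaustion, activated = 0.01, 0.05, 0.05
    return HostState(
        counts=counts,
        hormones=profile.hormone_levels(),
        initial_mutation_load=load,
        initial_cd8_exhaustion=exhaustion,
        initial_cd8_activated_fraction=activated,
    )
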