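"""Patient records, virtual images and cohort generation.

A patient record holds the clinical ground truth (sex, treatment, treatment
start step, observed OS and death flag); a virtual image is the
simulation-ready initial state derived from it (immune-cell counts, BMI,
hormone levels, initial tumor conditions). The package ships the 7-patient
RCC subset of the ARON-1 registry as a built-in reference cohort, and a
synthetic-cohort generator that produces ground-truth outcomes by running
the simulator under a known parameter set — so calibration can be tested
against a cohort whose generating parameters are known.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import host as host_mod
from .engine import SimulationConfig, run_simulation
from .params import LearnableParameterSet
from .therapy import ICI, ICI_TKI, TKI, TherapySchedule

__all__ = [
    "PatientRecord",
    "VirtualImage",
    "aron_rcc_cohort",
    "build_virtual_image",
    "schedule_for",
    "generate_synthetic_cohort",
    "read_cohort",
    "write_cohort",
]


class PatientRecord(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    id: str
    sex: str
    treatment: str
    treatment_start: int
    os_true: int
    death_true: bool
    bmi: float = 25.0
    explicit_counts: Optional[Dict[str, int]] = None

    @field_validator("sex")
    @classmethod
    def _sex(cls, v: str) -> str:
        if v not in (host_mod.FEMALE, host_mod.MALE):
            raise ValueError(f"unknown sex {v!r}")
        return v

    @field_validator("treatment")
    @classmethod
    def _treatment(cls, v: str) -> str:
        if v not in (ICI, TKI, ICI_TKI):
            raise ValueError(f"unknown treatment {v!r}")
        return v

    @field_validator("treatment_start", "os_true")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("must be >= 0")
        return v


class VirtualImage(BaseModel):
    """Initial simulation state for one patient."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    counts: Dict[str, int]
    bmi: float
    sex: str
    hormones: Dict[str, float]
    initial_mutation_load: float = 0.0
    initial_cd8_exhaustion: float = 0.0
    initial_cd8_activated_fraction: float = 0.2

    @field_validator("counts")
    @classmethod
    def _nonneg_counts(cls, v: Dict[str, int]) -> Dict[str, int]:
        if any(c < 0 for c in v.values()):
            raise ValueError("counts must be non-negative")
        return v


_ARON_RCC_ROWS = [
    # id, sex, treatment, start, os, death
    ("p1", host_mod.MALE, ICI, 30, 331, True),
    ("p2", host_mod.MALE, ICI, 15, 80, True),
    ("p3", host_mod.MALE, ICI, 29, 387, False),
    ("p4", host_mod.FEMALE, ICI_TKI, 119, 205, True),
    ("p5", host_mod.FEMALE, ICI_TKI, 41, 76, True),
    ("p6", host_mod.FEMALE, ICI_TKI, 3, 129, False),
    ("p7", host_mod.FEMALE, ICI_TKI, 28, 107, False),
]


def aron_rcc_cohort() -> List[PatientRecord]:
    """The seven RCC patients of the ARON-1 registry subset (3 M, 4 F).

    BMI is not part of the published subset and defaults to 25.
    """
    return [
        PatientRecord(id=i, sex=s, treatment=t, treatment_start=st,
                      os_true=os, death_true=d)
        for i, s, t, st, os, d in _ARON_RCC_ROWS
    ]


def build_virtual_image(record: PatientRecord,
                        defaults: Dict[str, int] | None = None) -> VirtualImage:
    """Deterministic record -> virtual-image mapping.

    Explicit counts pass through unchanged; otherwise counts come from the
    documented per-kind baselines adjusted by the sex/BMI initialization
    rules. The same record always produces the same image.
    """
    profile = host_mod.HostProfile(sex=record.sex, bmi=record.bmi)
    state = host_mod.initialize_host_state(profile, defaults)
    counts = dict(state.counts)
    if record.explicit_counts:
        counts.update(record.explicit_counts)
    return VirtualImage(
        counts=counts,
        bmi=record.bmi,
        sex=record.sex,
        hormones=state.hormones,
        initial_mutation_load=state.initial_mutation_load,
        initial_cd8_exhaustion=state.initial_cd8_exhaustion,
        initial_cd8_activated_fraction=state.initial_cd8_activated_fraction,
    )


def schedule_for(record: PatientRecord, ici_intensity: float = 1.0,
                 tki_intensity: float = 1.0) -> TherapySchedule:
    return TherapySchedule(drug=record.treatment, start_step=record.treatment_start,
                           ici_intensity=ici_intensity, tki_intensity=tki_intensity)


def generate_synthetic_cohort(
    n: int,
    seed: int,
    true_params: LearnableParameterSet | None = None,
    sim_config: SimulationConfig | None = None,
) -> Tuple[List[PatientRecord], LearnableParameterSet]:
    """Sample ``n`` synthetic patients with simulator-generated outcomes.

    Sex is Bernoulli(1/2), BMI a clipped normal around 27, treatment uniform
    over {ICI, TKI, ICI+TKI} with a uniform start step. Ground-truth
    ``(os_true, death_true)`` come from running the simulator under
    ``true_params``, so parameter-recovery experiments have a known target.
    Returns the records and the generating parameter set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    params = true_params or LearnableParameterSet()
    base = sim_config or SimulationConfig()
    base = base.model_copy(update={"params": params})
    records = []
    for i in range(n):
        sex = host_mod.FEMALE if rng.random() < 0.5 else host_mod.MALE
        bmi = float(np.clip(rng.normal(27.0, 4.0), 18.0, 45.0))
        treatment = (ICI, TKI, ICI_TKI)[rng.integers(3)]
        start = int(rng.integers(3, max(4, base.max_steps // 4)))
        rec = PatientRecord(id=f"s{i+1}", sex=sex, treatment=treatment,
                            treatment_start=start, os_true=0, death_true=False, bmi=bmi)
        image = build_virtual_image(rec)
        config = base.model_copy(update={"therapy": schedule_for(rec)})
        outcome = run_simulation(config, image, seed=int(rng.integers(2**31 - 1)))
        records.append(rec.model_copy(update={"os_true": outcome.os,
                                              "death_true": not outcome.survived}))
    return records, params


# -- I/O -------------------------------------------------------------------

_CSV_COLUMNS = ["id", "sex", "treatment", "treatment_start", "os_true", "death_true", "bmi"]


def write_cohort(records: List[PatientRecord], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps([r.model_dump() for r in records], indent=1))
    else:
        rows = [{k: getattr(r, k) for k in _CSV_COLUMNS} for r in records]
        pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path: str | Path) -> List[PatientRecord]:
    """Read a cohort file (CSV with the record header, or JSON list)."""
    path = Path(path)
    if path.suffix == ".json":
        return [PatientRecord(**row) for row in json.loads(path.read_text())]
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        row = {k: v for k, v in row.items() if k in _CSV_COLUMNS}
        row["death_true"] = bool(row["death_true"]) if not isinstance(row["death_true"], str) \
            else row["death_true"].strip().lower() in ("1", "true", "yes")
        records.append(PatientRecord(**row))
    return records
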