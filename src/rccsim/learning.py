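"""Adaptive learning: survival fitness functions and black-box tuning.

Two fitness functions compare simulated to observed survival outcomes:

* the concordance index (CI) over comparable patient pairs, where a pair
  (i, j) is comparable iff ``OS_i < OS_j`` and patient ``i`` died (an alive
  patient never serves as the earlier pair element), scored with the strict
  indicator ``I(os_hat_i < os_hat_j)`` so predicted ties contribute 0;

* the saturated squared error, ``(OS - OS_hat)^2`` when the survival flags
  agree and the fixed penalty ``D_max^2`` when they disagree.

``tune_parameters`` runs a bounded black-box search over the learnable
parameter set, evaluating each proposal with the multi-seed cohort
objective and retaining the incumbent best. Proposals alternate between
uniform draws over the search space and Gaussian perturbations of the
incumbent, always clipped to the declared bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .cohort import PatientRecord, build_virtual_image, schedule_for
from .engine import SimulationConfig, run_simulation
from .params import PARAMETER_BOUNDS, LearnableParameterSet

__all__ = [
    "OutcomePair",
    "TrialRecord",
    "UndefinedMetricError",
    "concordance_index",
    "mse_loss",
    "cohort_objective",
    "tune_parameters",
    "D_MAX_DEFAULT",
]

D_MAX_DEFAULT = 500


class UndefinedMetricError(ValueError):
    """Raised when a metric has no comparable pairs to evaluate."""


@dataclass(frozen=True)
class OutcomePair:
    """Predicted vs observed (OS, survived) for one patient."""

    os_hat: float
    survived_hat: bool
    os: float
    survived: bool

    def __post_init__(self) -> None:
        if self.os < 0 or self.os_hat < 0:
            raise ValueError("OS values must be non-negative")


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int
    parameters: LearnableParameterSet
    objective_kind: str
    objective_value: float
    per_patient: Dict[str, Tuple[float, float]]  # id -> (mean os_hat, death fraction)


def concordance_index(pairs: Sequence[OutcomePair]) -> float:
    """Pairwise concordance of predicted OS orderings.

    ``CI = |{(i,j) comparable : os_hat_i < os_hat_j}| / |comparable|`` with
    (i, j) comparable iff ``os_i < os_j`` and patient ``i`` died. Raises
    :class:`UndefinedMetricError` when no pair is comparable.
    """
    concordant = total = 0
    for a in pairs:
        if a.survived:
            continue
        for b in pairs:
            if b is not a and a.os < b.os:
                total += 1
                concordant += a.os_hat < b.os_hat
    if total == 0:
        raise UndefinedMetricError("no comparable patient pairs")
    return concordant / total


def mse_loss(pair: OutcomePair, d_max: int = D_MAX_DEFAULT) -> float:
    """Saturated squared survival-time error.

    ``(os - os_hat)^2`` when the survival flags agree, ``d_max^2`` otherwise.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if pair.survived == pair.survived_hat:
        return float((pair.os - pair.os_hat) ** 2)
    return float(d_max) ** 2


def _simulate_patient(record: PatientRecord, params: LearnableParameterSet,
                      base_config: SimulationConfig, seeds: Sequence[int],
                      simulate=None) -> List[Tuple[float, bool]]:
    image = build_virtual_image(record)
    config = base_config.model_copy(update={"params": params,
                                            "therapy": schedule_for(record)})
    out = []
    for s in seeds:
        if simulate is not None:
            os_hat, survived_hat = simulate(record, params, s)
        else:
            o = run_simulation(config, image, seed=s)
            os_hat, survived_hat = o.os, o.survived
        out.append((float(os_hat), bool(survived_hat)))
    return out


def cohort_objective(params: LearnableParameterSet, cohort: Sequence[PatientRecord],
                     objective_kind: str, n_seeds: int, rng: np.random.Generator,
                     base_config: SimulationConfig | None = None,
                     d_max: int | None = None, simulate=None,
                     _aggregates: Dict[str, Tuple[float, float]] | None = None) -> float:
    """Multi-seed cohort fitness under one parameter set.

    Runs ``n_seeds`` simulations per patient (seeds drawn once from ``rng``,
    shared across patients for comparability). For ``"MSE"`` the objective
    is the patient-mean of seed-mean saturated losses (minimize); for
    ``"CI"`` the concordance index of per-patient seed-mean predictions with
    majority-vote survival flags, ties counting as dead (maximize).

    ``simulate`` may replace the engine: a callable
    ``(record, params, seed) -> (os_hat, survived_hat)`` used in tests.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if objective_kind not in ("CI", "MSE"):
        raise ValueError(f"unknown objective {objective_kind!r}")
    base_config = base_config or SimulationConfig()
    if d_max is None:
        d_max = base_config.max_steps
    seeds = [int(s) for s in rng.integers(2**31 - 1, size=n_seeds)]

    losses, ci_pairs = [], []
    for record in cohort:
        results = _simulate_patient(record, params, base_config, seeds, simulate)
        mean_os = float(np.mean([o for o, _ in results]))
        death_frac = float(np.mean([not s for _, s in results]))
        if _aggregates is not None:
            _aggregates[record.id] = (mean_os, death_frac)
        if objective_kind == "MSE":
            losses.append(np.mean([
                mse_loss(OutcomePair(os_hat=o, survived_hat=s,
                                     os=record.os_true, survived=not record.death_true),
                         d_max)
                for o, s in results
            ]))
        else:
            survived_hat = death_frac < 0.5  # majority vote, ties count as dead
            ci_pairs.append(OutcomePair(os_hat=mean_os, survived_hat=survived_hat,
                                        os=record.os_true, survived=not record.death_true))
    if objective_kind == "MSE":
        return float(np.mean(losses))
    return concordance_index(ci_pairs)


def tune_parameters(space: Dict[str, Tuple[float, float]],
                    cohort: Sequence[PatientRecord], objective_kind: str,
                    n_trials: int, n_seeds: int, rng: np.random.Generator,
                    base_config: SimulationConfig | None = None,
                    start: LearnableParameterSet | None = None,
                    simulate=None) -> Tuple[LearnableParameterSet, List[TrialRecord]]:
    """Black-box search over the learnable parameters.

    ``space`` maps parameter names to (low, high) search bounds, each
    validated against the declared parameter bounds. The first trial
    evaluates ``start`` (clipped into the space); later trials alternate
    uniform draws with Gaussian perturbations of the incumbent (sd = 20% of
    each range). Every proposal lies inside the space; the incumbent best is
    retained and returned along with the full trial history. Seeds are fixed
    once so all trials face identical simulation noise.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not space:
        raise ValueError("empty search space")
    for name, (lo, hi) in space.items():
        blo, bhi = PARAMETER_BOUNDS[name]
        if not (blo <= lo < hi <= bhi):
            raise ValueError(f"{name}: search range [{lo}, {hi}] outside bounds [{blo}, {bhi}]")
    start = start or LearnableParameterSet()
    maximize = objective_kind == "CI"
    # one objective seed reused in every trial: all trials face the same
    # simulation seed list, so objective differences reflect the parameters
    objective_seed = int(rng.integers(2**31 - 1))

    names = sorted(space)
    history: List[TrialRecord] = []
    best: TrialRecord | None = None

    def propose(i: int) -> Dict[str, float]:
        if i == 0:
            return {n: float(np.clip(getattr(start, n), *space[n])) for n in names}
        if best is None or i % 2 == 1:
            return {n: float(rng.uniform(*space[n])) for n in names}
        out = {}
        for n in names:
            lo, hi = space[n]
            v = getattr(best.parameters, n) + rng.normal(scale=0.2 * (hi - lo))
            out[n] = float(np.clip(v, lo, hi))
        return out

    for i in range(n_trials):
        values = propose(i)
        params = start.replace(**values)
        aggregates: Dict[str, Tuple[float, float]] = {}
        value = cohort_objective(params, cohort, objective_kind, n_seeds,
                                 np.random.default_rng(objective_seed),
                                 base_config=base_config, simulate=simulate,
                                 _aggregates=aggregates)
        record = TrialRecord(i, params, objective_kind, value, aggregates)
        history.append(record)
        if best is None or (value > best.objective_value if maximize
                            else value < best.objective_value):
            best = record
    assert best is not None
    return best.parameters, history
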