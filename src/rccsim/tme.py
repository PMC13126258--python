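"""Spatial tumor microenvironment: agents, perception graph, interaction rules.

Interaction follows an interaction-as-perception scheme: each agent has a
search dimension ``d_s`` and perceives any other living agent strictly closer
than ``d_s``, producing a transient directed graph each step. Edges trigger
the cooperation/competition rules: dendritic cells capture tumor antigen and
hand it to CD8 T cells, activated CD8s and NK cells attempt kills, tumor
cells engage the PD-1/PD-L1 checkpoint to exhaust T cells, Tregs suppress,
and CD4 cells may differentiate into Tregs.

The probability formulas live in small pure helpers shared with the
vectorized engine so that the per-agent rules here and the batched engine
use literally the same arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TUMOR", "CD8", "CD4", "TREG", "NK", "DENDRITIC", "ADIPOCYTE", "KINDS",
    "Agent", "InteractionGraph", "Vessel", "Event",
    "build_interaction_graph",
    "kill_probability", "inhibition_probability", "capture_probability",
    "angiogenesis_probability",
    "dc_cycle", "ctl_kill_attempt", "tumor_checkpoint_inhibition",
    "resolve_auxiliary_interactions", "angiogenesis_step",
]

TUMOR, CD8, CD4, TREG, NK, DENDRITIC, ADIPOCYTE = (
    "tumor", "cd8", "cd4", "treg", "nk", "dendritic", "adipocyte",
)
KINDS = (TUMOR, CD8, CD4, TREG, NK, DENDRITIC, ADIPOCYTE)


@dataclass
class Agent:
    """A single cell-agent.

    Kind-specific state lives in optional fields: tumor cells carry gene
    mutation ``scores`` (mapping gene name -> [0,1]) plus a neoantigen load;
    CD8s an activation flag and exhaustion level; dendritic cells a
    phagocytized flag.
    """

    id: int
    kind: str
    position: np.ndarray
    search_dimension: float = 3.0
    alive: bool = True
    # cd8 state
    activated: bool = False
    exhaustion: float = 0.0
    # dendritic state
    phagocytized: bool = False
    # tumor state
    scores: Dict[str, float] = field(default_factory=dict)
    neoantigen_load: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}")
        if self.search_dimension <= 0 and self.search_dimension != 0.0:
            raise ValueError("search_dimension must be >= 0")
        if not 0.0 <= self.exhaustion <= 1.0:
            raise ValueError("exhaustion must lie in [0, 1]")


@dataclass(frozen=True)
class InteractionGraph:
    """Transient directed perception graph for one step."""

    step: int
    edges: Set[Tuple[int, int]]

    def out_neighbors(self, agent_id: int) -> List[int]:
        return sorted(t for s, t in self.edges if s == agent_id)


@dataclass
class Vessel:
    position: np.ndarray
    supply_radius: float = 8.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.supply_radius <= 0:
            raise ValueError("supply_radius must be positive")


@dataclass(frozen=True)
class Event:
    kind: str
    source: int
    target: int = -1


def build_interaction_graph(agents: Sequence[Agent], step: int = 0) -> InteractionGraph:
    """Directed edges (a, b) whenever dist(a, b) < a.search_dimension.

    Only living agents participate; perception is asymmetric because each
    agent uses its own search dimension.
    """
    alive = [a for a in agents if a.alive]
    edges: Set[Tuple[int, int]] = set()
    if len(alive) >= 2:
        pos = np.stack([a.position for a in alive])
        tree = cKDTree(pos)
        for i, a in enumerate(alive):
            if a.search_dimension <= 0:
                continue
            for j in sorted(tree.query_ball_point(pos[i], a.search_dimension)):
                if j != i and float(np.linalg.norm(pos[i] - pos[j])) < a.search_dimension:
                    edges.add((a.id, alive[j].id))
    return InteractionGraph(step=step, edges=edges)


# -- shared probability formulas ------------------------------------------

def kill_probability(base_kill: float, exhaustion: float, hormone_factor: float,
                     evasion: float) -> float:
    """CTL kill chance: base * (1 - exhaustion) * hormones * (1 - evasion)."""
    return float(np.clip(base_kill * (1.0 - exhaustion) * hormone_factor * (1.0 - evasion), 0.0, 1.0))


def inhibition_probability(base_inhibit: float, cd274_score: float, ici_intensity: float) -> float:
    """PD-L1 checkpoint engagement chance, blocked by ICI intensity."""
    return float(np.clip(base_inhibit * cd274_score * (1.0 - ici_intensity), 0.0, 1.0))


def capture_probability(p_phago: float, neoantigen_load: float, neo_gain: float,
                        recognition_threshold_factor: float, tki_intensity: float) -> float:
    """DC antigen-capture chance.

    Neoantigen load raises the base chance; a higher hormone-driven
    recognition threshold divides it; TKI unmasking interpolates the result
    toward 1 (full intensity guarantees capture).
    """
    p = p_phago * (1.0 + neo_gain * neoantigen_load) / max(recognition_threshold_factor, 1e-12)
    p = float(np.clip(p, 0.0, 1.0))
    return p + (1.0 - p) * float(np.clip(tki_intensity, 0.0, 1.0))


def angiogenesis_probability(p_angio: float, tumor_count: int, n_half: float,
                             tki_intensity: float) -> float:
    """Vessel sprouting chance, saturating in tumor burden, blocked by TKI."""
    return float(np.clip(p_angio * min(1.0, tumor_count / n_half) * (1.0 - tki_intensity), 0.0, 1.0))


# -- per-agent interaction rules ------------------------------------------

def _nearest(agent: Agent, candidates: Iterable[Agent]) -> Optional[Agent]:
    best, best_d = None, np.inf
    for c in candidates:
        d = float(np.linalg.norm(agent.position - c.position))
        if d < best_d:
            best, best_d = c, d
    return best


def _step_toward(agent: Agent, target: np.ndarray, move_step: float) -> None:
    delta = target - agent.position
    dist = float(np.linalg.norm(delta))
    if dist > 1e-12:
        agent.position = agent.position + delta * min(1.0, move_step / dist)


def dc_cycle(dc: Agent, graph: InteractionGraph, agents: Dict[int, Agent], params,
             rng: np.random.Generator, tki_intensity: float = 0.0,
             recognition_threshold_factor: float = 1.0, contact_radius: float = 1.0,
             move_step: float = 1.0) -> List[Event]:
    """One dendritic-cell cycle: seek/capture antigen, then seek/activate CD8.

    An unloaded DC approaches the nearest perceivable tumor cell and on
    contact captures antigen with the neoantigen- and TKI-modulated chance.
    A loaded DC approaches the nearest inactive CD8 and on contact activates
    it, resetting its own phagocytized state.
    """
    if dc.kind != DENDRITIC or not dc.alive:
        return []
    events: List[Event] = []
    perceived = [agents[j] for j in graph.out_neighbors(dc.id) if agents[j].alive]
    if not dc.phagocytized:
        target = _nearest(dc, (a for a in perceived if a.kind == TUMOR))
        if target is not None:
            _step_toward(dc, target.position, move_step)
            if float(np.linalg.norm(dc.position - target.position)) < contact_radius:
                p = capture_probability(params.p_phago, target.neoantigen_load,
                                        params.neo_gain, recognition_threshold_factor,
                                        tki_intensity)
                if rng.random() < p:
                    dc.phagocytized = True
                    events.append(Event("capture", dc.id, target.id))
    else:
        target = _nearest(dc, (a for a in perceived if a.kind == CD8 and not a.activated))
        if target is not None:
            _step_toward(dc, target.position, move_step)
            if float(np.linalg.norm(dc.position - target.position)) < contact_radius:
                target.activated = True
                dc.phagocytized = False
                events.append(Event("activate", dc.id, target.id))
    return events


def _antigen_evasion(tumor: Agent, antigen_genes: Sequence[str]) -> float:
    if not tumor.scores:
        return 0.0
    return float(np.mean([tumor.scores.get(g, 0.0) for g in antigen_genes]))


ANTIGEN_GENES = ("HLA-A", "HLA-B", "HLA-C", "JAK1", "JAK2", "B2M", "TAP1", "TAP2")


def ctl_kill_attempt(cd8: Agent, tumor: Agent, params, rng: np.random.Generator,
                     hormone_kill_factor: float = 1.0) -> bool:
    """Activated-CD8 kill attempt against one perceived tumor cell.

    Kill chance is the product of base cytotoxicity, remaining (1-exhaustion),
    the hormone kill factor, and (1 - antigen-presentation evasion), where
    evasion is the mean mutation score of the antigen-presentation genes.
    Inactive CD8s never kill.
    """
    if not cd8.activated or not cd8.alive or not tumor.alive:
        return False
    p = kill_probability(params.base_kill, cd8.exhaustion, hormone_kill_factor,
                         _antigen_evasion(tumor, ANTIGEN_GENES))
    if rng.random() < p:
        tumor.alive = False
        return True
    return False


def tumor_checkpoint_inhibition(tumor: Agent, tcell: Agent, ici_intensity: float,
                                params, rng: np.random.Generator,
                                exhaustion_gain_factor: float = 1.0) -> float:
    """PD-L1-driven T-cell exhaustion attempt; returns the exhaustion increment.

    Engagement chance scales with the CD274 mutation score and is reduced by
    the ICI checkpoint-block factor; on success, exhaustion rises by
    ``delta_exh`` (hormone-scaled) and is clamped at 1.
    """
    if not (tumor.alive and tcell.alive):
        return 0.0
    p = inhibition_probability(params.base_inhibit, tumor.scores.get("CD274", 0.0), ici_intensity)
    if rng.random() < p:
        inc = min(params.delta_exh * exhaustion_gain_factor, 1.0 - tcell.exhaustion)
        tcell.exhaustion += inc
        return inc
    return 0.0


def resolve_auxiliary_interactions(graph: InteractionGraph, agents: Dict[int, Agent],
                                   params, rng: np.random.Generator,
                                   tki_intensity: float = 0.0,
                                   contact_radius: float = 1.0) -> List[Event]:
    """NK kills, Treg suppression and CD4 -> Treg differentiation.

    NK kills ignore antigen-presentation evasion (innate recognition). A Treg
    in contact with a CD8 raises its exhaustion by ``treg_suppress``. Each
    CD4 differentiates into a Treg with probability ``p_diff*(1-tki)``.
    """
    events: List[Event] = []
    for aid in sorted(agents):
        agent = agents[aid]
        if not agent.alive:
            continue
        neighbors = [agents[j] for j in graph.out_neighbors(aid) if agents[j].alive]
        in_contact = [n for n in neighbors
                      if float(np.linalg.norm(agent.position - n.position)) < contact_radius]
        if agent.kind == NK:
            for n in in_contact:
                if n.kind == TUMOR and rng.random() < np.clip(params.nk_kill, 0.0, 1.0):
                    n.alive = False
                    events.append(Event("nk_kill", aid, n.id))
                    break
        elif agent.kind == TREG:
            for n in in_contact:
                if n.kind == CD8:
                    n.exhaustion = min(1.0, n.exhaustion + params.treg_suppress)
                    events.append(Event("suppress", aid, n.id))
        elif agent.kind == CD4:
            p = float(np.clip(params.p_diff * (1.0 - tki_intensity), 0.0, 1.0))
            if rng.random() < p:
                agent.kind = TREG
                events.append(Event("differentiate", aid))
    return events


def angiogenesis_step(vessels: List[Vessel], tumor_positions: np.ndarray,
                      tki_intensity: float, params, rng: np.random.Generator,
                      supply_radius: float = 8.0) -> List[Vessel]:
    """Possibly sprout one new vessel near a random tumor cell.

    Sprouting probability saturates with tumor burden and is fully blocked
    at TKI intensity 1. Returns the (possibly extended) vessel list.
    """
    count = int(np.atleast_2d(tumor_positions).shape[0]) if tumor_positions.size else 0
    p = angiogenesis_probability(params.p_angio, count, params.n_half, tki_intensity)
    if count and rng.random() < p:
        anchor = np.atleast_2d(tumor_positions)[rng.integers(count)]
        offset = rng.normal(scale=2.0, size=2)
        vessels.append(Vessel(anchor + offset, supply_radius))
    return vessels
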