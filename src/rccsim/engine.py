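"""Simulation loop: step scheduling, tumor duplication, outcome extraction.

The engine advances a population of cell-agents on a bounded 2-D rectangle
through a fixed phase order each step: perception, dendritic-cell cycle,
CTL/NK kills, checkpoint inhibition, auxiliary interactions (Treg
suppression, CD4 differentiation, apoptosis), tumor division, therapy
effects, angiogenesis, and cleanup. Tumor duplication follows the learnable
clamped formula

    p_dup = clamp((e_tg * w1 + mutation(MYC) * w2) / 2 + b1, 0, 1)

where ``e_tg`` is the cell's normalized growth potential (modulated by
proliferation-oncogene damage, APC loss and vessel proximity) and
``mutation(MYC)`` its MYC mutation score.

A virtual patient dies when the tumor burden reaches ``lethal_burden``
cells; eradication or surviving the horizon counts as survival, with
overall survival (OS) capped at ``max_steps``.

The agent population is stored as structure-of-arrays (positions, state
flags, genome code matrix, cached gene scores) so one step costs a handful
of vectorized array operations plus k-d-tree neighbor queries; the
probability arithmetic is shared with the per-agent rules in
:mod:`rccsim.tme`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy.spatial import cKDTree

from . import genome as genome_mod
from . import host as host_mod
from . import therapy as therapy_mod
from .genome import GenePanel, MutationProfile, default_panel, population_mutation_profile
from .params import InvalidParameterError, LearnableParameterSet
from .therapy import TherapySchedule, active_intensities
from .tme import KINDS

__all__ = [
    "SimulationConfig",
    "SimulationOutcome",
    "SimulationState",
    "duplication_probability",
    "simulation_step",
    "run_simulation",
]

KIND_CODE = {k: i for i, k in enumerate(KINDS)}
TUMOR, CD8, CD4, TREG, NK, DC, ADIPO = (KIND_CODE[k] for k in KINDS)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    width: float = 100.0
    height: float = 100.0
    max_steps: int = 500
    lethal_burden: int = 500
    contact_radius: float = 1.0
    move_step: float = 1.0
    crowd_radius: float = 2.0
    crowd_cap: int = 10
    initial_vessels: int = 4
    vessel_radius: float = 8.0
    seed: int = 0
    # Neutral-evolution control: genomes still mutate and are inherited, but
    # no behavior depends on genotype (drift baseline for selection analyses).
    neutral_evolution: bool = False
    params: LearnableParameterSet = LearnableParameterSet()
    therapy: Optional[TherapySchedule] = None

    def model_post_init(self, __context) -> None:
        if self.max_steps <= 0:
            raise ValueError("max_steps must be positive")
        if self.lethal_burden <= 0:
            raise ValueError("lethal_burden must be positive")


@dataclass
class SimulationOutcome:
    """(OS, Survived) plus the per-step trajectory and final mutation profile."""

    os: int
    survived: bool
    trajectory: pd.DataFrame
    final_mutation_profile: MutationProfile


def duplication_probability(e_tg: float, myc_score: float, w1: float, w2: float,
                            b1: float) -> float:
    """Clamped learnable duplication probability.

    ``p' = (e_tg*w1 + myc_score*w2)/2 + b1``; returns 1 if ``p' > 1``, 0 if
    ``p' < 0``, else ``p'``. Negative weights are rejected.
    """
    if w1 < 0 or w2 < 0:
        raise InvalidParameterError("w1 and w2 must be non-negative")
    p = (e_tg * w1 + myc_score * w2) / 2.0 + b1
    return float(min(1.0, max(0.0, p)))


class SimulationState:
    """Structure-of-arrays agent population plus vessels and step counter."""

    def __init__(self, config: SimulationConfig, image, rng: np.random.Generator,
                 panel: GenePanel | None = None):
        self.config = config
        self.params = config.params
        self.panel = panel or default_panel()
        self.rng = rng
        self.t = 0
        self.tki_intensity = 0.0
        self.neutral = config.neutral_evolution
        self.sex = getattr(image, "sex", host_mod.FEMALE)

        p = self.params
        thresholds = host_mod.HormoneThresholds({
            "estrogen": (p.estrogen_low, p.estrogen_high),
            "testosterone": (p.testosterone_low, p.testosterone_high),
        })
        modulation = host_mod.default_modulation_map()
        levels = dict(image.hormones)
        self.hormones = levels
        f = lambda trait: host_mod.hormone_trait_factor(levels, thresholds, modulation, trait)
        self.kill_factor = f("cd8_kill")
        self.activation_factor = f("cd8_activation")
        self.apoptosis_factor = f("cd8_apoptosis")
        self.recognition_factor = f("antigen_recognition_threshold")
        self.recruitment_factor = f("immune_recruitment")
        self.exhaustion_gain_factor = f("cd8_exhaustion_gain")

        # agent arrays
        self.kind = np.empty(0, dtype=np.int8)
        self.pos = np.empty((0, 2))
        self.alive = np.empty(0, dtype=bool)
        self.exh = np.empty(0)
        self.activated = np.empty(0, dtype=bool)
        self.phag = np.empty(0, dtype=bool)
        self.e_tg = np.empty(0)
        self.genomes = np.empty((0, self.panel.total_length), dtype=np.uint8)
        self.scores = np.empty((0, len(self.panel.names)))
        self.neo = np.empty(0)
        self.mut_rate = np.empty(0)

        self.vessel_pos = np.empty((0, 2))
        self.trajectory_rows: List[Dict[str, float]] = []

        self._populate(image)

    # -- construction ----------------------------------------------------
    def _rand_pos(self, n: int) -> np.ndarray:
        c = self.config
        return self.rng.uniform([0, 0], [c.width, c.height], size=(n, 2))

    def _append(self, kind: int, pos: np.ndarray, *, exh: float = 0.0,
                activated=False, genomes: np.ndarray | None = None,
                e_tg: np.ndarray | None = None) -> None:
        n = pos.shape[0]
        if n == 0:
            return
        self.kind = np.concatenate([self.kind, np.full(n, kind, dtype=np.int8)])
        self.pos = np.concatenate([self.pos, pos])
        self.alive = np.concatenate([self.alive, np.ones(n, dtype=bool)])
        if np.isscalar(exh):
            exh = np.full(n, float(exh))
        self.exh = np.concatenate([self.exh, exh])
        if isinstance(activated, bool):
            activated = np.full(n, activated, dtype=bool)
        self.activated = np.concatenate([self.activated, activated])
        self.phag = np.concatenate([self.phag, np.zeros(n, dtype=bool)])
        if genomes is None:
            genomes = np.zeros((n, self.panel.total_length), dtype=np.uint8)
            scores = np.zeros((n, len(self.panel.names)))
            neo = np.zeros(n)
            rate = np.zeros(n)
        else:
            scores = self.panel.gene_scores(genomes, self.params.k_expr)
            neo = self.panel.neoantigen_load(genomes)
            if self.neutral:
                rate = np.full(n, self.params.base_mutation_rate)
            else:
                brca = scores[:, self.panel.instability_idx].mean(axis=1)
                rate = np.clip(self.params.base_mutation_rate
                               * (1.0 + self.params.instability_gain * brca), 0.0, 1.0)
        self.genomes = np.concatenate([self.genomes, genomes])
        self.scores = np.concatenate([self.scores, scores])
        self.neo = np.concatenate([self.neo, neo])
        self.mut_rate = np.concatenate([self.mut_rate, rate])
        if e_tg is None:
            e_tg = np.zeros(n)
        self.e_tg = np.concatenate([self.e_tg, e_tg])

    def _populate(self, image) -> None:
        c, rng = self.config, self.rng
        counts = dict(image.counts)
        n_tumor = int(counts.get("tumor", 0))
        if n_tumor:
            center = np.array([c.width / 2, c.height / 2])
            tpos = np.clip(center + rng.normal(scale=5.0, size=(n_tumor, 2)),
                           [0, 0], [c.width, c.height])
            load = float(getattr(image, "initial_mutation_load", 0.0))
            wt = np.broadcast_to(self.panel.wildtype, (n_tumor, self.panel.total_length))
            g = genome_mod.mutate_codes(np.ascontiguousarray(wt), load, rng)
            e_tg = rng.uniform(0.5, 1.0, size=n_tumor) * self.params.e_tg_scale
            self._append(TUMOR, tpos, genomes=g, e_tg=e_tg)
        n_cd8 = int(counts.get("cd8", 0))
        if n_cd8:
            frac = float(getattr(image, "initial_cd8_activated_fraction", 0.2))
            act = rng.random(n_cd8) < frac
            self._append(CD8, self._rand_pos(n_cd8),
                         exh=np.full(n_cd8, float(getattr(image, "initial_cd8_exhaustion", 0.0))),
                         activated=act)
        for name, code in (("cd4", CD4), ("treg", TREG), ("nk", NK),
                           ("dendritic", DC), ("adipocyte", ADIPO)):
            n = int(counts.get(name, 0))
            if n:
                self._append(code, self._rand_pos(n))
        self.vessel_pos = self._rand_pos(c.initial_vessels)
        self._record()

    # -- helpers ---------------------------------------------------------
    def counts(self) -> Dict[str, int]:
        out = {}
        for name, code in KIND_CODE.items():
            out[name] = int(np.count_nonzero(self.alive & (self.kind == code)))
        return out

    def tumor_count(self) -> int:
        return int(np.count_nonzero(self.alive & (self.kind == TUMOR)))

    def _record(self) -> None:
        row: Dict[str, float] = {"step": self.t}
        row.update(self.counts())
        row["vessels"] = self.vessel_pos.shape[0]
        self.trajectory_rows.append(row)

    def _idx(self, code: int, extra: np.ndarray | None = None) -> np.ndarray:
        m = self.alive & (self.kind == code)
        if extra is not None:
            m &= extra
        return np.flatnonzero(m)

    def _random_walk(self, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        ang = self.rng.uniform(0.0, 2 * np.pi, size=idx.size)
        step = self.config.move_step
        self.pos[idx] += np.column_stack([np.cos(ang), np.sin(ang)]) * step
        self._clip(idx)

    def _clip(self, idx: np.ndarray) -> None:
        c = self.config
        self.pos[idx] = np.clip(self.pos[idx], [0, 0], [c.width, c.height])

    def _move_toward(self, idx: np.ndarray, targets: np.ndarray,
                     dists: np.ndarray) -> np.ndarray:
        """Step ``idx`` agents toward targets; returns post-move distances."""
        if idx.size == 0:
            return dists
        step = self.config.move_step
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.minimum(1.0, step / np.maximum(dists, 1e-12))
        self.pos[idx] += (targets - self.pos[idx]) * frac[:, None]
        self._clip(idx)
        return np.maximum(dists - step, 0.0)

    def _chase(self, idx: np.ndarray, target_tree: cKDTree | None,
               target_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Move agents toward their nearest target within d_s.

        Returns (engaged subset of idx, their target agent indices,
        post-move distances); agents with no perceivable target random-walk.
        """
        if idx.size == 0 or target_tree is None:
            self._random_walk(idx)
            return np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0)
        d, j = target_tree.query(self.pos[idx], k=1, distance_upper_bound=self.params.d_s)
        found = np.isfinite(d)
        self._random_walk(idx[~found])
        engaged = idx[found]
        tgt = target_idx[j[found]]
        post = self._move_toward(engaged, self.pos[tgt], d[found])
        return engaged, tgt, post

    # -- therapy hooks ---------------------------------------------------
    def recover_cd8(self, amount: float) -> None:
        cd8 = self._idx(CD8)
        self.exh[cd8] = np.maximum(0.0, self.exh[cd8] - amount)

    def spawn_infiltration(self, n: int, rng: np.random.Generator) -> None:
        """New immune agents appear at uniform random boundary positions."""
        kinds, weights = zip(*therapy_mod.INFILTRATION_MIX)
        w = np.array(weights, dtype=float)
        choice = rng.choice(len(kinds), size=n, p=w / w.sum())
        c = self.config
        side = rng.integers(0, 4, size=n)
        u = rng.random(n)
        pos = np.empty((n, 2))
        pos[:, 0] = np.where(side == 0, 0.0, np.where(side == 1, c.width, u * c.width))
        pos[:, 1] = np.where(side < 2, u * c.height,
                             np.where(side == 2, 0.0, c.height))
        for k, name in enumerate(kinds):
            sel = choice == k
            if sel.any():
                self._append(KIND_CODE[name], pos[sel])

    # -- the step --------------------------------------------------------
    def step(self) -> None:
        self.t += 1
        rng, p, c = self.rng, self.params, self.config
        ici, tki = active_intensities(c.therapy, self.t)
        therapy_mod.tki_effects(self, tki, p, rng)

        tumors = self._idx(TUMOR)
        tumor_tree = cKDTree(self.pos[tumors]) if tumors.size else None

        # --- dendritic-cell cycle ---
        dcs = self._idx(DC)
        unloaded = dcs[~self.phag[dcs]]
        loaded = dcs[self.phag[dcs]]
        eng, tgt, post = self._chase(unloaded, tumor_tree, tumors)
        contact = post < c.contact_radius
        if contact.any():
            ce, ct = eng[contact], tgt[contact]
            neo = np.zeros(ct.size) if self.neutral else self.neo[ct]
            base = np.clip(p.p_phago * (1.0 + p.neo_gain * neo)
                           / max(self.recognition_factor, 1e-12), 0.0, 1.0)
            prob = base + (1.0 - base) * tki
            hit = rng.random(ce.size) < prob
            self.phag[ce[hit]] = True
        inactive_cd8 = self._idx(CD8, ~self.activated)
        cd8_tree = cKDTree(self.pos[inactive_cd8]) if inactive_cd8.size else None
        eng, tgt, post = self._chase(loaded, cd8_tree, inactive_cd8)
        contact = post < c.contact_radius
        if contact.any():
            ce, ct = eng[contact], tgt[contact]
            hit = rng.random(ce.size) < min(1.0, self.activation_factor)
            self.activated[ct[hit]] = True
            self.phag[ce[hit]] = False

        # --- CTL and NK kills ---
        act_cd8 = self._idx(CD8, self.activated)
        eng, tgt, post = self._chase(act_cd8, tumor_tree, tumors)
        contact = post < c.contact_radius
        if contact.any():
            ce, ct = eng[contact], tgt[contact]
            evasion = (np.zeros(ct.size) if self.neutral
                       else self.scores[ct][:, self.panel.antigen_idx].mean(axis=1))
            prob = np.clip(p.base_kill * (1.0 - self.exh[ce]) * self.kill_factor
                           * (1.0 - evasion), 0.0, 1.0)
            hit = rng.random(ce.size) < prob
            self.alive[ct[hit]] = False
        nks = self._idx(NK)
        eng, tgt, post = self._chase(nks, tumor_tree, tumors)
        contact = post < c.contact_radius
        if contact.any():
            ct = tgt[contact]
            hit = rng.random(ct.size) < np.clip(p.nk_kill, 0.0, 1.0)
            self.alive[ct[hit]] = False

        # --- checkpoint inhibition (tumor -> T cell in contact) ---
        tumors = self._idx(TUMOR)
        tumor_tree = cKDTree(self.pos[tumors]) if tumors.size else None
        cd8s = self._idx(CD8)
        if tumor_tree is not None and cd8s.size:
            d, j = tumor_tree.query(self.pos[cd8s], k=1,
                                    distance_upper_bound=c.contact_radius)
            near = np.isfinite(d)
            ce, ct = cd8s[near], tumors[j[near]]
            cd274 = (np.zeros(ct.size) if self.neutral
                     else self.scores[ct, self.panel.checkpoint_idx[0]])
            prob = np.clip(p.base_inhibit * cd274 * (1.0 - ici), 0.0, 1.0)
            hit = rng.random(ce.size) < prob
            inc = p.delta_exh * self.exhaustion_gain_factor
            self.exh[ce[hit]] = np.minimum(1.0, self.exh[ce[hit]] + inc)

        # --- auxiliary: Treg suppression, CD4 differentiation, apoptosis ---
        tregs = self._idx(TREG)
        self._random_walk(tregs)
        if tregs.size and cd8s.size:
            treg_tree = cKDTree(self.pos[tregs])
            d, _ = treg_tree.query(self.pos[cd8s], k=1,
                                   distance_upper_bound=c.contact_radius)
            near = np.isfinite(d)
            self.exh[cd8s[near]] = np.minimum(1.0, self.exh[cd8s[near]] + p.treg_suppress)
        cd4s = self._idx(CD4)
        self._random_walk(cd4s)
        if cd4s.size:
            prob = float(np.clip(p.p_diff * (1.0 - tki), 0.0, 1.0))
            diff = rng.random(cd4s.size) < prob
            self.kind[cd4s[diff]] = TREG
        if cd8s.size:
            prob = np.clip(p.cd8_apoptosis_rate * self.apoptosis_factor, 0.0, 1.0)
            die = rng.random(cd8s.size) < prob
            self.alive[cd8s[die]] = False
        tumors = self._idx(TUMOR)
        if tumors.size:
            suppressor = (np.zeros(tumors.size) if self.neutral
                          else self.scores[tumors][:, self.panel.suppressor_idx].mean(axis=1))
            prob = np.clip(p.suppressor_apoptosis * (1.0 - suppressor), 0.0, 1.0)
            die = rng.random(tumors.size) < prob
            self.alive[tumors[die]] = False

        # --- tumor division ---
        tumors = self._idx(TUMOR)
        if tumors.size:
            if self.neutral:
                prolif_factor = np.ones(tumors.size)
                apc = myc = np.zeros(tumors.size)
            else:
                # each damaged proliferative oncogene cuts growth multiplicatively
                harm = self.scores[tumors][:, self.panel.proliferation_harm_idx]
                prolif_factor = np.prod(1.0 - p.prolif_loss * harm, axis=1)
                apc = self.scores[tumors, self.panel.apc_idx]
                myc = self.scores[tumors, self.panel.myc_idx]
            e_eff = self.e_tg[tumors] * prolif_factor * (1.0 + p.apc_gain * apc)
            if self.vessel_pos.shape[0]:
                vd, _ = cKDTree(self.vessel_pos).query(self.pos[tumors], k=1)
                e_eff = e_eff * np.where(vd < c.vessel_radius, 1.0 + p.vessel_boost, 1.0)
            e_eff = np.clip(e_eff, 0.0, 1.0)
            prob = np.clip((e_eff * p.w1 + myc * p.w2) / 2.0 + p.b1, 0.0, 1.0)
            prob *= therapy_mod.tki_duplication_factor(tki, p.tki_prolif_block)
            crowd = cKDTree(self.pos[tumors]).query_ball_point(
                self.pos[tumors], c.crowd_radius, return_length=True)
            prob = np.where(np.asarray(crowd) > c.crowd_cap, 0.0, prob)
            parents = tumors[rng.random(tumors.size) < prob]
            if parents.size:
                child = self.genomes[parents].copy()
                hit = rng.random(child.shape) < self.mut_rate[parents][:, None]
                nh = int(hit.sum())
                if nh:
                    child[hit] = (child[hit] + rng.integers(1, 4, size=nh).astype(np.uint8)) % 4
                ang = rng.uniform(0, 2 * np.pi, parents.size)
                r = rng.uniform(0.2, 1.0, parents.size)
                offset = np.column_stack([np.cos(ang), np.sin(ang)]) * r[:, None]
                cpos = np.clip(self.pos[parents] + offset, [0, 0], [c.width, c.height])
                self._append(TUMOR, cpos, genomes=child, e_tg=self.e_tg[parents].copy())

        # --- therapy effects (recovery + infiltration) ---
        therapy_mod.ici_effects(self, ici, p, rng)

        # --- angiogenesis ---
        tumors = self._idx(TUMOR)
        from .tme import angiogenesis_probability
        pa = angiogenesis_probability(p.p_angio, tumors.size, p.n_half, tki)
        if tumors.size and rng.random() < pa:
            anchor = self.pos[tumors[rng.integers(tumors.size)]]
            sprout = np.clip(anchor + rng.normal(scale=2.0, size=2), [0, 0], [c.width, c.height])
            self.vessel_pos = np.concatenate([self.vessel_pos, sprout[None]])

        # --- cleanup: drop dead agents, record trajectory ---
        keep = self.alive
        for name in ("kind", "pos", "alive", "exh", "activated", "phag",
                     "e_tg", "genomes", "scores", "neo", "mut_rate"):
            setattr(self, name, getattr(self, name)[keep])
        self._record()

    def trajectory(self) -> pd.DataFrame:
        return pd.DataFrame(self.trajectory_rows)

    def mutation_profile(self) -> MutationProfile:
        tumors = self._idx(TUMOR)
        if tumors.size == 0:
            zeros = np.zeros(self.panel.total_length)
            per_gene = {n: 0.0 for n in self.panel.names}
            return MutationProfile(zeros, per_gene)
        return population_mutation_profile(self.genomes[tumors], self.panel)


def simulation_step(state: SimulationState) -> SimulationState:
    """Advance the state by one step (in place; returned for chaining)."""
    state.step()
    return state


def run_simulation(config: SimulationConfig, image, seed: int | None = None,
                   panel: GenePanel | None = None) -> SimulationOutcome:
    """Simulate one virtual patient to completion.

    ``image`` provides the initial state: agent counts, hormone levels, and
    initial tumor/CD8 conditions (a :class:`rccsim.cohort.VirtualImage` or
    :class:`rccsim.host.HostState`). ``seed`` overrides ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    state = SimulationState(config, image, rng, panel=panel)
    os_steps, survived = config.max_steps, True
    for _ in range(config.max_steps):
        state.step()
        burden = state.tumor_count()
        if burden >= config.lethal_burden:
            os_steps, survived = state.t, False
            break
        if burden == 0:
            break
    else:
        survived = state.tumor_count() < config.lethal_burden
    return SimulationOutcome(
        os=os_steps,
        survived=survived,
        trajectory=state.trajectory(),
        final_mutation_profile=state.mutation_profile(),
    )
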