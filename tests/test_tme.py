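"""Perception graph and cooperation/competition interaction rules."""

import numpy as np
import pytest

from rccsim.tme import (
    Agent,
    Vessel,
    angiogenesis_probability,
    angiogenesis_step,
    build_interaction_graph,
    capture_probability,
    ctl_kill_attempt,
    dc_cycle,
    inhibition_probability,
    kill_probability,
    resolve_auxiliary_interactions,
    tumor_checkpoint_inhibition,
)
from rccsim.params import LearnableParameterSet


def brute_force_edges(agents):
    """All-pairs oracle for the perception graph."""
    alive = [a for a in agents if a.alive]
    edges = set()
    for a in alive:
        for b in alive:
            if a.id != b.id and np.linalg.norm(a.position - b.position) < a.search_dimension:
                edges.add((a.id, b.id))
    return edges


def random_scene(rng, n, size=50.0):
    return [
        Agent(id=i, kind="tumor" if rng.random() < 0.5 else "cd8",
              position=rng.uniform(0, size, 2),
              search_dimension=float(rng.uniform(0.5, 8.0)))
        for i in range(n)
    ]


class TestInteractionGraph:
    def test_empty_scene(self):
        assert build_interaction_graph([]).edges == set()

    def test_symmetric_under_equal_search_dimension(self):
        a = Agent(id=0, kind="tumor", position=(0.0, 0.0), search_dimension=2.0)
        b = Agent(id=1, kind="cd8", position=(1.0, 0.0), search_dimension=2.0)
        assert build_interaction_graph([a, b]).edges == {(0, 1), (1, 0)}

    def test_asymmetric_perception(self):
        a = Agent(id=0, kind="tumor", position=(0.0, 0.0), search_dimension=5.0)
        b = Agent(id=1, kind="cd8", position=(3.0, 0.0), search_dimension=1.0)
        assert build_interaction_graph([a, b]).edges == {(0, 1)}

    def test_boundary_distance_excluded(self):
        a = Agent(id=0, kind="tumor", position=(0.0, 0.0), search_dimension=1.0)
        b = Agent(id=1, kind="cd8", position=(1.0, 0.0), search_dimension=1.5)
        assert build_interaction_graph([a, b]).edges == {(1, 0)}

    def test_dead_agents_never_appear(self, rng):
        agents = random_scene(rng, 30)
        for a in agents[:10]:
            a.alive = False
        edges = build_interaction_graph(agents).edges
        dead = {a.id for a in agents[:10]}
        assert all(s not in dead and t not in dead for s, t in edges)

    def test_zero_search_dimension_isolates(self, rng):
        agents = random_scene(rng, 20)
        for a in agents:
            a.search_dimension = 0.0
        assert build_interaction_graph(agents).edges == set()

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            agents = random_scene(rng, 50)
            assert build_interaction_graph(agents).edges == brute_force_edges(agents)


class TestProbabilityFormulas:
    def test_kill_probability_product(self):
        assert kill_probability(0.8, 0.5, 1.0, 0.0) == pytest.approx(0.4)

    def test_full_exhaustion_never_kills(self):
        assert kill_probability(0.9, 1.0, 1.5, 0.0) == 0.0

    def test_full_evasion_never_killed(self):
        assert kill_probability(0.9, 0.0, 1.5, 1.0) == 0.0

    def test_inhibition_product(self):
        assert inhibition_probability(0.6, 0.5, 0.5) == pytest.approx(0.15)

    def test_full_checkpoint_block(self):
        assert inhibition_probability(0.9, 1.0, 1.0) == 0.0

    def test_wildtype_checkpoint_never_inhibits(self):
        assert inhibition_probability(0.9, 0.0, 0.0) == 0.0

    def test_full_tki_guarantees_capture(self):
        assert capture_probability(0.0, 0.0, 0.0, 1.0, 1.0) == 1.0

    def test_angiogenesis_zero_cases(self):
        assert angiogenesis_probability(0.5, 0, 100, 0.0) == 0.0
        assert angiogenesis_probability(0.5, 1000, 100, 1.0) == 0.0

    def test_all_probabilities_bounded(self, rng):
        for _ in range(500):
            args = rng.uniform(0, 2, size=4)
            assert 0.0 <= kill_probability(*args) <= 1.0
            assert 0.0 <= inhibition_probability(args[0], args[1], rng.uniform(0, 1)) <= 1.0
            assert 0.0 <= capture_probability(rng.uniform(0, 1), args[0], args[1],
                                              rng.uniform(0.2, 2), rng.uniform(0, 1)) <= 1.0
            assert 0.0 <= angiogenesis_probability(rng.uniform(0, 1), rng.integers(0, 500),
                                                   100, rng.uniform(0, 1)) <= 1.0


def _dc(pos=(0.0, 0.0), phagocytized=False):
    return Agent(id=0, kind="dendritic", position=pos, phagocytized=phagocytized)


def _tumor(pos=(0.5, 0.0), scores=None, neo=0.0, ident=1):
    return Agent(id=ident, kind="tumor", position=pos, scores=scores or {},
                 neoantigen_load=neo)


class TestDendriticCycle:
    def test_zero_capture_chance_never_captures(self, rng):
        params = LearnableParameterSet(p_phago=0.0, neo_gain=0.0)
        for _ in range(50):
            dc, tu = _dc(), _tumor()
            agents = {0: dc, 1: tu}
            graph = build_interaction_graph(list(agents.values()))
            dc_cycle(dc, graph, agents, params, rng)
            assert not dc.phagocytized

    def test_certain_capture_on_contact(self, rng):
        params = LearnableParameterSet(p_phago=1.0)
        dc, tu = _dc(), _tumor()
        agents = {0: dc, 1: tu}
        graph = build_interaction_graph(list(agents.values()))
        events = dc_cycle(dc, graph, agents, params, rng)
        assert dc.phagocytized and events[0].kind == "capture"

    def test_loaded_dc_activates_cd8_and_resets(self, rng):
        params = LearnableParameterSet()
        dc = _dc(phagocytized=True)
        cd8 = Agent(id=2, kind="cd8", position=(0.4, 0.0), activated=False)
        agents = {0: dc, 2: cd8}
        graph = build_interaction_graph(list(agents.values()))
        events = dc_cycle(dc, graph, agents, params, rng)
        assert cd8.activated and not dc.phagocytized
        assert events[0].kind == "activate"


class TestCtlKill:
    def test_inactive_cd8_is_noop(self, rng):
        cd8 = Agent(id=0, kind="cd8", position=(0, 0), activated=False)
        tu = _tumor()
        assert ctl_kill_attempt(cd8, tu, LearnableParameterSet(base_kill=1.0), rng) is False
        assert tu.alive

    def test_fully_exhausted_never_kills(self, rng):
        cd8 = Agent(id=0, kind="cd8", position=(0, 0), activated=True, exhaustion=1.0)
        for _ in range(50):
            assert not ctl_kill_attempt(cd8, _tumor(), LearnableParameterSet(base_kill=1.0), rng)

    def test_full_antigen_evasion_blocks_kill(self, rng):
        cd8 = Agent(id=0, kind="cd8", position=(0, 0), activated=True)
        scores = {g: 1.0 for g in ("HLA-A", "HLA-B", "HLA-C", "JAK1", "JAK2",
                                   "B2M", "TAP1", "TAP2")}
        for _ in range(50):
            assert not ctl_kill_attempt(cd8, _tumor(scores=scores),
                                        LearnableParameterSet(base_kill=1.0), rng)

    def test_certain_kill(self, rng):
        cd8 = Agent(id=0, kind="cd8", position=(0, 0), activated=True)
        tu = _tumor()
        assert ctl_kill_attempt(cd8, tu, LearnableParameterSet(base_kill=1.0), rng)
        assert not tu.alive


class TestCheckpointInhibition:
    def test_full_ici_blocks(self, rng):
        tu = _tumor(scores={"CD274": 1.0})
        cd8 = Agent(id=0, kind="cd8", position=(0, 0), activated=True)
        params = LearnableParameterSet(base_inhibit=1.0, delta_exh=0.3)
        for _ in range(50):
            assert tumor_checkpoint_inhibition(tu, cd8, 1.0, params, rng) == 0.0
        assert cd8.exhaustion == 0.0

    def test_wildtype_checkpoint_inert(self, rng):
        tu = _tumor(scores={"CD274": 0.0})
        cd8 = Agent(id=0, kind="cd8", position=(0, 0), activated=True)
        params = LearnableParameterSet(base_inhibit=1.0)
        for _ in range(50):
            assert tumor_checkpoint_inhibition(tu, cd8, 0.0, params, rng) == 0.0

    def test_exhaustion_increment_clamped(self, rng):
        tu = _tumor(scores={"CD274": 1.0})
        cd8 = Agent(id=0, kind="cd8", position=(0, 0), activated=True, exhaustion=0.9)
        params = LearnableParameterSet(base_inhibit=1.0, delta_exh=0.5)
        tumor_checkpoint_inhibition(tu, cd8, 0.0, params, rng)
        assert cd8.exhaustion == 1.0


class TestAuxiliaryInteractions:
    def test_full_tki_blocks_differentiation(self, rng):
        cd4 = Agent(id=0, kind="cd4", position=(0, 0))
        agents = {0: cd4}
        graph = build_interaction_graph([cd4])
        params = LearnableParameterSet(p_diff=1.0)
        for _ in range(30):
            resolve_auxiliary_interactions(graph, agents, params, rng, tki_intensity=1.0)
            assert cd4.kind == "cd4"

    def test_nk_kill_ignores_antigen_evasion(self, rng):
        nk = Agent(id=0, kind="nk", position=(0, 0))
        scores = {g: 1.0 for g in ("HLA-A", "HLA-B", "HLA-C", "JAK1", "JAK2",
                                   "B2M", "TAP1", "TAP2")}
        tu = _tumor(pos=(0.5, 0.0), scores=scores)
        agents = {0: nk, 1: tu}
        graph = build_interaction_graph(list(agents.values()))
        events = resolve_auxiliary_interactions(graph, agents,
                                                LearnableParameterSet(nk_kill=1.0), rng)
        assert not tu.alive and events[0].kind == "nk_kill"

    def test_treg_raises_exhaustion(self, rng):
        treg = Agent(id=0, kind="treg", position=(0, 0))
        cd8 = Agent(id=1, kind="cd8", position=(0.5, 0.0), activated=True)
        agents = {0: treg, 1: cd8}
        graph = build_interaction_graph(list(agents.values()))
        resolve_auxiliary_interactions(graph, agents,
                                       LearnableParameterSet(treg_suppress=0.2), rng)
        assert cd8.exhaustion == pytest.approx(0.2)

    def test_no_edges_no_events(self, rng):
        nk = Agent(id=0, kind="nk", position=(0, 0), search_dimension=0.0)
        tu = _tumor(pos=(30.0, 30.0))
        agents = {0: nk, 1: tu}
        graph = build_interaction_graph(list(agents.values()))
        events = resolve_auxiliary_interactions(
            graph, agents, LearnableParameterSet(nk_kill=1.0, p_diff=0.0), rng)
        assert events == []


class TestAngiogenesis:
    def test_no_tumor_no_sprout(self, rng):
        vessels = [Vessel((5.0, 5.0))]
        out = angiogenesis_step(vessels, np.empty((0, 2)), 0.0,
                                LearnableParameterSet(p_angio=1.0), rng)
        assert len(out) == 1

    def test_full_tki_blocks_sprouting(self, rng):
        vessels = []
        pos = rng.uniform(0, 10, size=(200, 2))
        for _ in range(50):
            angiogenesis_step(vessels, pos, 1.0, LearnableParameterSet(p_angio=1.0), rng)
        assert vessels == []

    def test_sprout_frequency_matches_probability(self):
        rng = np.random.default_rng(11)
        params = LearnableParameterSet(p_angio=0.2, n_half=100)
        pos = rng.uniform(0, 10, size=(150, 2))  # above n_half -> saturated
        n_steps = 1000
        vessels = []
        for _ in range(n_steps):
            angiogenesis_step(vessels, pos, 0.0, params, rng)
        se = np.sqrt(0.2 * 0.8 * n_steps)
        assert abs(len(vessels) - 0.2 * n_steps) < 3 * se
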