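"""Genetic representation: translation, scoring, inheritance, selection."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import mannwhitneyu

from rccsim.genome import (
    EmptyPopulationError,
    GeneSegment,
    GeneSpec,
    Genome,
    InvalidSequenceError,
    effective_mutation_rate,
    expression_level,
    inherit_genome,
    mutation_score,
    population_mutation_profile,
    selection_simulation,
    translate,
)


class TestTranslate:
    @pytest.mark.parametrize("coding,protein", [
        ("ATG", "M"),
        ("ATGTAAATG", "M"),      # stop truncates
        ("TTTAAAGGG", "FKG"),
        ("TAA", ""),             # immediate stop
    ])
    def test_examples(self, coding, protein):
        assert translate(coding) == protein

    @pytest.mark.parametrize("bad", ["AT", "ATGN", "", "ATGU"])
    def test_invalid_sequences_rejected(self, bad):
        with pytest.raises(InvalidSequenceError):
            translate(bad)

    def test_matches_biopython_on_panel_wildtypes(self, panel):
        for spec in panel.specs:
            expected = str(Seq(spec.wildtype_coding).translate())
            assert translate(spec.wildtype_coding) == expected
            assert expected == spec.wildtype_protein  # frozen fixture value

    def test_matches_biopython_on_random_sequences(self, rng):
        bases = "ACGT"
        for _ in range(200):
            seq = "".join(bases[i] for i in rng.integers(0, 4, size=30))
            bio = str(Seq(seq).translate(to_stop=True))
            assert translate(seq) == bio


class TestExpressionLevel:
    def test_identical_promoters_are_neutral(self):
        assert expression_level("ACGTACGT", "ACGTACGT") == 1.0

    def test_fully_mutated_doubles_at_unit_coefficient(self):
        assert expression_level("CCCC", "AAAA", k_expr=1.0) == 2.0

    def test_partial_mutation(self):
        wt = "A" * 20
        mut = "C" * 2 + "A" * 18
        assert expression_level(mut, wt, k_expr=1.0) == pytest.approx(1.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidSequenceError):
            expression_level("AAA", "AAAA")

    def test_monotone_in_hamming_distance(self, rng):
        wt = "ACGT" * 5
        prev = 0.0
        for k in range(21):
            mut = "".join("C" if c == "A" else "A" for c in wt[:k]) + wt[k:]
            level = expression_level(mut, wt)
            assert level >= prev
            prev = level


def _spec_with(promoter="A" * 20, coding="ATG" + "AAA" * 9):
    return GeneSpec(name="X", wildtype_promoter=promoter, wildtype_coding=coding,
                    wildtype_protein=translate(coding),
                    effect_category="checkpoint",
                    effect_direction="mutation_benefits_tumor")


class TestMutationScore:
    def test_wildtype_scores_zero(self):
        spec = _spec_with()
        seg = GeneSegment(spec.wildtype_promoter, spec.wildtype_coding)
        assert mutation_score(seg, spec) == 0.0

    def test_promoter_only_mutation_scores_zero(self):
        # expression amplifies a protein change; alone it is silent
        spec = _spec_with()
        seg = GeneSegment("C" * 20, spec.wildtype_coding)
        assert mutation_score(seg, spec) == 0.0

    def test_full_protein_mismatch_clamps_to_one(self):
        spec = _spec_with(coding="AAA" * 10)          # KKKKKKKKKK
        seg = GeneSegment(spec.wildtype_promoter, "GGG" * 10)  # GGGGGGGGGG
        assert mutation_score(seg, spec) == 1.0

    def test_one_residue_with_doubled_expression(self):
        # 1 of 10 residues changed, fully mutated promoter, k_expr 1 -> 0.2
        spec = _spec_with(coding="AAA" * 10)
        seg = GeneSegment("C" * 20, "GGG" + "AAA" * 9)
        assert mutation_score(seg, spec) == pytest.approx(0.2)

    def test_premature_stop_counts_downstream_as_mismatch(self):
        spec = _spec_with(coding="AAA" * 10)
        seg = GeneSegment(spec.wildtype_promoter, "TAA" + "AAA" * 9)
        assert mutation_score(seg, spec) == pytest.approx(1.0)

    def test_score_bounded_on_random_segments(self, panel, rng):
        bases = "ACGT"
        spec = panel.specs[0]
        for _ in range(200):
            prom = "".join(bases[i] for i in rng.integers(0, 4, size=20))
            cod = "".join(bases[i] for i in rng.integers(0, 4, size=60))
            s = mutation_score(GeneSegment(prom, cod), spec, k_expr=2.0)
            assert 0.0 <= s <= 1.0


class TestEffectiveMutationRate:
    def test_wildtype_returns_base_rate(self, panel):
        g = panel.wildtype_genome()
        assert effective_mutation_rate(g, 0.001, instability_gain=5.0) == 0.001

    def test_fully_mutated_brca_doubles_rate_at_unit_gain(self, panel):
        codes = panel.wildtype.copy()
        for name in ("BRCA1", "BRCA2"):
            sl = panel.gene_slices[name]
            codes[sl] = (codes[sl] + 2) % 4  # transversion at every position
        g = Genome(codes, panel)
        scores = g.scores()
        assert scores["BRCA1"] == 1.0 and scores["BRCA2"] == 1.0
        assert effective_mutation_rate(g, 0.001, 1.0) == pytest.approx(0.002)

    def test_clamped_to_one(self, panel):
        codes = panel.wildtype.copy()
        for name in ("BRCA1", "BRCA2"):
            sl = panel.gene_slices[name]
            codes[sl] = (codes[sl] + 2) % 4
        assert effective_mutation_rate(Genome(codes, panel), 0.9, 1.0) == 1.0

    def test_monotone_in_gain(self, panel, rng):
        from rccsim.genome import mutate_codes

        g = Genome(mutate_codes(panel.wildtype, 0.05, rng), panel)
        rates = [effective_mutation_rate(g, 0.001, gain) for gain in (0, 1, 2, 5)]
        assert rates == sorted(rates)


class TestInheritGenome:
    def test_zero_rate_copies_exactly(self, panel, rng):
        parent = panel.wildtype_genome()
        child = inherit_genome(parent, 0.0, rng)
        assert np.array_equal(child.codes, parent.codes)

    def test_unit_rate_substitutes_every_position(self, panel, rng):
        parent = panel.wildtype_genome()
        child = inherit_genome(parent, 1.0, rng)
        assert np.all(child.codes != parent.codes)

    def test_substitution_count_matches_binomial(self, panel):
        rng = np.random.default_rng(77)
        parent = panel.wildtype_genome()
        rate, n_rep = 0.01, 300
        L = panel.total_length
        hits = [int((inherit_genome(parent, rate, rng).codes != parent.codes).sum())
                for _ in range(n_rep)]
        mean = np.mean(hits)
        se = np.sqrt(L * rate * (1 - rate) / n_rep)
        assert abs(mean - L * rate) < 3 * se

    def test_deterministic_under_fixed_seed(self, panel):
        parent = panel.wildtype_genome()
        a = inherit_genome(parent, 0.05, np.random.default_rng(5))
        b = inherit_genome(parent, 0.05, np.random.default_rng(5))
        assert np.array_equal(a.codes, b.codes)


class TestPopulationMutationProfile:
    def test_all_wildtype_is_zero(self, panel):
        cells = [panel.wildtype_genome() for _ in range(4)]
        prof = population_mutation_profile(cells)
        assert not prof.per_nucleotide_fraction.any()
        assert all(v == 0.0 for v in prof.per_gene_mean.values())

    def test_single_mutant_position_fraction(self, panel):
        cells = [panel.wildtype_genome() for _ in range(4)]
        cells[0].codes[10] = (cells[0].codes[10] + 1) % 4
        prof = population_mutation_profile(cells)
        assert prof.per_nucleotide_fraction[10] == 0.25
        assert prof.per_nucleotide_fraction.sum() == 0.25

    def test_single_cell_profile_is_binary_mask(self, panel, rng):
        from rccsim.genome import mutate_codes

        g = Genome(mutate_codes(panel.wildtype, 0.1, rng), panel)
        prof = population_mutation_profile([g])
        assert set(np.unique(prof.per_nucleotide_fraction)) <= {0.0, 1.0}
        assert np.array_equal(prof.per_nucleotide_fraction.astype(bool),
                              g.codes != panel.wildtype)

    def test_union_is_size_weighted_mean(self, panel, rng):
        from rccsim.genome import mutate_codes

        a = [Genome(mutate_codes(panel.wildtype, 0.05, rng), panel) for _ in range(3)]
        b = [Genome(mutate_codes(panel.wildtype, 0.05, rng), panel) for _ in range(5)]
        pa = population_mutation_profile(a).per_nucleotide_fraction
        pb = population_mutation_profile(b).per_nucleotide_fraction
        pu = population_mutation_profile(a + b).per_nucleotide_fraction
        np.testing.assert_allclose(pu, (3 * pa + 5 * pb) / 8)

    def test_empty_population_rejected(self, panel):
        with pytest.raises(EmptyPopulationError):
            population_mutation_profile([])


_SELECTION_KW = dict(kill_rate=0.25, division_rate=0.4, mutation_rate=0.001,
                     checkpoint_protection=0.8, instability_gain=12.0,
                     n_init=200, capacity=800)
_SELECTION_SEEDS = 10


@pytest.fixture(scope="module")
def arms(panel):
    sel, neu = [], []
    for s in range(_SELECTION_SEEDS):
        sel.append(selection_simulation(
            panel, np.random.default_rng(s), return_population=True, **_SELECTION_KW))
        neu.append(selection_simulation(
            panel, np.random.default_rng(7000 + s), selection=False,
            return_population=True, **_SELECTION_KW))
    return sel, neu


class TestSelectionSimulation:
    """Tumor evolution under sustained immune pressure vs neutral drift.

    Under selection, immune-evasion loci (PD-L1 checkpoint) rise above and
    proliferation oncogenes (EGFR) fall below the genome-wide drift level,
    and BRCA-driven hypermutator lineages carry genome-wide excess load.
    """

    @staticmethod
    def _excess(profile, gene):
        means = profile.per_gene_mean
        return means[gene] - np.mean(list(means.values()))

    def test_checkpoint_gene_enriched_under_selection(self, arms):
        sel, neu = arms
        a = [self._excess(p, "CD274") for p, _ in sel]
        b = [self._excess(p, "CD274") for p, _ in neu]
        assert mannwhitneyu(a, b, alternative="greater").pvalue < 0.05

    def test_proliferation_oncogene_purged_under_selection(self, arms):
        sel, neu = arms
        a = [self._excess(p, "EGFR") for p, _ in sel]
        b = [self._excess(p, "EGFR") for p, _ in neu]
        assert mannwhitneyu(a, b, alternative="less").pvalue < 0.05

    def test_brca_load_predicts_hypermutation_under_selection(self, arms, panel):
        brca_cols = np.concatenate([
            np.arange(panel.gene_slices[g].start, panel.gene_slices[g].stop)
            for g in ("BRCA1", "BRCA2")])
        other_cols = np.setdiff1d(np.arange(panel.total_length), brca_cols)

        def assoc(pop):
            mask = pop != panel.wildtype
            brca = mask[:, brca_cols].mean(axis=1)
            rest = mask[:, other_cols].mean(axis=1)
            if brca.std() < 1e-12 or rest.std() < 1e-12:
                return 0.0
            return float(np.corrcoef(brca, rest)[0, 1])

        sel, neu = arms
        a = [assoc(pop) for _, pop in sel]
        b = [assoc(pop) for _, pop in neu]
        assert mannwhitneyu(a, b, alternative="greater").pvalue < 0.05
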