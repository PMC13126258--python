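"""Tumor-cell genetic representation and mutation scoring.

Each tumor cell carries a fixed-layout string of nucleotides divided into one
segment per gene of a 19-gene panel (antigen presentation, checkpoint,
genomic instability, tumor suppressors, proliferation oncogenes, division
control). Every segment has a promoter part, whose mutations scale
expression, and a coding part, whose mutations alter the translated protein.
The mutation score of a gene is the fraction of altered protein residues
multiplied by the promoter expression level, clamped to [0, 1]; these scores
drive the behavioral effects of mutations during a simulation (immune
evasion, checkpoint engagement, genomic instability, proliferation changes).

Only point substitutions are modeled, so all segments keep their wildtype
lengths and per-nucleotide comparison against the wildtype is well defined.
The genome is stored internally as a ``numpy`` ``uint8`` code array
(A=0, C=1, G=2, T=3) so that scoring whole populations stays vectorized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np

__all__ = [
    "GeneSpec",
    "GeneSegment",
    "Genome",
    "MutationProfile",
    "GenePanel",
    "InvalidSequenceError",
    "EmptyPopulationError",
    "default_panel",
    "translate",
    "expression_level",
    "mutation_score",
    "effective_mutation_rate",
    "inherit_genome",
    "population_mutation_profile",
    "selection_simulation",
]

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}
_STOP = ord("*")

# Codon table indexed by 16*b0 + 4*b1 + b2 over base codes A=0,C=1,G=2,T=3.
_CODON_AA = np.zeros(64, dtype=np.uint8)
_STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
for _codon, _aa in _STANDARD_TABLE.items():
    _idx = 16 * _BASE_CODE[_codon[0]] + 4 * _BASE_CODE[_codon[1]] + _BASE_CODE[_codon[2]]
    _CODON_AA[_idx] = ord(_aa)


class InvalidSequenceError(ValueError):
    """Raised for non-ACGT characters or malformed sequence lengths."""


class EmptyPopulationError(ValueError):
    """Raised when a population-level statistic is requested on zero cells."""


@dataclass(frozen=True)
class GeneSpec:
    """Wildtype definition and effect annotation for one panel gene."""

    name: str
    wildtype_promoter: str
    wildtype_coding: str
    wildtype_protein: str
    effect_category: str
    effect_direction: str

    def __post_init__(self) -> None:
        for seq in (self.wildtype_promoter, self.wildtype_coding):
            if not set(seq) <= set(_BASES):
                raise InvalidSequenceError(f"{self.name}: non-ACGT wildtype sequence")
        if len(self.wildtype_coding) < 3 or len(self.wildtype_coding) % 3:
            raise InvalidSequenceError(f"{self.name}: coding length must be a positive multiple of 3")


@dataclass(frozen=True)
class GeneSegment:
    """A cell's (possibly mutated) promoter and coding sequence for one gene."""

    promoter: str
    coding: str


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.uint8)
    except KeyError as exc:
        raise InvalidSequenceError(f"non-ACGT character {exc}") from None


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


class GenePanel:
    """Registry of the gene panel with a fixed concatenated genome layout.

    Layout per gene ``g``: ``[promoter | coding]`` blocks concatenated in
    panel order. Index helpers are precomputed so batched scoring of whole
    tumor populations is pure array arithmetic.
    """

    def __init__(self, specs: Sequence[GeneSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene in panel")
        self.specs: List[GeneSpec] = list(specs)
        self.names: List[str] = names
        self.index: Dict[str, int] = {n: i for i, n in enumerate(names)}

        prom_idx, cod_idx, slices = [], [], {}
        wt = []
        pos = 0
        for s in specs:
            lp, lc = len(s.wildtype_promoter), len(s.wildtype_coding)
            prom_idx.append(np.arange(pos, pos + lp))
            cod_idx.append(np.arange(pos + lp, pos + lp + lc))
            slices[s.name] = slice(pos, pos + lp + lc)
            wt.append(_encode(s.wildtype_promoter))
            wt.append(_encode(s.wildtype_coding))
            pos += lp + lc
        self.total_length = pos
        self.gene_slices = slices
        self.wildtype = np.concatenate(wt)
        # Homogeneous segment lengths allow rectangular index matrices.
        if len({a.size for a in prom_idx}) == 1 and len({a.size for a in cod_idx}) == 1:
            self._prom_idx = np.stack(prom_idx)          # (G, Lp)
            self._cod_idx = np.stack(cod_idx)            # (G, Lc)
        else:  # pragma: no cover - default panel is homogeneous
            raise ValueError("panel requires homogeneous segment lengths")
        self.n_codons = self._cod_idx.shape[1] // 3
        self._wt_aa = self._translate_codes(self.wildtype[self._cod_idx][None])[0]

        def group(cat: str) -> np.ndarray:
            return np.array([i for i, s in enumerate(specs) if s.effect_category == cat])

        self.antigen_idx = group("antigen_presentation")
        self.checkpoint_idx = group("checkpoint")
        self.instability_idx = group("genomic_instability")
        self.suppressor_idx = group("tumor_suppressor")
        self.proliferation_harm_idx = np.array(
            [i for i, s in enumerate(specs)
             if s.effect_category == "proliferation" and s.effect_direction == "mutation_harms_tumor"]
        )
        self.myc_idx = self.index["MYC"]
        self.apc_idx = self.index["APC"]

    def _translate_codes(self, coding: np.ndarray) -> np.ndarray:
        """(..., G, Lc) base codes -> (..., G, n_codons) amino-acid codes."""
        c = coding.reshape(*coding.shape[:-1], self.n_codons, 3).astype(np.int64)
        return _CODON_AA[c[..., 0] * 16 + c[..., 1] * 4 + c[..., 2]]

    # -- batched scoring -------------------------------------------------
    def gene_scores(self, genomes: np.ndarray, k_expr: float) -> np.ndarray:
        """Mutation scores for a batch of genomes.

        Parameters
        ----------
        genomes : uint8 array of shape (n, total_length)
        k_expr : promoter expression coefficient

        Returns
        -------
        (n, G) array of scores in [0, 1]. A premature stop codon counts
        every residue from the stop onwards as mismatched.
        """
        g = np.atleast_2d(genomes)
        aa = self._translate_codes(g[:, self._cod_idx])
        mism = aa != self._wt_aa
        truncated = np.cumsum(aa == _STOP, axis=-1) > 0
        ham = (mism | truncated).mean(axis=-1)
        prom_ham = (g[:, self._prom_idx] != self.wildtype[self._prom_idx]).mean(axis=-1)
        expr = 1.0 + k_expr * prom_ham
        return np.clip(ham * expr, 0.0, 1.0)

    def neoantigen_load(self, genomes: np.ndarray) -> np.ndarray:
        """Per-cell mean nucleotide mutation fraction (neoantigen proxy)."""
        g = np.atleast_2d(genomes)
        return (g != self.wildtype).mean(axis=1)

    def wildtype_genome(self) -> "Genome":
        return Genome(self.wildtype.copy(), self)


@dataclass
class Genome:
    """One cell's genome: a code array over the panel's fixed layout."""

    codes: np.ndarray
    panel: GenePanel

    def __post_init__(self) -> None:
        if self.codes.shape != (self.panel.total_length,):
            raise InvalidSequenceError("genome length does not match panel layout")

    @classmethod
    def from_segments(cls, segments: Mapping[str, GeneSegment], panel: GenePanel) -> "Genome":
        if set(segments) != set(panel.names):
            raise InvalidSequenceError("segment keys must exactly match the panel")
        codes = panel.wildtype.copy()
        for name, seg in segments.items():
            spec = panel.specs[panel.index[name]]
            if len(seg.promoter) != len(spec.wildtype_promoter) or len(seg.coding) != len(spec.wildtype_coding):
                raise InvalidSequenceError(f"{name}: segment lengths differ from wildtype")
            codes[panel.gene_slices[name]] = np.concatenate([_encode(seg.promoter), _encode(seg.coding)])
        return cls(codes, panel)

    @property
    def segments(self) -> Dict[str, GeneSegment]:
        out = {}
        for name in self.panel.names:
            spec = self.panel.specs[self.panel.index[name]]
            block = self.codes[self.panel.gene_slices[name]]
            lp = len(spec.wildtype_promoter)
            out[name] = GeneSegment(_decode(block[:lp]), _decode(block[lp:]))
        return out

    def scores(self, k_expr: float = 1.0) -> Dict[str, float]:
        row = self.panel.gene_scores(self.codes[None], k_expr)[0]
        return dict(zip(self.panel.names, row.tolist()))


@dataclass(frozen=True)
class MutationProfile:
    """Population mutation-mask average.

    ``per_nucleotide_fraction[p]`` is the fraction of cells whose nucleotide
    at position ``p`` differs from wildtype; ``per_gene_mean`` averages those
    fractions over each gene's positions.
    """

    per_nucleotide_fraction: np.ndarray
    per_gene_mean: Dict[str, float]

    def to_frame(self, panel: GenePanel):
        import pandas as pd

        gene_of = np.empty(panel.total_length, dtype=object)
        for name, sl in panel.gene_slices.items():
            gene_of[sl] = name
        return pd.DataFrame(
            {
                "position": np.arange(panel.total_length),
                "gene": gene_of,
                "fraction": self.per_nucleotide_fraction,
            }
        )


_DEFAULT_PANEL: GenePanel | None = None


def default_panel() -> GenePanel:
    """The shipped 19-gene synthetic-wildtype panel (loaded once)."""
    global _DEFAULT_PANEL
    if _DEFAULT_PANEL is None:
        raw = json.loads(resources.files("rccsim.data").joinpath("gene_panel.json").read_text())
        _DEFAULT_PANEL = GenePanel([GeneSpec(**g) for g in raw["genes"]])
    return _DEFAULT_PANEL


# -- string-level operations ----------------------------------------------

def translate(coding: str) -> str:
    """Standard-genetic-code translation; a stop codon truncates the protein.

    Raises :class:`InvalidSequenceError` for non-ACGT input or a length not
    divisible by 3.
    """
    if len(coding) % 3 or not coding:
        raise InvalidSequenceError("coding length must be a positive multiple of 3")
    codes = _encode(coding).astype(np.int64).reshape(-1, 3)
    aa = _CODON_AA[codes[:, 0] * 16 + codes[:, 1] * 4 + codes[:, 2]]
    protein = "".join(chr(c) for c in aa)
    stop = protein.find("*")
    return protein if stop < 0 else protein[:stop]


def expression_level(promoter: str, wildtype_promoter: str, k_expr: float = 1.0) -> float:
    """Promoter expression multiplier: ``1 + k_expr * hamming / length``."""
    if len(promoter) != len(wildtype_promoter):
        raise InvalidSequenceError("promoter length differs from wildtype")
    if not promoter:
        raise InvalidSequenceError("empty promoter")
    ham = int((_encode(promoter) != _encode(wildtype_promoter)).sum())
    return 1.0 + k_expr * ham / len(promoter)


def mutation_score(segment: GeneSegment, spec: GeneSpec, k_expr: float = 1.0) -> float:
    """Gene mutation score in [0, 1].

    Protein hamming fraction (against the wildtype protein, with a premature
    stop counting all downstream residues as mismatched) times the promoter
    expression multiplier, clamped to [0, 1]. Zero iff the translated protein
    equals the wildtype protein.
    """
    if len(segment.coding) != len(spec.wildtype_coding):
        raise InvalidSequenceError(f"{spec.name}: coding length differs from wildtype")
    protein = translate(segment.coding)
    wt = spec.wildtype_protein
    n = len(wt)
    ham = sum(a != b for a, b in zip(protein, wt)) + (n - len(protein))
    expr = expression_level(segment.promoter, spec.wildtype_promoter, k_expr)
    return float(np.clip(ham / n * expr, 0.0, 1.0))


def effective_mutation_rate(genome: Genome, base_rate: float, instability_gain: float,
                            k_expr: float = 1.0) -> float:
    """Per-nucleotide substitution rate raised by genomic-instability mutations.

    ``base_rate * (1 + instability_gain * mean(score(BRCA1), score(BRCA2)))``,
    clamped to [0, 1]; an all-wildtype genome returns exactly ``base_rate``.
    """
    if not 0.0 <= base_rate <= 1.0:
        raise ValueError("base_rate must lie in [0, 1]")
    scores = genome.panel.gene_scores(genome.codes[None], k_expr)[0]
    brca = float(scores[genome.panel.instability_idx].mean())
    return float(np.clip(base_rate * (1.0 + instability_gain * brca), 0.0, 1.0))


def mutate_codes(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point-substitute each position independently with probability ``rate``.

    Substituted positions take a uniform choice among the 3 other bases.
    Accepts a (L,) or (n, L) array; returns a new array of the same shape.
    """
    out = codes.copy()
    hit = rng.random(out.shape) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # new base = (old + 1..3) mod 4 is uniform over the other three bases
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit).astype(np.uint8)) % 4
    return out


def inherit_genome(parent: Genome, rate: float, rng: np.random.Generator) -> Genome:
    """Copy a parent genome with independent per-nucleotide substitutions.

    Tumor division is asexual: inheritance is copy plus point mutation, with
    no crossover. ``rate = 0`` yields an identical copy; ``rate = 1`` forces a
    substitution at every position.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    return Genome(mutate_codes(parent.codes, rate, rng), parent.panel)


def population_mutation_profile(cells: Iterable[Genome] | np.ndarray,
                                panel: GenePanel | None = None) -> MutationProfile:
    """Average binary mutation mask across a tumor population.

    Accepts either an iterable of :class:`Genome` or an (n, L) code array
    plus the panel. Raises :class:`EmptyPopulationError` on zero cells.
    """
    if isinstance(cells, np.ndarray):
        if panel is None:
            raise ValueError("panel required with a raw code array")
        mat = np.atleast_2d(cells)
    else:
        genomes = list(cells)
        if not genomes:
            raise EmptyPopulationError("no tumor cells")
        panel = genomes[0].panel
        mat = np.stack([g.codes for g in genomes])
    if mat.shape[0] == 0:
        raise EmptyPopulationError("no tumor cells")
    frac = (mat != panel.wildtype).mean(axis=0)
    per_gene = {name: float(frac[sl].mean()) for name, sl in panel.gene_slices.items()}
    return MutationProfile(frac, per_gene)


def selection_simulation(panel: GenePanel, rng: np.random.Generator, *,
                         n_steps: int = 500, n_init: int = 100, capacity: int = 400,
                         kill_rate: float = 0.3, division_rate: float = 0.12,
                         mutation_rate: float = 0.004, instability_gain: float = 4.0,
                         checkpoint_protection: float = 0.5, prolif_loss: float = 1.0,
                         k_expr: float = 1.0, selection: bool = True,
                         return_population: bool = False):
    """Well-mixed tumor-evolution run isolating the genetic-selection layer.

    Every step each cell (i) survives an immune attack with probability
    ``1 - kill_rate*(1-evasion)*(1-checkpoint_protection*score(CD274))``
    where evasion is the mean antigen-presentation score, and (ii), while the
    population is below ``capacity``, divides with probability
    ``division_rate * prod(1 - prolif_loss*score(g))`` over the harmful
    proliferation oncogenes, passing its genome to the child with point
    mutations at ``mutation_rate * (1 + instability_gain*mean BRCA score)``.

    With ``selection=False`` every cell experiences the flat wildtype rates
    regardless of genotype — a neutral-drift control in which all genes
    accumulate mutations symmetrically. Because overall turnover differs
    between the arms, selection effects are read off the *within-run excess*
    of a gene over the genome-wide mean fraction, which is zero in
    expectation under drift. Returns the final population mutation profile;
    raises :class:`EmptyPopulationError` if the population dies out.
    """
    pop = np.ascontiguousarray(
        np.broadcast_to(panel.wildtype, (n_init, panel.total_length))
    ).copy()
    scores = panel.gene_scores(pop, k_expr)
    for _ in range(n_steps):
        if selection:
            evasion = scores[:, panel.antigen_idx].mean(axis=1)
            cd274 = scores[:, panel.checkpoint_idx[0]]
            death = kill_rate * (1.0 - evasion) * (1.0 - checkpoint_protection * cd274)
        else:
            death = np.full(pop.shape[0], kill_rate)
        keep = rng.random(pop.shape[0]) >= death
        pop, scores = pop[keep], scores[keep]
        if pop.shape[0] == 0:
            raise EmptyPopulationError("population extinct under selection pressure")
        if pop.shape[0] < capacity:
            if selection:
                harm = scores[:, panel.proliferation_harm_idx]
                div = division_rate * np.prod(1.0 - prolif_loss * harm, axis=1)
                brca = scores[:, panel.instability_idx].mean(axis=1)
                rate = np.clip(mutation_rate * (1.0 + instability_gain * brca), 0.0, 1.0)
            else:
                div = np.full(pop.shape[0], division_rate)
                rate = np.full(pop.shape[0], mutation_rate)
            parents = np.flatnonzero(rng.random(pop.shape[0]) < div)
            if parents.size:
                children = pop[parents].copy()
                hit = rng.random(children.shape) < rate[parents][:, None]
                nh = int(hit.sum())
                if nh:
                    children[hit] = (children[hit]
                                     + rng.integers(1, 4, size=nh).astype(np.uint8)) % 4
                pop = np.concatenate([pop, children])
                scores = np.concatenate([scores, panel.gene_scores(children, k_expr)])
    profile = population_mutation_profile(pop, panel)
    return (profile, pop) if return_population else profile
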