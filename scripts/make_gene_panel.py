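"""Regenerate the synthetic wildtype gene panel fixture.

The simulator's gene panel covers 19 genes implicated in immune evasion,
genomic instability, cell-cycle control and oncogenic signalling. No real
human reference sequences are used: each gene gets a synthetic wildtype
promoter (20 nt) and coding sequence (60 nt, 20 codons, no in-frame stop),
drawn once from a frozen seed so that mutation scores are exact and
reproducible. Wildtype proteins are computed with Biopython's codon table
so the package's own translator can be checked against an independent
implementation.

Run from the repository root:

    python scripts/make_gene_panel.py
"""

import json
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

SEED = 20240917
PROMOTER_LEN = 20
CODING_CODONS = 20
BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}

# (name, effect_category, effect_direction)
PANEL = [
    ("HLA-A", "antigen_presentation", "mutation_benefits_tumor"),
    ("HLA-B", "antigen_presentation", "mutation_benefits_tumor"),
    ("HLA-C", "antigen_presentation", "mutation_benefits_tumor"),
    ("JAK1", "antigen_presentation", "mutation_benefits_tumor"),
    ("JAK2", "antigen_presentation", "mutation_benefits_tumor"),
    ("B2M", "antigen_presentation", "mutation_benefits_tumor"),
    ("TAP1", "antigen_presentation", "mutation_benefits_tumor"),
    ("TAP2", "antigen_presentation", "mutation_benefits_tumor"),
    ("CD274", "checkpoint", "mutation_benefits_tumor"),
    ("BRCA1", "genomic_instability", "mutation_benefits_tumor"),
    ("BRCA2", "genomic_instability", "mutation_benefits_tumor"),
    ("TP53", "tumor_suppressor", "mutation_benefits_tumor"),
    ("RB1", "tumor_suppressor", "mutation_benefits_tumor"),
    ("CDKN2A", "tumor_suppressor", "mutation_benefits_tumor"),
    ("MYC", "proliferation", "mutation_benefits_tumor"),
    ("RAS", "proliferation", "mutation_harms_tumor"),
    ("EGFR", "proliferation", "mutation_harms_tumor"),
    ("HER2", "proliferation", "mutation_harms_tumor"),
    ("APC", "division_reduction", "mutation_benefits_tumor"),
]


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def random_coding(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    while len(codons) < n_codons:
        c = random_seq(rng, 3)
        if c not in STOPS:
            codons.append(c)
    return "".join(codons)


def main() -> None:
    rng = np.random.default_rng(SEED)
    genes = []
    for name, category, direction in PANEL:
        promoter = random_seq(rng, PROMOTER_LEN)
        coding = random_coding(rng, CODING_CODONS)
        protein = str(Seq(coding).translate())
        assert "*" not in protein and len(protein) == CODING_CODONS
        genes.append(
            {
                "name": name,
                "wildtype_promoter": promoter,
                "wildtype_coding": coding,
                "wildtype_protein": protein,
                "effect_category": category,
                "effect_direction": direction,
            }
        )
    out = Path(__file__).resolve().parents[1] / "src" / "rccsim" / "data" / "gene_panel.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps({"seed": SEED, "genes": genes}, indent=1) + "\n")
    print(f"wrote {out} ({len(genes)} genes)")


if __name__ == "__main__":
    main()
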