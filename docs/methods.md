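# Methods

## Model overview

`rccsim` simulates the tumor microenvironment of renal cell carcinoma as a
population of cell-agents (tumor, CD8+, CD4+, Treg, NK, dendritic cells,
adipocytes) on a continuous 2-D rectangle (default 100 × 100 arbitrary
length units) advanced in discrete steps. Agents interact when they perceive
one another: a directed edge exists from `a` to `b` whenever their Euclidean
distance is strictly below `a`'s search dimension `d_s` (default 3.0,
learnable). Reducing `d_s` emulates poor tissue perfusion; enlarging it
emulates lymphocyte infiltration after vascular normalization.

Each step executes a fixed phase order: perception, dendritic-cell cycle,
CTL/NK kills, checkpoint inhibition, auxiliary interactions (Treg
suppression, CD4→Treg differentiation, apoptosis), tumor division, therapy
effects, angiogenesis, cleanup. The fixed phase order makes runs
reproducible; stochastic decisions inside each phase are vectorized
Bernoulli draws from a single per-run generator, so a (config, seed) pair
determines the entire trajectory bit-for-bit.

Movement is a fixed-length step toward the current target (nearest
perceivable tumor for CTL/NK/unloaded DCs, nearest inactive CD8 for loaded
DCs) and a uniform random walk otherwise. Tumor cells and adipocytes do not
move; daughters are placed within one unit of the parent, so tumors grow as
spatial clusters. Contact (distance < 1.0) is distinct from perception.

## Tumor genetics

Tumor cells carry a synthetic genome of 19 gene segments; each segment is a
20-nt promoter plus a 60-nt coding sequence (20 codons, no premature stop in
the wildtype). Wildtype sequences are synthetic, generated once from a
frozen seed and shipped as `data/gene_panel.json`; no human reference
sequences are used. Only point substitutions are modeled, so all sequence
comparisons are position-wise.

A gene's mutation score is
`clamp(protein_hamming_fraction × (1 + k_expr · promoter_hamming_fraction), 0, 1)`;
a premature stop counts every downstream residue as mismatched. Scores feed
the behavioral channels:

* antigen-presentation genes (HLA-A/B/C, JAK1/2, B2M, TAP1/2): the mean
  score is the *evasion* term reducing CTL kill probability;
* CD274 (PD-L1): scales the checkpoint-inhibition probability that
  exhausts a contacting T cell;
* BRCA1/2: mean score raises the per-nucleotide inheritance mutation rate by
  `1 + instability_gain · score`;
* TP53/RB1/CDKN2A: mean score reduces intrinsic tumor apoptosis;
* MYC: enters the duplication formula through `w2`;
* RAS/EGFR/HER2: each damaged oncogene multiplies the growth potential by
  `1 − prolif_loss · score` (mutations here *hurt* the tumor);
* APC: score raises growth by `1 + apc_gain · score`;
* neoantigen load (mean nucleotide mutation fraction) raises dendritic-cell
  capture probability.

NK kills deliberately ignore the antigen-presentation term (innate,
MHC-independent recognition).

### Selection analysis

`genome.selection_simulation` studies the evolutionary layer in isolation: a
well-mixed population in which each cell per step survives an attack with
probability `1 − kill·(1−evasion)·(1−protection·score(CD274))` and, below a
capacity, divides with probability `division·∏(1−prolif_loss·score)` over
the harmful oncogenes, inheriting its genome with BRCA-elevated mutation
rates. The spatial engine is unsuitable for this measurement: kills are
contact-limited and division is crowding-gated at the cluster rim, which
makes per-locus selection coefficients too small to detect at practical run
sizes.

Because overall turnover necessarily differs between a selected arm and any
genotype-blind control (in either direction, depending on which channel
dominates), selection effects are read off the *within-run excess* of a gene
over the genome-wide mean fraction; under drift this excess is zero in
expectation for every gene, which the control arm verifies. In an asexual,
fully linked genome the mutator loci (BRCA1/2) elevate all genes of their
lineage equally, so their own locus-level excess is structurally near zero;
their signature is instead the strong per-cell association between BRCA-gene
load and rest-of-genome load (observed r ≈ 0.8 under selection vs ≈ 0.25
under drift). The tests assert exactly these three signatures: checkpoint
enrichment, oncogene purging, and the mutator association.

## Host effects

Hormones are represented in arbitrary units with three-level thresholds
(low < 0.3, high > 1.5 by default, learnable; boundary values classify as
normal). Off-normal levels multiply traits (CD8 activation, apoptosis, kill
efficiency, antigen-recognition threshold, immune recruitment, exhaustion
gain); normal levels are strictly neutral. Sex defaults place the dominant
hormone at 1.0 (normal) and the other at 0.2 (low): males therefore sit in
the low-estrogen band (reduced immune recruitment and activation) and
females in the low-testosterone band (reduced exhaustion gain). High-band
coefficients encode the anti-inflammatory role of high estrogen and the
immunosuppressive role of high testosterone.

Sex also sets the initial conditions: males start with a 1.5× larger CD8
compartment of which 70% is pre-activated but carries exhaustion 0.35 and a
higher initial tumor mutation load (1.5% of nucleotides vs 1%); females
start with a smaller, fresher, mostly naive pool (5% activated, exhaustion
0.05). This encodes the picture of male RCC as highly infiltrated but
androgen-exhausted, and the female compartment as initially less engaged but
more expandable. Under combination therapy started at step 100 these choices
produce the qualitative contrast the package tests: males begin marked tumor
decline earlier, while females recruit a larger CD8 peak and decline later.
Tumor-decline onset is measured as the first step at which the burden falls
to half of its value at treatment start — with full-intensity TKI the burden
maximum itself sits trivially at the start step for both sexes, so the
half-burden crossing is the informative onset marker.

BMI maps to adipocyte count linearly with a floor
(`round(2·(BMI − 18.5))⁺ + 5`); adipocytes are inert space-fillers in this
version.

## Therapy

Both drug classes activate at a scheduled step with intensities in [0, 1].
ICI: multiplies checkpoint engagement by `1 − intensity`, lowers every CD8's
exhaustion by `recover_rate · intensity` per step (gradual reawakening), and
spawns Poisson(`infil_rate · intensity · recruitment_factor`) immune agents
per step at the boundary (mix CD8:NK:DC = 3:1:1). TKI: multiplies
duplication by `1 − intensity · tki_prolif_block`, angiogenesis and CD4→Treg
differentiation by `1 − intensity`, and interpolates DC capture probability
toward 1 (full intensity guarantees capture on contact). Combination therapy
applies both lists from the shared start step. Intensities default to 1.

## Outcome and loss semantics

Death occurs when the tumor burden reaches `lethal_burden` (default 500
cells); eradication or reaching the 500-step horizon counts as survival,
with OS capped at the horizon. `D_max = 500` steps, so a survival-flag
mismatch saturates the squared loss at exactly 250000. The concordance index
uses the strict indicator (predicted ties score 0) and excludes alive
patients as the earlier pair element; when no pair is comparable the metric
raises an explicit error rather than returning 0. For multi-seed cohort
objectives, the MSE kind averages per-seed losses per patient and then over
patients; the CI kind first aggregates per patient (mean predicted OS,
majority-vote survival with ties counted as dead).

## Calibration

`tune_parameters` is a bounded black-box loop: trial 0 evaluates the
starting parameter set (clipped into the search space); subsequent trials
alternate uniform draws over the space with Gaussian perturbations of the
incumbent (sd = 20% of each range), always clipped to the declared bounds.
One objective seed is fixed up front, so every trial faces the same
simulation-noise realization and objective differences reflect the
parameters. The incumbent best is retained and returned with the full trial
history.

## Synthetic cohorts

`generate_synthetic_cohort` emulates the structure of a small real-world
RCC cohort: sex ~ Bernoulli(1/2), BMI ~ Normal(27, 4) clipped to [18, 45],
treatment uniform over {ICI, TKI, ICI+TKI}, start step uniform in the first
quarter of the horizon. Ground-truth outcomes are produced by running the
simulator under a known parameter set, so recovery experiments have a known
target. The generator does not emulate real-data features such as
measurement error in cell concentrations, correlated covariates, informative
censoring, or treatment switching — passing recovery tests therefore shows
the calibration loop works on data the model can represent, not that the
model is identified on clinical data.

## Defaults and problem sizes

Key defaults: `w1 = 1.0`, `w2 = 0.5`, `b1 = 0`, `base_kill = 0.45`,
`nk_kill = 0.25`, `base_inhibit = 0.5`, `delta_exh = 0.15`,
`p_phago = 0.35`, `recover_rate = 0.08`, `infil_rate = 0.6` agents/step,
`base_mutation_rate = 0.003`/nt/division, `instability_gain = 3`,
`e_tg_scale = 0.18`, `suppressor_apoptosis = 0.005`/step,
`cd8_apoptosis_rate = 0.002`/step, initial counts
{tumor 40, CD8 40 (×1.5 male), CD4 20, Treg 10, NK 15, DC 15}. The growth
scale and intrinsic apoptosis rate were chosen so that an untreated default
patient dies between roughly step 150 and the horizon — late enough that
treatment can start as late as step ~120 (the latest start in the reference
cohort) while the patient is alive, and so that post-treatment decline is
dominated by immune kills rather than burden-proportional intrinsic death.

Statistical tests run scaled: cohort-level experiments use a 60 × 60 arena
with a 120-step horizon and a 150-cell lethal burden (~0.1 s per run);
recovery experiments use 10 trials × 2 seeds × 7 patients × 5 replicates;
the selection analysis uses populations of 200–800 cells for 500 steps; the
sex-contrast and determinism checks run the full-size configuration
(100 × 100, 500 steps, 10–12 seeds per condition).

## Numerical choices and degenerate inputs

Probabilities are clamped to [0, 1] after every modulation. Exhaustion is
clamped to [0, 1]; increments saturate at 1, recovery at 0. A genome with
zero mutations scores exactly 0 on every gene, and `effective_mutation_rate`
returns the base rate exactly for wildtype BRCA. Empty tumor populations
raise an explicit error in `population_mutation_profile`; a finished run
with an eradicated tumor reports an all-zero profile. Agents removed by
death never appear in subsequent perception graphs. k-d trees
(`scipy.spatial.cKDTree`) provide neighbor queries; the strict `< d_s`
comparison is re-checked exactly at the boundary.

## Known limitations

* Space is 2-D with no oxygen/cytokine fields; vessels act only as local
  growth boosts and visual anchors for angiogenesis.
* No insertions/deletions, crossover, or real reference sequences; the
  genome layer is a substitution-only model on synthetic wildtypes.
* Hormone levels are static within a run (no cycles or age dependence), and
  no effect size is calibrated to measured endocrinology — all hormone
  coefficients are modeling defaults exposed as learnable parameters.
* The step↔days mapping is uncalibrated; OS values are comparable between
  simulations, not directly to clinical time.
* Therapy has no pharmacokinetics: intensities are constant from the start
  step onward.
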