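# Methods

`somamosaic` implements a complete analysis chain for low-level somatic
mosaicism in deep bulk exome data — the setting where a mutation present in a
few percent of cells must be separated from sequencing and alignment error at
~584× read depth. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic cohort does and does not
emulate.

## Error model and EBscore

Per-site error is modelled as a beta-binomial: at a given (chrom, pos, ref,
alt), the alt counts of a panel of unrelated normal samples are treated as
draws from BetaBinomial(depth, α, β). (α, β) are fitted by maximum
likelihood — the likelihood is written directly in `gammaln` form and
optimised by L-BFGS-B with analytic digamma gradients on (log α, log β),
initialised from method-of-moments (pooled mean, concentration from the
spread of per-sample fractions). A panel with zero alt reads everywhere is
uninformative about overdispersion; it returns a floor model with
α = pseudocount (default 0.1) and β = mean panel depth, so the error mean
stays strictly positive and a case observation can still be scored.

A case sample's support is scored as

    EBscore = −log10 P(X ≥ alt_count),  X ~ BetaBinomial(depth, α, β),

evaluated as a log-space sum of pmf terms (a reverse cumulative log-sum-exp
for whole score curves), so tails of order 10⁻¹⁰⁰ at depth 1000 are exact to
machine precision rather than cancelled away in `1 − CDF`. Strand-pooled
counts are used throughout: the count tables carry no per-strand columns, so
the strand-aware decomposition of the original empirical-Bayes formulation
collapses to one beta-binomial per site. This is a deliberate simplification.

The score cutoff is calibrated on labelled calls: an ROC over all distinct
score thresholds (score ≥ threshold classifies positive), cutoff = the
smallest threshold attaining the maximal Youden J = sensitivity +
specificity − 1, AUC by the trapezoid rule. When no calibration set is
supplied the filter uses the default cutoff 2.396; calls with score ≤ cutoff
are rejected (ties reject).

## Post-filter stack

Reason-coded and recomputed from scratch on every application (hence
idempotent and order-independent). Matched mode: depth < 35 (`min_depth`);
VAF ≥ 40 % (`germline_vaf`, suspected germline); EBscore ≤ cutoff
(`eb_score`); all supporting reads within the terminal 10 bp of their reads
(`read_position`; the flag is computed upstream — 10 bp is a common artifact
window); fewer than 3 quality-filtered alt reads OR ≤ 50 % of raw alt support
retained after MQ20/BQ30 filtering (`min_support`; this reading covers both
numbers in the ambiguous "more than 50 % (at least three reads)" rule); and a
low-mappability flag (`mappability`, standing in for a BLAT second-hit
check). Brain-only mode, for subjects with no matched normal, tightens depth
to < 100 and VAF to ≥ 20 %.

## Amplicon validation

A candidate re-sequenced on a deep amplicon platform validates when its alt
count is above the platform's background error for its pyrimidine-centred
substitution class by a one-sided exact binomial test,
p = P(X ≥ alt | n = depth, p = rate), at α = 0.05 (no multiple-testing
correction by default; none is part of the procedure being modelled). The six
class rates (T>A 3.12e-3, T>C 7.97e-3, T>G 7.58e-4, C>T 4.07e-3, C>G
7.65e-4, C>A 1.85e-3) were measured on spike-in replicates of a two-step PCR
platform and are shipped as the default table. Precision = validated/tested
(reported to one decimal of percent); concordance is the Pearson r of
(WES VAF, amplicon VAF) over validated records, defined at ≥ 3 pairs.

## Burden and the mutation clock

Per subject × tissue: SNV count, mean/median VAF, fraction below 5 % VAF, and
the six-way consequence composition (which must partition the call set). The
age clock is an OLS regression of per-subject count on age — chosen to match
the linear "SNVs per exome per year" phrasing of the quantity — with a
Poisson GLM (identity link) as an option for count-aware inference; both
report slope, intercept and slope SE, requiring ≥ 3 subjects and non-zero age
spread. Genome extrapolation scales the exome slope by genome_bp/exome_bp
(defaults 3e9/75e6 = 40), and tissues are compared as the blood/brain slope
ratio (a zero brain slope yields an infinity-marked ratio).

## Mutational signatures

Spectra live on the standard 96 channels (six pyrimidine-centred substitution
classes × 16 flanking contexts, class-major order, 5′ then 3′ base A<C<G<T);
purine-reference variants are reverse-complemented in. A signature catalog is
a set of probability vectors over these channels; genome-derived catalogs are
exome-adjusted by multiplying each channel by the exome/genome frequency
ratio of its trinucleotide context and renormalising.

Exposures of a signature subset are fitted by maximising the multinomial
log-likelihood of the channel *counts* under the mixture (simplex-constrained
SLSQP with analytic gradients; ε = 1e-12 guards on log arguments), which is
the statistically coherent version of "constrained linear" refitting; an
NNLS-on-fractions mode is kept as a cross-check. Model selection searches all
subsets of the candidate list up to `max_k` (default 5, guarded by a subset
budget) and picks minimal BIC = k·ln(n_mutations) − 2·loglik, breaking
near-ties (1e-9) by higher cosine similarity to the observed spectrum, then
by smaller subset. The BIC constant multinomial coefficient is omitted — it
cancels across subsets.

No reference catalog file is bundled. `synthetic_catalog()` builds a
deterministic synthetic catalog of three named processes mimicking the
qualitative shapes that dominate ageing tissue — a CpG-focused C>T
deamination signature (the SBS1 shape class), a flat featureless signature
(SBS5 class), a C>A-heavy oxidative-damage signature (SBS18 class) — plus
random decoys; a loader for standard 96×S TSV catalogs is provided for users
with a real catalog. Reproducing published decompositions (e.g. SBS5/1/18 ≈
23.6 %/15 %/22.2 % for pooled AD-brain mosaics) requires that real catalog
and the pooled call set, so it is a documentation example, not a test.

## Prioritisation and enrichment

Consequence terms collapse into six categories (Non-synonymous, Synonymous,
UTR, Intronic, Splicing, Intergenic) by a fixed term table; unknown terms
are logged as `unclassified` rather than failing. Putatively pathogenic =
Non-synonymous AND (population MAF absent or < 0.01 %) AND Phred-scaled
CADD > 20 (both bounds strict in the direction that excludes the boundary).

Enrichment of a query gene set in a pathway: draw `draw_size` genes
(default |query|) from the cohort gene pool without replacement, n_perm
times (default 10,000), and report
perm_p = (1 + #{draws with overlap ≥ observed}) / (n_perm + 1) — the +1
correction keeps p ≥ 1/(n_perm+1). For the unstratified test the exact
hypergeometric upper tail is computed alongside as the closed-form
reference; the two must agree to Monte-Carlo error, which the test suite
asserts. Gene-length adjustment stratifies the null draws by pool
length-quintile, preserving the query's quintile composition (a surrogate
for length-aware permutation schemes whose exact design is unpublished).
Benjamini–Hochberg across pathways is available as a flag; the 5 %
significance cut is a report column, never a hard filter.

## Carriers

Germline genotypes from filtered counts: VAF ≥ 40 % calls a non-reference
genotype (the conventional germline bound in this setting) and VAF ≥ 90 %
a homozygote — the second boundary is this package's choice, needed to count
two ε4 copies from unphased counts. APOE: ε4 = rs429358-C with rs7412-C,
ε3 = T/C, ε2 = T/T; copies of 429358-C and 7412-T resolve the diplotype
except for the double heterozygote (ε2/ε4 vs ε1/ε3), which is reported
ambiguous and excluded from copy counts with a warning. Pathogenic germline =
two ε4 copies OR any catalogued risk-modifier hit; pathogenic somatic = ≥ 1
putatively pathogenic brain somatic SNV in the designated
tau-phosphorylation pathway union. The four categories (germline-only,
somatic-only, both, none) partition the cohort; percentages to one decimal.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces the *statistical* structure the downstream stages
assume, per fixed seed and bit-reproducibly:

- **Subjects** — 52 AD / 11 non-AD by default, ages uniform on the requested
  range, AD onset 2–18 y before death, Braak high (3–6) in AD and 0–1
  otherwise, APOE genotypes from ε-haplotype frequencies (ε4 0.39 in AD,
  0.16 in non-AD; ε2 0.05), chosen to match the ~15 % ε4/ε4 and ~48 % ε4
  heterozygote composition of the emulated cohort.
- **Clock** — per-subject truth SNV counts are Poisson with mean
  intercept + slope × age (slope default 0.53/exome/year for brain;
  2.55 for blood), the linear-rate model the clock stage fits back.
- **VAFs** — Beta(1.2, 40) truncated to (0.005, 0.40): median ≈ 2 %, ~82 %
  of mass below 5 %, emulating the observed low-VAF dominance.
- **Contexts** — each variant's channel is drawn from a configurable
  signature mixture over the synthetic catalog (brain default 0.39 flat /
  0.25 deamination / 0.36 oxidative — the three processes' relative
  proportions in the emulated brain tissue; blood 0.78/0.22); the reporting
  strand is randomised so spectrum building must strand-fold. Coordinates
  live on one abstract contig; no real genome ships.
- **Counts** — depths Poisson around 584; case alt ~ Binomial(depth,
  VAF + class error), matched normal and the 21 panel samples ~
  Binomial(depth, class error), using the amplicon background table as the
  per-class noise floor; decoy sites carry pure error in every sample.
- **Pathogenicity** — each truth variant is flagged pathogenic with
  probability 0.014, set so that ~27 % of simulated AD subjects carry at
  least one pathway pathogenic somatic SNV, the carrier prevalence of the
  emulated cohort.

Not emulated: read-level artifacts (the read-position and mappability flags
are generated, not derived from reads), strand bias, indels/CNVs,
contamination, per-site depth overdispersion beyond Poisson (real capture
data are more variable), linkage between sites, and realistic gene-length /
gene-membership structure (genes are uniform labels). Consequently, passing
filter-stack tests shows the statistical machinery is correct under the
assumed error model, not that real-data artifact modes are handled; those
enter only through the upstream flags.

## Problem sizes and numerics

The test suite and the acceptance script run end-to-end on these scales,
chosen to make Monte-Carlo tolerances meaningful while keeping a laptop run
comfortable: 5,000-site filter experiments (≈ half truth, half decoy) at
584×; 100-seed signature-recovery sweeps at 10,000 mutations; 50-seed clock
recovery at 200 subjects; 10,000-permutation enrichment on toy pools;
EBscore fidelity checked against independent gammaln tail summation at
depths to 1,000 (agreement ~2e-10). Degenerate inputs fail loudly with typed
errors (empty cohorts, single-class calibration labels, < 2-sample panels,
zero spectra, degenerate regressions); boundary conventions are: score ties
reject, VAF 40 % is germline-suspect (and het-call inclusive for germline
genotyping), CADD 20 and MAF 0.01 % exclude the boundary.
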