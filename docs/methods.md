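# Methods

This note records the models, parameter choices, numerical conventions and
limitations behind `renomics`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Metabolomics model and normalization

Untargeted metabolomics reports relative ion counts with run-day-scale
instrument drift. The pipeline normalizes in three fixed steps:

1. **Run-day registration** — within each run-day block, every compound's
   observed values are divided by the block median, registering block
   medians to 1.00. A compound with no observed value in a block cannot be
   registered there; it is flagged and left undivided rather than silently
   zeroed.
2. **Median scaling** — each compound is divided by its median across all
   samples (per-compound median becomes 1).
3. **Minimum imputation** — each missing (below-detection) entry is
   replaced by that compound's lowest measured abundance; fully missing
   compounds are dropped with a log record.

Conventions: the median of an even-sized set is the mean of the two central
values; missing values are excluded from every median (treating them as
zero would bias block medians under censoring); imputation runs *after*
normalization because the imputed quantity ("lowest measured abundance")
lives on the normalized scale of the published tables. The pipeline is
scale-equivariant per compound and `median_scale` is idempotent (both
property-tested). A `--already-normalized` flag skips steps 1–2 for
matrices published post-normalization, since upstream provenance is often
unknowable.

A caveat worth knowing: block-median registration gives every
(compound, cohort) its own scale. Group contrasts are preserved *within* a
cohort (run-day blocks are balanced by design), but per-sample quantities
from different normalization runs must never be pooled raw — see the
replicate-averaging design below.

## Differential abundance

Per compound, a two-sided Mann–Whitney U test compares the two groups:
exact enumeration when both groups have ≤ 8 observations and no ties,
otherwise the normal approximation with mid-ranks, tie-corrected variance
and continuity correction. Identical pooled values give p = 1. BH
correction spans all compounds of one contrast (not pooled across
contrasts). Fold change defaults to the ratio of group means on normalized,
imputed data (ratio of medians available as an option; the two differ
under skew and the difference is documented by test). Hit gating uses
strict inequalities: q < 0.1 and FC > 2 or FC < 1/2.

Discreteness matters at these sample sizes: at n = 9 vs 10 the exact null
rejection probability at nominal α = 0.05 is ≈ 0.043 (the largest
attainable level below 0.05), so calibration checks compare the simulated
rejection rate against that enumerated level, not against 0.05 itself.

## Redox-couple inference

Reactions are supplied as a flat TSV (id, substrates, products, oxidized,
reduced) rather than a genome-scale reconstruction — the network is used
only as a lookup. The bundled `nad_reactions_synthetic.tsv` is a
hand-constructed stand-in containing the five canonical measurable couples
plus NAD-dependent reactions whose central members (pyruvate,
α-ketoglutarate, oxaloacetate, DHAP) are typically unmeasured and act as
negative controls. The cofactor exemption set is {NAD⁺, NADH, H⁺, H₂O,
phosphate, O₂, CO₂} (case-insensitive).

Direction (drop/rise/flat) is decided on group medians of the per-sample
oxidized/reduced ratio — robust at n ≈ 10 — with Mann–Whitney significance
reported separately, BH-corrected across the couple family. The default
contrast is tumor vs normal, configurable.

## mtDNA copy number and mtRNA

mt_cn = 2 × (mt mean coverage)/(autosomal mean coverage) assumes a diploid
autosomal background; tumor aneuploidy is not corrected (the tumor/normal
*relative* factor largely cancels it). Autosomal coverage is the mean over
fixed 10 kb windows (width configurable) intersected against optional BED
exclusion masks; reads are filtered at MAPQ ≥ 30 with duplicate,
secondary and supplementary reads excluded, which suppresses cross-mapping
with nuclear mitochondrial segments (NUMTs). GC correction is not applied
— a known limitation. Alignments are streamed (no index needed), so
plain-text SAM works as well as BAM/CRAM.

The coverage simulator draws per-window base counts
Poisson(depth × window) and mitochondrial counts
Poisson(depth × mt_length × cn/2 × f), f = 1 for normal and the depletion
factor for tumor; under this model the estimator is unbiased, which the
simulation tests verify (mean over 50 replicates within ±10% at 30×
depth).

mtRNA load is the per-sample TPM sum over the 13 mtDNA-encoded protein
genes (rRNAs excluded by default), reported both as a TPM sum and as a
fraction of total expression; input columns must sum to 10⁶ within 1%.

## Duplex mtDNA calling

Somatic calls require VAF ≤ 1% (strictly greater excluded as
inherited/clonal — the wording of the published cutoff is honored exactly,
so 1.000% is retained), depth ≥ 100 duplex reads, and at least one variant
read; each (position, ref, alt) type counts once per position. The
mutation-frequency denominator ("duplex bases surveyed") is not precisely
defined in the literature this implements; here it is the sum of depths
over distinct positions passing the depth cutoff, including variant-free
positions when present in the input.

Consequence annotation uses the vertebrate mitochondrial code (translation
table 2: AGA/AGG stops, TGA = Trp), with strand-aware codon extraction;
MT-ND6 is modeled as the sole reverse-strand protein gene. Coordinates are
1-based; calls spanning the circular origin are rejected (none arise at
SNV level).

## Nuclear variant filter cascades

Every rule is evaluated for every record — no short-circuiting — so
verdicts list all violated rules and per-rule failure counts are exact.
Numeric conventions chosen where the published wording is silent: "middle
3rd of a read" is fractional position ∈ [1/3, 2/3] and "first 2/3" is
[0, 2/3], boundaries inclusive; "at least a third" of base qualities ≥ 25
is inclusive (exactly one third passes); the 5× matched-normal rule
compares VAF fractions and a matched-normal VAF of exactly 0 satisfies the
disjunct; the indel "no repeats" predicate in the caller-support rule is
distinct from the "≤ 9 repeats" rule (zero vs nine), as printed. Panel
evidence is consumed as precomputed per-site (reads, burden) tuples plus a
panel size, since the original panels are not distributable. Region flags
may be given directly or derived from BED masks (0-based half-open,
converted to the records' 1-based loci).

The record generator builds each synthetic record *compositionally* from
its target violation set, because the quality, read-position and strand
evidence interact (the strand-bias rule is only armed below mean BQ 20);
ground-truth labels are assigned by construction, never by running the
filters, so the cascade-vs-labels concordance check is a genuine
round-trip.

## Mutation spectra

Channels follow the conventional pyrimidine-strand order (6 classes × 16
contexts). Purine-reference variants are folded by reverse complement;
boundary variants (no flanking base) and non-SNVs are skipped with
warnings, and totals are conserved (total + skipped = input). Strand
invariance means reading the complementary strand 5'→3': reverse-
complemented reference with positions mapped p → L+1−p. The C:G>A:T
enrichment test is an exact two-sided binomial test of the C>A fraction
against a baseline; the default uniform 1/6 null is a deliberate
simplification — supply a cohort-matched spectrum as the baseline for real
analyses. Signature refitting is out of scope; a non-negative
least-squares hook accepts a user-supplied signature matrix but is not
validated against any published catalog.

## The synthetic study cohort

The generator's defaults define the emulated study conditions. Abundances
follow a log-normal model:
abundance(s, c) = exp(μ_c + N(0, σ_c)) × effect(c, group(s)) × batch(day(s)),
with detection-limit censoring; multiplicative effects match the
median-ratio normalization and make fold changes the natural effect
currency. Run days are assigned round-robin so blocks are balanced; the
batch factor is shared across compounds within a day. All randomness flows
from one integer seed through a single generator stream per operation, so
regeneration is bit-identical.

Study conditions: 9 CCPAP, 10 ccRCC (2 atypically sorbitol-high, generated
as a subgroup and relabeled into ccRCC with their ids returned for optional
exclusion), 10 adjacent-normal; 548 compounds; σ = 0.5 on the natural-log
scale (per-compound variance is not recoverable from published tables;
0.5 ≈ 65% CV is typical of untargeted tissue panels); 3 run days with
batch σ = 0.2; detection limit 2.5 natural-log units below baseline, so
only the low tails of strongly depleted compounds (a few percent) censor
and exercise the imputation path. Key-metabolite effects are fixed at their
reported magnitudes (sorbitol 36× vs normal and 8.5× vs the full ccRCC arm
— 64× vs typical ccRCC alone; fructose 32×/5×; glutathione species 13×;
ophthalmate 6×/4×; aspartate 3.5× down; fumarate 4× down), the NAD(H)
couple members are set so exactly four of five couples shift toward the
reduced member in tumor, and the background contains 142 tumor-specific
and 48 ccRCC-driven differential compounds (designed truth: 200
differential vs ccRCC, 152 intersecting vs normal) among 344 nulls.

What the generator does *not* emulate: compound-compound correlation,
heteroscedastic platform noise, batch × compound interactions, adduct
redundancy and annotation ambiguity. Passing tests therefore demonstrate
that the pipeline recovers designed effects under its own model
assumptions, not that it is robust to every artifact of real LC/GC-MS
data.

## Replicate-averaged acceptance measurements

Cohort-level quantities are measured on replicate synthetic cohorts and
summarized as: plain means for hit counts (6 replicates of the full
two-contrast pipeline); geometric means for fold changes (50 replicates —
fold changes live on the log scale, and the geometric mean avoids the
Jensen inflation of averaging ratios); and, for redox direction, the
within-cohort difference of group median log-ratios averaged across 60
replicates (a paired design — per-sample ratios from different
normalization runs carry different registration scales and must not be
pooled raw). The vs-ccRCC sorbitol fold change carries a known upward skew
bias of order +15%: the two high-sorbitol samples make the denominator
group mean heavy-tailed, and the plug-in ratio of group means is noisy in
exactly the way a 10-sample arithmetic mean of a log-normal mixture is.
Tolerances in the acceptance tests are set at roughly three standard
errors of these summaries at the replicate counts used. Problem sizes
(replicate counts, 1000 null simulations for calibration, 100 seeds for
effect recovery, n = 9600 for the spectrum round trip) were chosen so each
summary's sampling error is well inside its tolerance while the whole
suite stays lightweight.

## Degenerate inputs and error policy

Empty groups, fully flagged subsets, zero denominators (autosomal or
normal-mt coverage, group summaries), empty spectra, unknown rule ids,
inconsistent read counts (variant reads > depth, non-parallel evidence
lists) and out-of-range probabilities all raise `ValueError`/`KeyError`
with the offending entity named. Malformed records inside a filter cascade
produce a per-record `malformed` verdict and the cascade continues.
Unmapped reaction rows and missing expression genes are skipped with
logged warnings rather than silently dropped.
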