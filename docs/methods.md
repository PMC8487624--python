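# Methods

This note documents the models, statistics and design choices behind
`aeroscore`, in the order a run executes them.

## Data model and canonicalization

ASV tables are samples × ASVs integer matrices; both on-disk orientations
are accepted and resolved by intersecting axis labels with the metadata's
sample ids (an overlap on both axes is an error rather than a guess).
Taxonomy lineages are canonicalized on read: rank prefixes (`k__`, `g__`,
…) and whitespace are stripped; the tokens `""`, `NA`, `unassigned`,
`unclassified`, `unidentified`, `unknown` and `uncultured` map
case-insensitively to the single sentinel `UNASSIGNED`; any named taxon
below an unassigned rank is truncated, so a lineage is always a prefix of
the rank ladder. A species column is carried if present but never consulted
by consensus logic, which operates at genus level throughout. Sample types
form a closed vocabulary: `sample`, `sampling_control` (carried through
field sampling and the laboratory), `laboratory_control` (extraction blank;
laboratory exposure only), `positive_control` (excluded from all
statistics). Missing DNA concentrations are recorded as absent, never as
zero.

## Diversity metrics

Hill numbers of orders 0, 1, 2 are reported per sample: richness,
exponential Shannon and inverse Simpson, all in effective-ASV units so the
ordering D0 ≥ D1 ≥ D2 always holds. Cross-sample summaries (mean, median,
sd) accompany the per-sample values because pipeline comparisons test the
per-sample distributions, not single summary numbers. Bray–Curtis
dissimilarity defaults to relative-abundance inputs: the pipelines under
comparison retain different read depths, and raw-count Bray–Curtis would
conflate depth with composition. A raw-count mode is retained for parity
with the default behaviour of classical ecology software. Samples with zero
reads are excluded from diversity and dissimilarity summaries and reported
in their own "samples with no reads completing the pipeline" count. No
rarefaction is performed anywhere.

## Mann–Whitney U

Pipeline metric distributions are compared with a two-sided Mann–Whitney U
test. When both group sizes are at most `exact_cutoff` (default 8) the
p-value is exact: the tie-aware permutation distribution of U over all
C(n₁+n₂, n₁) group assignments, with p = P(|U − n₁n₂/2| ≥ |U_obs −
n₁n₂/2|). Above the cutoff, a normal approximation with tie-corrected
variance and a 0.5 continuity correction is used (numerically identical to
the standard asymptotic implementation in scipy). Degenerate data — all
values identical — yields p = 1 with a note rather than an error.

A caveat documented deliberately: at the small sizes where the exact branch
applies, the permutation distribution of U is a coarse lattice (atoms of
0.1–0.4 probability at n₁ = n₂ = 2), so the asymptotic approximation can
differ from the exact p by far more than a percentage point, particularly
at large p. The two branches track each other closely in the
decision-relevant tail and converge as sizes grow; the package always uses
the exact branch where it is feasible, so the approximation's small-n error
never affects reported results.

## Cross-pipeline ASV matching and the scorecard

ASVs are matched across pipelines by exact, case-normalized sequence
equality — the only assumption-free criterion when the upstream tools'
trimming behaviour is unknown. A `prefix` mode additionally matches a
sequence to a longer one it prefixes with at least `min_overlap` (default
200 nt) of overlap, for pipeline pairs that trim to different lengths;
matching is one-to-one with ties broken by longest overlap then
lexicographic id. Duplicate sequences within one pipeline are collapsed to
one representative with a warning.

Overlap statistics report mutual support fractions (shared ÷ each
pipeline's total), read-total histograms of each side's exclusive ASVs, and
counts of exclusives above configurable whole-dataset read thresholds
(defaults 100 and 500) — low-abundance exclusives are the signature of
denoiser artefacts, while well-supported high-abundance ASVs appear in both
pipelines.

The scorecard aggregates six criteria with declared preference directions:
total reads (higher), samples completing (higher), per-sample richness
(higher), significantly differentially abundant ASVs by location (higher),
mutual support fraction (higher), and low-abundance exclusive burden
(lower). Criteria backed by a per-sample Mann–Whitney test vote with full
weight only when p < α (default 0.05) and abstain otherwise; descriptive
criteria (single numbers with no sampling distribution in hand) vote with
half weight. Weights are configurable and default to 1. The verdict is the
larger weighted vote sum, ties broken by total reads, and `indeterminate`
when nothing separates the pipelines. Swapping the two inputs provably
mirrors every vote.

Differential abundance is a plugin slot; the default is a per-ASV
Kruskal–Wallis test on relative abundances across locations (vectorized,
tie-corrected) with Benjamini–Hochberg correction at α, counting unique
significant ASVs. Negative-binomial model fits are intentionally out of
scope; the report records which method produced the count.

## Consensus taxonomy

Genus comparison is case-insensitive exact string equality after
canonicalization, with `Candidatus ` prefixes stripped; no synonym
resolution is attempted. Per ASV: both databases naming the same genus →
*high* confidence; both naming different genera → *medium*, the primary
database's lineage is kept and the alternative genus recorded for audit;
exactly one naming a genus → *low*, from that database; neither →
*unassigned*, retaining the deepest assigned prefix from the primary (else
secondary) database. ASVs above-genus-conflicting are listed in a log
field. "Assigned at genus level" always means genus ≠ UNASSIGNED;
higher-rank-only lineages count as unassigned in rate statistics, whose
denominator is the full ASV universe of the count table. Genus-name Venn
counts are name-set overlap, deliberately distinct from per-ASV agreement,
which `consistency_at_genus` reports overall and for the top-N ASVs by
whole-dataset reads (ties at the cutoff broken by id). Extension to more
than two databases is pairwise with a priority list; the first-listed
database plays the primary role.

## Decontamination

The two strategies are reference analogs of the removal and subtraction
families of decontamination tools, defined by this package:

* **Prevalence**: per ASV, a one-sided Fisher exact test (hypergeometric
  upper tail) on the presence/absence 2×2 table of negative controls vs
  true samples, alternative = over-represented in controls. ASVs present
  everywhere or absent from controls get p = 1 by construction.
* **Frequency**: per ASV present in at least `min_presence` (default 5)
  concentration-bearing true samples, a one-sided Spearman test for
  negative association between relative abundance and DNA concentration.
  ASVs below the presence minimum carry no score.
* **Combination**: Fisher's method (χ² with 4 df) where both scores exist,
  pass-through otherwise; flag when the combined p falls below the
  threshold (default 0.1). With no usable concentrations the frequency
  method is skipped with a warning and combination degrades to prevalence.
* **Subtraction**: the background profile is the mean relative abundance
  across in-scope negative controls (zero-read controls skipped with a
  warning); each true sample's expected contaminant count is profile ×
  library size, rounded half-up; corrected counts floor at zero. The
  profile is scaled in proportion space because the study design has no
  spike-in reference. Control samples are excluded from the corrected
  table and ASVs zeroed everywhere are dropped.

The comparator partitions ASVs into flagged-and-adjusted, flagged-only and
adjusted-only; `missed_high_abundance` lists removal-flagged ASVs above a
read-total threshold (default 400) that subtraction left untouched — the
candidates for outright deletion after subtraction. Restricting prevalence
to laboratory controls yields `laboratory_deletion_candidates`: ASVs the
sampled environment never saw, which should be deleted whole rather than
partially subtracted. Metric deltas (mean Hill numbers, mean Bray–Curtis)
before and after correction quantify the cost of the correction.

## Synthetic data generator

The generator emulates the shape of an urban-park bioaerosol survey: 66
samples across 11 locations, with controls amounting to one third of all
units (22 sampling, 11 laboratory). True ASV mean abundances are
log-normal (σ = 1.5); 20 ASVs carry a 5× abundance multiplier at a third
of locations to create a recoverable location signal. Library sizes are
log-normal around 10,000 reads (4,000 for controls).

Contamination has two sources with distinct log-normal profiles: a
laboratory source that reaches every unit, and a sampling-stage source
that reaches samples and sampling controls but never laboratory controls.
A configurable subset of laboratory contaminants is batch-specific and
confined to laboratory controls — these are the ground truth for the
deletion-candidate analysis. Each sample's contaminant fraction is Beta(2,
4)-distributed (mean ⅓, wide), and DNA concentration is proportional to
the uncontaminated fraction with log-normal noise, giving the frequency
method its inverse signal. Sampling controls carry a 5% "leak" of the true
community, as real sampling controls do.

Dual-membership ASVs — genuine community members that are also prominent
(15% share) in the sampling-stage contaminant profile — are the stress
case for strategy comparison. Their sample-side contaminant share exceeds
their true relative abundance, so the frequency method flags them, while
the control-side profile share is diluted by laboratory controls that lack
them, so proportional subtraction removes reads without zeroing them:
flagged by removal, partially reduced by subtraction, exactly the
situation where the two strategies genuinely disagree.

Pipeline observation applies per-pipeline binomial read thinning
(retention defaults 1.0 vs 0.75), per-ASV detection sensitivity (0.98
both), and appends pipeline-private spurious ASVs (600 vs 3,000) with
geometric-tail read totals capped below the 10th percentile of real ASV
totals and random 250–450 nt sequences. Shared real ASVs carry identical
sequences across the pair so exact matching recovers them. Taxonomy
simulation covers each ASV at genus level independently per database
(coverages c₁, c₂), with agreement probability a when co-covered, yielding
closed-form tier expectations high = c₁c₂a, medium = c₁c₂(1−a), low =
c₁(1−c₂) + c₂(1−c₁), unassigned = (1−c₁)(1−c₂) used by the recovery tests.

What the generator does *not* model: read-level errors, chimeras,
primer/trimming artefacts, cross-talk, compositional correlations between
taxa, or database-specific assignment biases. Passing tests therefore
demonstrate the statistical machinery behaves correctly under a faithful
abundance-structure model, not that any particular real dataset would
yield the same verdicts.

## Numerical choices and degenerate inputs

All randomness flows through `numpy.random.default_rng` with explicit
seeds; a fixed seed reproduces every table byte-for-byte. Subtraction
rounds half-up to keep integer counts. Fisher-combination clips log inputs
at 1e-300. All-zero count vectors raise an undefined-metric error rather
than returning 0. Empty reports refuse to serialize. Problem sizes in the
test suite and acceptance script (100-seed selection and recovery runs,
5,000-ASV tier recovery, 500-dataset Mann–Whitney sweeps) were chosen to
put simulation confidence intervals well inside the asserted bounds on a
single CPU.

## Known limitations

* The subtraction rule is the verbal proportion-space description of
  background deduction, not a re-implementation of any specific tool's
  internal algorithm (no reference-ASV scaling, no per-run constant
  estimation).
* Prevalence uses presence/absence only; an abundance-aware prevalence
  test would be more sensitive for ubiquitous contaminants.
* Exactly two pipelines and two databases per call; larger comparisons
  compose pairwise.
* Genus-name matching has no synonym or spelling harmonization.
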