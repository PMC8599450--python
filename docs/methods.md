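# Methods

This note records the statistical procedures `tcrdyn` implements, the
conventions adopted where more than one reasonable definition exists,
what the synthetic-data generator does and does not emulate, and the
package's known limitations.

## Repertoire representation

A repertoire is a clone table (clone key, CDR3 amino-acid sequence,
V/J calls, UMI count) for one sample. Clone identity is configurable:
by default (`key_mode="auto"`) the key is (V, J, nucleotide junction)
when a nucleotide junction column is present and (V, J, CDR3 aa)
otherwise; keying on the CDR3 amino-acid sequence alone is available
for cross-sample analyses that should ignore V/J assignment. Upstream
pipelines differ on what "the same TCR" means across samples, so the
mode in force is logged with every run rather than hard-coded. Rows
with zero UMI count or an empty CDR3 are unusable for frequency
arithmetic and are dropped with a logged count. Multi-region samples
of one patient/timepoint/compartment are pooled by summing per-clone
counts; pooled frequency is summed count over summed total, so total
UMI count is conserved exactly.

## Clonality

`clonality = 1 − H/ln N` with `H = −Σ p_i ln p_i` in natural-log
units. The complement-of-normalised-entropy form is the standard
clonality convention; a same-sign variant of the formula sometimes
seen in print would exceed 1 for any non-degenerate repertoire and is
not used. For N = 1 the denominator vanishes and the score is
returned as undefined (None), never as an exception. Values are
clipped to [0, 1] to absorb ~1e-16 rounding at the uniform boundary.
Clonality is reported per region sample and on pooled repertoires;
output tables label which.

## Cosine similarity

Abundance vectors are indexed by the lexicographically ordered union
of clone keys with zeros for absences. The cosine is invariant to
positive rescaling of either vector, so counts and frequencies give
identical values; raw counts are used. Longitudinal similarity
compares the pooled pre- and post-treatment repertoires of one
patient/compartment; spatial similarity compares regions within a
single timepoint only.

## Expansion, dynamics, fates

Expanded: frequency strictly greater than 2/1000 (the threshold is
configurable, and an inclusive-boundary mode exists because the strict
reading is a convention, not a law). The per-clone two-timepoint test
is the exact conditional binomial test for two count rates: given
exposures `t_pre`, `t_post` (total UMI per timepoint) and counts
`c_pre`, `c_post`, under the null `c_pre | c_pre + c_post ~
Binomial(c_pre + c_post, t_pre/(t_pre + t_post))`. The two-sided
p-value doubles the smaller tail and caps at 1 — the most common
exact-test convention; a minimum-likelihood two-sided rule would
differ in the third decimal for asymmetric nulls and is not offered.
Clones absent at one timepoint enter with count 0 so appearance and
disappearance can reach significance. No multiple-testing correction
is applied across clones; the fixed α = 0.01 plays that role.

Fates are defined on the expanded sets of pooled per-timepoint
repertoires: maintained (expanded both), replaced (expanded pre only,
including absent post), novel (expanded post only). Maintained and
replaced partition the pre-expanded set by construction. The mean
frequency ratio averages `f_pre/f_post` over pre-expanded clones with
non-zero post count; clones undetected post are excluded, and the
value is undefined when no clone qualifies.

## CDR3 triplet kernel and clustering

The kernel is the k = 3 spectrum kernel with multiplicity:
`k(x, y) = Σ_t c_x(t)·c_y(t)` over contiguous amino-acid triplets,
normalised by `√(k(x,x)·k(y,y))`. Counting with multiplicity is the
conventional definition of the spectrum-kernel family; it makes the
normalised value 1 exactly when the triplet count vectors are
proportional (e.g. "AAAA" vs "AAA"). Sequences shorter than 3 have no
triplets and are excluded before evaluation with a logged count.

Edges require kernel strictly greater than 0.82, a threshold
optimised elsewhere for antigen-sharing TCR pairs and treated here as
a fixed configuration constant. Clusters are connected components
with at least two members — singletons are not clusters, otherwise
"number of clusters" would scale with repertoire size. The
normalised cluster count `Nreal/Ncon` draws, for each of 10 controls,
as many nodes as there are expanded CDR3s uniformly without
replacement from the full node set (selection ignores cluster
membership); a variant restricting controls to unclustered nodes is
available via `control_pool="unclustered"` since the sampling
population admits both readings. Controls are seeded; the ratio is
undefined when the control mean is zero. Under a uniformly random
expanded set the ratio is ≈ 1 in expectation (slightly above, by
Jensen's inequality applied to the control mean in the denominator —
about +3% at the problem sizes used here).

## Tumour genomics

CCF model: `VAF = CN_mut·CCF·p / (CN_n(1−p) + CN_t·p)` with CN_n = 2
unless stated. The inverse problem is solved by exhaustive search
over CCF ∈ {0.01, …, 1.00} (step 0.01) and CN_mut ∈ {1, …, CN_t},
minimising `|expected − observed VAF|`. Ties (within 1e-12) are
broken toward smaller CN_mut then smaller CCF — the most parsimonious
state — and the number of tying grid points is reported so that
non-injective (CCF, CN_mut) combinations, e.g. (1.00, 1) vs (0.50, 2),
are flagged rather than silently resolved. A likelihood-based fit
would need read depths; the absolute-difference criterion matches the
grid's resolution and is depth-free.

Burdens: TMB = exonic nsSNVs / capture territory (Mb). The territory
is a required input with no default — it depends on the capture kit
and silently assuming one corrupts cross-cohort comparisons. Clonal
burdens count ubiquitous mutations (present in every sample of the
patient) for multi-region cases, CCF > 0.5 for single-region cases.
Neoantigen burden counts strong binders: mutant %rank < 0.5 and
wildtype %rank > 0.5.

wGII: per autosome, the fraction of covered bases whose total copy
number differs from round(ploidy); the index is the unweighted mean
over the 22 autosomal fractions (chromosomes without segments are
excluded with a warning). Rounding the ploidy defines "aberrant"
crisply for near-integer ploidies; the value is invariant to segment
splitting.

Neoantigen depletion: a mutation undergoes genomic contraction when
its CCF drops by ≥ 0.10 from the (median, if multi-sample)
pre-treatment baseline, or when it disappears. The drop is absolute
in CCF units by default; a relative mode (≥ 10% of baseline) is
provided because "decreased by 10%" is genuinely ambiguous.
Enrichment of contraction among neoantigen-encoding mutations is
Fisher's exact test, one-sided in the enrichment direction by default
(the scientific question is directional); `alternative="two-sided"`
is available. Empty table margins return the table with an undefined
p-value.

Signature scores: per-gene z-scoring across samples (population SD),
then the per-sample mean over the signature's genes present in the
matrix; absent genes are logged, a fully absent set is undefined.

## Group comparisons

Two-sided Wilcoxon rank-sum. For groups of ≤ 12 each, the p-value is
computed exactly by enumerating all `C(n, n₁)` assignments of pooled
midranks and counting assignments with `|S − E[S]| ≥ |s_obs − E[S]|`;
this handles ties correctly and reproduces the classical exact tables
(e.g. {1,2,3} vs {4,5,6} → p = 0.1). Larger groups use the
tie-corrected normal approximation; the method used is recorded in
the output. Patient-level values entering comparisons are computed on
pooled repertoires (one value per patient); where a metric is
per-region, medians across regions are taken first.

## Synthetic cohorts

The generator encodes the study conditions the analyses are validated
under:

| parameter | default | rationale |
|---|---|---|
| patients | 4 responders / 11 non-responders | 15-patient trial-like cohort |
| n_clones | 3000 | order of the median unique β-chain clonotypes per deep bulk TCR-seq sample |
| depth | 20,000 UMIs | deep bulk TCR-seq after UMI correction |
| n_regions | 2 | typical multi-region sampling |
| zipf_exponent | 1.3 | heavy-tailed clone-size law typical of memory-rich repertoires |
| n_expanded_truth | 30 | ≈ 1% of clones above 2/1000 |
| maintain_prob | 0.8 / 0.2 | responders maintain, non-responders replace — a qualitative contrast, not an effect-size claim |
| lognormal_sigma | 0.5 | moderate frequency drift of persisting clones |
| motif families | 5 × 6 | small antigen-focused CDR3 families among the expanded clones |
| cdr3_len_range | 8–18 aa | β-chain CDR3 length range |

Baseline frequencies: truth-expanded clones draw uniformly from
(0.004, 0.02) (the upper bound shrinks for large expanded sets so
their total mass stays below ~0.6); the remaining mass follows a
normalised Zipf law. Post-treatment, each expanded clone is
maintained with the group's probability; maintained clones drift by a
lognormal factor, replaced clones fall to background (2×10⁻⁴), and an
equal number of novel clones takes over their niche. Regions are
independent multinomial draws at the configured depth, matching
UMI-level sampling.

Two guard rails keep generated fate labels observable after
multinomial sampling: maintained clones' post-treatment generating
frequency is floored at 0.0035 (1.75× the expansion threshold) and
background clones are capped at 0.0015 (0.75×). Without the guard
band, clones generated near 2/1000 would cross the threshold by
sampling noise alone and the generating maintenance probability would
not be recoverable — a property of the generator, not of the fate
classifier. Consequently, passing calibration tests demonstrate
correct bookkeeping and estimator behaviour under the generative
model; they do not bound misclassification on real repertoires, where
clone frequencies populate the threshold neighbourhood densely.

The generator does not model V(D)J recombination statistics,
generation probabilities, sequencing error, alpha chains, or
inter-region heterogeneity beyond multinomial noise. CDR3 families
are built by mutating ≤ 2 positions of a seed (from length ≥ 12, where
the kernel constraint is satisfiable) and verifying every
within-family kernel > 0.82 at generation.

Genomic samples are the forward CCF/VAF model with binomial read
noise, CN_t ∈ {1..4}, and segment tables with a known aberrant
fraction per autosome.

## Numerical and degenerate-input conventions

Undefined quantities (clonality at N = 1, ratio with zero control
mean, ITH with zero clonal drivers, Fisher p with an empty margin,
frequency ratio with no qualifying clone) are returned as explicit
None/flagged results, never imputed. Union orderings, node orderings
and cluster orderings are lexicographic so repeated runs are
byte-identical; all Monte-Carlo draws flow from one seed through
`numpy.random.SeedSequence` spawning. Report tables are written with
`%.10g` floats.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate on: 1000 random
CDR3 pairs against a brute-force kernel oracle; uniform repertoires of
N = 2…1000; ~460 rate-test instances against direct CDF enumeration;
1000 noise-free CCF round trips plus 100 comparisons against an
independently coded exhaustive loop; 200 + 200 normalised-cluster-count
replicates on a 520-node network (30 planted families); 50 one-patient
cohorts (2000 clones, 100 expanded, maintain_prob 0.5) for
maintained-proportion recovery; 20 six-patient cohort batches for the
responder/non-responder cosine contrast; and full-pipeline reruns on a
five-patient cohort for byte-level determinism. These sizes give
stable Monte-Carlo estimates (the calibration bands are several
standard errors wide) while a full run stays in the tens of seconds.

## Limitations

- Read-level processing (alignment, UMI error correction, variant
  calling, copy-number segmentation, purity/ploidy solving, HLA
  typing, peptide-MHC affinity prediction) is out of scope; the
  package consumes their outputs.
- The 0.82 kernel threshold and the 2/1000 expansion threshold are
  adopted constants; their optimality is not re-derived here.
- The exact rate test conditions on total UMI counts as exposures;
  overdispersion beyond multinomial sampling (e.g. PCR jackpots
  surviving UMI correction) would inflate significance.
- Driver clonal/subclonal labels for the ITH index are caller-provided
  inputs, as they typically require manual review.
- Survival/clinical endpoint modelling and mixed-effect longitudinal
  models are not implemented; group contrasts use rank-sum tests.
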