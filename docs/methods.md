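# Methods

## Scope and data model

The package analyses cytosine modification (5mC and, indirectly, 5hmC) in
a compact gene-dense genome. Coordinates are 0-based half-open internally;
all text reports print 1-based positions. A cytosine *site* is
strand-specific: the reference base is C on the plus strand or G on the
minus strand. Its context is the 3-mer on its own strand — CG if the next
base is G, CHG if the base after next is G, CHH otherwise (H = A, T or C);
a window that runs off the chromosome or contains an N makes the context
*undefined*, and undefined sites are excluded from every denominator.

Region labels (Exon, Cds, Intron, SpliceSiteDonor/Acceptor, Gene,
Transcript, Upstream, Downstream, Intergenic, Intragenic) are non-exclusive
sets: a base may be Exon ∧ Cds ∧ Gene ∧ Transcript at once, and the
per-site summary tables count a site once per label it carries, so label
rows deliberately sum to more than genome-wide totals. Conventions where a
choice had to be made: splice donor = first `splice_site` (default 2, the
GT/AG motif width) bases of an intron in transcription order, acceptor =
the last; Upstream/Downstream are `flank` (default 3000) bases in the
gene's transcription direction; Gene = hull of its transcript spans;
Intragenic = inside the hull but in no transcript span; Intergenic = in no
transcript span and no flank. Interval-level summaries (e.g. of
immunoprecipitation reads) instead assign each interval exclusively, by
midpoint, with precedence SpliceSiteAcceptor > Donor > Exon > Intron >
Intragenic > Upstream > Downstream > Intergenic, so those percentages sum
to 100 as conventionally printed.

## Three-level methylation calling

Calling treats methylation like a diploid genotype: level m ∈ {0, ½, 1}.
Per observation (one read base over the site),

P(C | m) = m(1−e) + (1−m)(c(1−e) + (1−c)e),

with c the bisulfite non-conversion failure probability (default 0.005, a
configuration constant, not estimated from spike-ins) and e the phred
error of the read base, e = max(10^(−Q/10), 10⁻⁴). The floor keeps a
single maximum-quality base from dominating a pileup. The posterior over
the three levels under a uniform prior is computed in log space
(logsumexp); the call is the argmax, ties broken toward the *lower* level
(conservative); call quality is Q = −10·log₁₀(1 − posterior), capped at
255; a call passes when Q ≥ 20 and depth ≥ 1. The model intentionally does
not output continuous methylation fractions: the three-level contract
trades that resolution for sensitivity at sparse non-CG sites.

Pileup construction applies two read-level filters. (1) An observation is
discarded when the read mismatches the reference — in the reduced
bisulfite alphabet, so conversion itself is never a mismatch — within 2
bases of the cytosine. (2) Optionally (off by default; on for
conservative re-analyses) a whole read is dropped when it carries three
consecutive methylated CHH cytosines; "consecutive" counts only CHH sites,
and non-CHH cytosines neither extend nor break the run.

Symmetric methylation pairs a passing modified CG/CHG call with its
palindromic partner (+i ↔ −(i+1) for CG, +i ↔ −(i+2) for CHG). The
reported percentage divides by *all* modified passing sites of the
context, whether or not the partner is covered — the convention that
reproduces the printed symmetric fractions. CHH has no partner; its
symmetric percentage is 0 by construction.

Known behaviour worth stating: because a hemi site becomes confidently
callable at lower depth than a homozygous site, the passing-site
population at low coverage is slightly enriched for modified sites, and
non-conversion events put a floor (~0.2% at 20×) under the apparent
modification rate of unmodified regions. Both effects are visible in, and
bounded by, the end-to-end recovery tests.

## Bisulfite-aware mapping

Reads are aligned in a reduced alphabet: genome and read collapsed C→T for
plus-strand interrogation and G→A (on the reverse complement) for
minus-strand interrogation. Exact k-mer seeding on the first k bases
(k = 20) per route, ungapped extension counting reduced-alphabet
mismatches, budget 2; a read is reported only with a *unique* best
location (ties → unmapped). There is no multi-seeding and no indel
handling: the mapper is built for the simulator's reads and desk-scale
validation; real data aligned with an external bisulfite mapper enters via
SAM (`read_sam`), taking the bisulfite strand from an `XG`-style tag when
present and the reverse flag otherwise, and dropping
secondary/supplementary records. Consequence of seeding: a sequencing
error inside the first (or, for the reverse route, last) k bases can lose
an alignment an exhaustive scan would find; with error-free seeds the
mapper equals the exhaustive best-hit scan, which is how it is tested.

## 5hmC inference from PvuRts1I cut offsets

The enzyme cuts double-stranded DNA 3′ of a 5hmC: 11–13 nt away on the top
strand and 9–10 nt on the bottom strand. Inference inverts this: a
top-strand fragment end at p votes for every plus-strand cytosine at
p − d, d ∈ {11,12,13}; a bottom-strand end at p for every minus-strand
cytosine at p + d, d ∈ {9,10}. A cut supports *all* cytosines in its
window — no probabilistic weighting, the simplest rule consistent with a
fixed narrow offset range — and sites with support ≥ 2 (default; filters
background singletons) are called. Candidates at non-cytosine bases are
silently skipped; out-of-range cuts are skipped and counted. The same
sign convention is shared by the digestion simulator, and both offset sets
are configurable if the opposite orientation is preferred.

The naive peak caller (centred sliding-window mean over per-base fragment
coverage; maximal runs above `min_fold` × genome-wide mean; score = max
fold) is a deliberately simple stand-in for model-based peak callers,
intended for synthetic concordance experiments, where digestion-derived
and immunoprecipitation-derived peaks from one planted truth overlap
almost completely.

## Differential-modification statistics

Per-gene differential calls use the two-sided Fisher exact test on
(modified, unmodified) × (sample A, sample B) with Benjamini–Hochberg FDR
across genes; the two-sided p sums hypergeometric probabilities ≤ the
observed table's (one of several conventions; stated because they differ).
Gene-set enrichment offers two modes. *Fixed*: the standard two-sample
Wilcoxon rank-sum of member vs non-member scores, exact when both groups
have ≤ 10 untied values, otherwise normal approximation with tie
correction. *Greedy*: genes ranked by descending score; at every prefix
cutoff the standardized rank-sum of the membership indicator between
prefix and suffix (equivalently a finite-population enrichment z) is
evaluated; the best cutoff is reported, and the selection bias of that
search is corrected by permuting set labels (default 10,000 permutations,
seeded; p = (1 + #{perm ≥ obs}) / (n + 1)). Uncorrected, the greedy scan's
type-I error is badly inflated (~0.4 at α = 0.05 in the null calibration);
corrected, it is calibrated — both facts are asserted by the test suite.
Quantile normalization is the classic sorted-mean mapping; ties receive
the mean of the rank-averaged values, which means the "identical sorted
columns" property holds exactly only for tie-free data.

## The synthetic-data generator

The simulator defines the study conditions; its defaults are fixed, not
tuned per experiment.

| parameter | default | meaning |
|---|---|---|
| coverage | 20× | fold coverage of bisulfite reads |
| read_length | 76 bp | ungapped single-end reads |
| conv_fail `c` | 0.005 | non-conversion failure probability |
| seq_error `e` | 0.001 | per-base sequencing error |
| exon CG rate | 6.26% | planted 5mC probability per exon CG site |
| intron CHH rate | 3.99% | half 5mC, half 5hmC |
| intron CHG rate | 1.08% | half 5mC, half 5hmC |
| hemi_fraction | 0.2 | modified sites planted at level ½ |
| cg_comod | 0.21 | fraction of modified CG sites symmetric |
| pvu offsets | {11,12,13} / {9,10} | top/bottom cut distances |
| dip_fragment_range | 300–600 bp | immunoprecipitation fragment lengths |
| flank / splice_site | 3000 / 2 bp | region-index geometry |

The genome generator emits an AT-rich (GC 0.35) sequence carrying
non-overlapping multi-exon genes with canonical GT…AG splice motifs,
alternating between a CpG-poor class (o/e ≈ 0.6) and a CpG-rich class
(o/e ≈ 1.2) so the per-gene o/e distribution is bimodal. CG sites are
planted *pair-wise*: each strand's marginal modification probability
equals the (region, context) table rate while the probability that both
strands are modified is cg_comod × rate (with the Fréchet lower bound
2r − 1 taking over only at degenerate rates near 1); pairs straddling a
region boundary fall back to independent per-site draws. This keeps
recovered region percentages comparable to the nominal rates and the
symmetric fraction at its configured value simultaneously. The read
simulator implements exactly the caller's channel: molecule-level
modification Bernoulli(level), conversion of unmodified cytosines with
probability 1 − c, then a symmetric C↔T flip with probability e at
interrogated bases (uniform substitution elsewhere).

Randomness: every operation derives its own numpy Generator from
(config.seed, a fixed per-operation salt), so each output is deterministic
given (seed, config) and independent of the order operations are invoked —
slightly stronger than a single shared stream, and the reason the
round-trip tests can re-simulate pieces in isolation.

What the simulator does **not** emulate — and hence what passing tests do
not demonstrate about real data: PCR duplicates and amplification bias,
indels and structural variation, base-quality profiles (constant Q40),
SNPs confounding conversion calls, chromatin-dependent fragmentation, and
mapping ambiguity of genuinely repetitive DNA beyond what random sequence
produces. Pvu-seq background cut rate is a free parameter (default 0)
because no empirical value is established.

## Problem sizes and numerical choices

The end-to-end validation uses a 1 Mb genome with 100 genes at 20×
coverage — the study-scale coverage on a desk-scale genome — which the
package processes in about a minute; smaller fixtures (100–200 kb) back
the digestion round trip and peak concordance. Likelihoods are computed in
log space; posteriors at extreme confidence saturate float precision, so
oracle comparisons switch to the error-probability scale beyond Q = 60.
Percentages in report tables are rounded half-up (not banker's rounding)
to 2 decimals, computed in exact decimal arithmetic; a zero denominator
prints NA. Region masks use merged sorted interval arrays with binary
search, making the megabase summaries vectorised end to end.

## Limitations

The mapper is intentionally minimal (no indels, single seed) and is not a
replacement for production bisulfite aligners on real libraries. BS-seq
cannot distinguish 5mC from 5hmC, so "modified" in all bisulfite outputs
means either mark; only the digestion-based analysis is 5hmC-specific.
The three-level caller is blind to continuous intermediate methylation
(e.g. cell-population mosaicism finer than hemi/full). The greedy
enrichment procedure is one reasonable formalisation of a published-only-
as-software method and is labelled an interpretation.
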