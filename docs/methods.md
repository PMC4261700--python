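# Methods

`hadpipe` analyses host-associated differentiation between two transcript
sets assembled from the same species kept on different host plants: an
"original-host" set and a "derived-host" set. The pipeline has two arms —
sequence divergence (ortholog pairing, CDS/UTR partitioning, per-region
divergence, Ka/Ks) and expression divergence (two-library count tests with
cross-contrast intersection) — and a synthetic-data generator that produces
inputs with known ground truth for every stage.

## Ortholog pairing

Candidate pairs come from an exact-k-mer-seeded local similarity search
(word size 11; match +2, mismatch −3; a gap of length L costs 5 + 2L; both
strands). A subject is aligned only when it shares at least 5 words with
the query (scaled down for very short queries); candidates are scored by
affine-gap local alignment and reported with a Karlin–Altschul-style
length-normalized surrogate for the expected number of chance hits.
Filtering is by raw score: the default threshold of 40 sits above the
99.9th percentile of best scores observed between shuffled ~1 kb sequences
(a score of 40 corresponds to a 20 bp perfect match), which expresses the
intended stringency of a very low E-value cutoff without pretending the
tiny local database matches a public one.

Reciprocal best matches keep (a, b) iff b is a's unique top-scoring subject
and vice versa; any tie at the top removes the query from consideration, so
the matching is injective and deterministic — ambiguity always resolves to
"no call". The same rule applies when transcripts are mapped to the pooled
reference transcriptome. The double ortholog filter then requires both
members to map to the same pooled-reference sequence and to annotate to the
same protein (six-frame translation, local BLOSUM62 alignment, gap open 11
/ extend 1, score cutoff 50); every dropped pair carries a reason code.
Because local alignment scores are symmetric, the pipeline runs the search
once and transposes the hits for the reverse direction.

## CDS/UTR annotation

The best protein hit pins the reading frame. The CDS start is the nearest
in-frame ATG at or upstream of the hit start (the scan never crosses an
in-frame stop; if no ATG is found the CDS begins at the hit start and is
flagged `partial_start`). The CDS end is the first in-frame stop at or
downstream of the hit end (`partial_stop` and transcript end if none).
Transcripts are removed when an in-frame stop lies strictly inside the hit
region (`internal_stop`) or the resulting CDS is shorter than 150 bp
(`too_short`). The stop codon is assigned to neither CDS nor 3′UTR: it is
held out as a 3-base buffer so that per-region substitution counts never
mix regions under different selective pressure. A UTR pair enters the
divergence analysis only when both members have ≥ 10 bases of it (the
published analyses state no such threshold; 10 bp is this package's floor
for a meaningful denominator), which is why UTR pair counts fall below
ortholog counts. All internal coordinates are 0-based half-open on the
coding strand; GFF3 output converts to 1-based inclusive.

## Divergence and Ka/Ks

Region pairs are globally aligned (same scoring as above); divergence is
substitutions / bases compared, with gap and N columns excluded from the
denominator. Region summaries are unweighted means of per-pair fractions.

Two Ka/Ks estimators are reported side by side:

* **NG86** (the transparent oracle): per-codon site counts enumerate the 9
  single-base mutants; stop-creating mutants are excluded from a position's
  denominator and the position rescaled so every codon contributes exactly
  3 sites. Multi-difference codon pairs average over all minimal mutational
  pathways, dropping pathways through stop codons (all pathways are kept if
  every one is blocked). pS and pN are Jukes–Cantor corrected.
* **YN00-style** (the headline method): the transition/transversion ratio
  κ is estimated from fourfold-degenerate and nondegenerate site
  comparisons (K80 form, pooled and weighted by site counts, clamped to
  [0.01, 100], falling back to 1 when no estimate exists); site counts
  weight each mutation by κ and by position-specific target-base
  frequencies (F3×4); pathways are weighted by their substitution rates
  (κ per transition, the current ω per nonsynonymous step); pS and pN are
  corrected with the transition/transversion-aware K80 distance, and ω is
  iterated to convergence (tolerance 1e−6, max 100 iterations;
  non-convergence is flagged with the NG86 fallback noted).

Ka/Ks > 1 classifies a pair as under positive selection, < 1 purifying,
= 1 neutral. Ks = 0 with Ka > 0 is reported as *undefined* and tallied
separately rather than as infinity, so division-by-zero artefacts never
inflate the positive count. Summary bands (> 1, 0.5–1, < 0.5) mirror the
usual selection-scan presentation.

## Differential expression

Between-library normalization is the trimmed mean of M-values: reference
column by upper-quartile proximity, gene-wise M/A on genes nonzero in both
columns, trimming 30% from each M tail and 5% from each A tail,
precision-weighted mean M, factors rescaled to geometric mean 1.

The two-library test conditions on a gene's total t = k1 + k2: under the
random-sampling null k1 is binomial(t, n1/(n1+n2)) with n1, n2 the
effective (normalized) library sizes. The reported z is the
continuity-corrected normal deviate of that conditional binomial and p is
its two-sided tail; at equal library sizes this tracks the exact
conditional test to within ~0.002 everywhere. Because the exact conditional
test is discrete, the procedure is mildly conservative at these count
depths: at a mean total of ~200 its realized size at α = 0.05 is ≈ 0.039
rather than 0.050, and the continuity-corrected approximation inherits
this. We prefer fidelity to the exact null over nominal-size cosmetics. M
and A use a 0.5 offset for zero counts; the offset never enters the test.
Genes with both counts zero are not tested.

"Up-regulated" means higher in the **original-host** library (M > 0).
Calls default to Q < 0.05 (Storey q-values: π0 from a λ-grid
0.05…0.95 with cubic-spline smoothing evaluated at λ = 0.95; BH step-up as
fallback/alternative) and |log2 fold change| > 1; both gates are
configurable, including testing on p instead of Q. Per-sex consistent
up-sets intersect the contrasts of one sex; the final set intersects the
sexes. Sample agreement is summarized by Spearman correlation of
normalized counts; qPCR support uses the ΔCT method
(relative expression 2^−(Ct_target − Ct_ref), replicates paired,
mean ± sd).

## Synthetic data

Each gene is an ancestral transcript — 5′UTR, ATG-initiated CDS of whole
sense codons, a stop codon, 3′UTR — whose derived copy accumulates
substitutions per region. Region lengths are Poisson-distributed above a
floor (defaults 150/900/250 bp mean for 5′UTR/CDS/3′UTR). UTR sites mutate
independently at the configured rate; the CDS evolves codon-by-codon:
candidate site uniform, target base with transition weight κ,
nonsynonymous changes accepted with probability proportional to ω,
stop-creating changes rejected and resampled (an error is raised only if
resampling fails 1000 times). Substitution placement is without
replacement by default so truth counts equal observable differences; a
with-replacement mode exists for testing the distance corrections. Default
per-region rates (0.23% / 0.13% / 0.19%) mirror the magnitude and ordering
reported for whitefly host strains; ω defaults to a two-point mixture (5%
of genes at ω = 2, the rest at ω = 0.2) and can be fixed globally. Each
generated set carries 10% decoy transcripts with no partner to exercise
the filters. Count matrices share one lognormal(0, 1) abundance vector
across libraries; planted up genes have their abundance multiplied by the
fold change in the original library, down genes in the derived libraries;
counts are multinomial draws to the library size. All randomness flows
through a single seeded generator; identical configs reproduce output
byte-identically.

What the generator does **not** emulate: indels, assembly artefacts and
chimeras, paralog families, sequencing-error N runs, overdispersed
(biological-replicate) counts, and any per-gene divergence-rate
heterogeneity beyond the ω mixture. Passing recovery tests therefore show
the estimators are correct under their own model assumptions, not that
real libraries meet those assumptions.

## Numerical and design choices

* Alignment ties: the aligner's first-reported optimum is used —
  deterministic for fixed input, though not guaranteed to prefer
  substitutions over gaps among co-optimal alignments.
* κ estimation at low divergence is noisy (few fourfold-degenerate
  differences per pair); ω-recovery checks therefore run at 5% CDS
  divergence (≈ 75 substitutions per 500-codon pair), where the ratio is
  informative. At the ~0.1% divergence typical of host-strain contrasts,
  per-pair ω point estimates are dominated by counting noise, exactly as
  the small positive-selection tallies in such studies suggest.
* Saturated distances (pS or pN ≥ 3/4, or K80 log arguments ≤ 0) are
  flagged and fall back to the uncorrected proportion rather than NaN.
* Degenerate inputs: empty transcript sets, stop or ambiguous codons in
  site counting, all-trimmed TMM, zero-variance correlation columns and
  missing ΔCT references raise or flag as documented per function.

## Problem sizes used in validation

Recovery checks run at desk scale, chosen to make the assertions sharp at
3-SE/binomial tolerances: 500 ortholog pairs for per-region rate recovery,
200 replicate 500-codon pairs for ω recovery, 200 genes + 10% decoys for
pairing precision/recall, and 10^4-gene count matrices at library size
10^6 for test calibration and DE recovery. The acceptance script reruns
the same studies at 300 genes / 120 replicates to keep a full from-scratch
reproduction inside a few minutes on one CPU.
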