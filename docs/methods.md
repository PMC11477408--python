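# Methods

## Overview

`allergoscope` implements an integrative analysis of fish allergenicity
that starts from assembled muscle transcriptomes and ends at diagnostic
panel evaluation.  Five linked questions are addressed:

1. Which transcripts are putative allergens? (translated homology scan)
2. How much of each allergen does each fish express, and does the
   expression profile split fish into parvalbumin-high and
   parvalbumin-low groups? (expression profiling)
3. How representative is one parvalbumin of the family as a whole?
   (consensus conservation scoring)
4. Does expression-profile similarity between fish predict how their
   serum sIgE titres co-vary in an allergic cohort? (serology
   integration)
5. How well do single sIgE analytes and multi-analyte logistic panels
   predict oral-food-challenge (OFC) outcomes? (diagnostic models)

The real inputs of such a study — public RNA-seq assemblies and a
clinical cohort — are not shippable, so a first-class synthetic-data
module generates all inputs with the statistical structure the analysis
assumes, together with complete truth tables.  Everything downstream of
assembly is implemented; read processing, de novo assembly and multiple
alignment construction are inputs, not steps.

## Homology scan

Each transcript is translated in all six reading frames (standard
genetic code, stops retained as `*`) and aligned locally
(Smith–Waterman, affine gaps) against every reference allergen protein.
Scoring uses BLOSUM62 with gap open 11 / extend 1 (a gap of length L
costs 11 + L), the standard protein-search setting; all three are
configurable.  Per transcript/allergen pair only the best-scoring frame
is kept (chimeric multi-frame transcripts are out of scope).

A hit must satisfy both:

* **pairwise identity ≥ 50%** — identical columns over alignment
  columns, and
* **subject coverage > 90%** (strict) — the aligned reference span over
  the reference length.

Each surviving transcript gets one **primary allergen**: its lowest
E-value hit, ties broken by higher identity then lexicographic allergen
id.  All passing hits are retained in the output for cross-reactivity
inspection, but expression is pooled over primary assignments only, so
no TPM is double-counted.  Hits are annotated with an identity tier
(<70% low, 70–90% medium, ≥90% high) reflecting the convention that
only >70%-identity homologs are medium-to-high-probability allergens.

E-values use the Karlin–Altschul form E = K·m·n·e^(−λS) with fixed
gapped-BLOSUM62 constants λ = 0.267, K = 0.041, m = query length and
n = total database residues.  With m and n fixed per transcript this
ranks identically to raw score; the absolute calibration is therefore
not load-bearing and is not tuned.

A caveat worth knowing: local alignment trims low-scoring ends, which
slightly inflates measured identity relative to the full-length
(global) identity of a planted homolog.  The bias scales as 1/L; at
enzyme-like lengths (~300 aa) it stays under one identity point even at
55% true identity, while on a 110-aa parvalbumin-sized protein it can
reach a few points at identities far below those fish parvalbumins
actually show.

## Expression profiling

Transcript TPMs are pooled per allergen *name* (all parvalbumin
homologs together, matching how families are reported), and relative
abundances are computed against the allergen-only total of each sample;
a per-entry mode is available by treating each database id as its own
name.  Isoforms of one allergen in one sample are numbered in
descending TPM order (ties broken by transcript id); transcripts with
zero TPM in a sample are not isoforms of that sample.

The **true-allergen filter** retains an allergen iff (a) its best hit
identity anywhere exceeds 70% and (b) its relative abundance exceeds 1%
in at least 3 samples.  The identity criterion applies to the allergen
(maximum over samples and isoforms), not to every transcript.  Both
thresholds are strict inequalities and the filter is monotone in both.

**Fish grouping** computes Pearson correlation between per-fish mean
relative-abundance vectors (replicate-level mode retained), converts to
the distance 1 − r, agglomerates with average linkage and cuts at k = 2;
the cluster with the higher mean parvalbumin relative abundance is
labelled PV-high.  Average linkage was chosen as robust for the 8–24
sample sizes in scope; constant profiles are excluded with a warning.

## Conservation scoring

Given an aligned protein family (an input; the package does not build
multiple alignments), every column gets symbol frequencies with the
number of sequences as denominator, **gaps counting as a symbol**.  The
consensus keeps the most frequent non-gap residue per column
(alphabetical tie-break) and drops columns whose gap frequency reaches
0.5.

A sequence's conservation score is the mean, over its own non-gap
columns, of the frequency of **its own residue** at each column — not
the consensus residue's frequency.  This is the reading under which two
family members can score differently, which is the point of the
statistic (ranking candidate reference molecules by family
representativeness).  Scores live in (0, 1]; for an ungapped family of
N sequences they are bounded below by 1/N.  A `columns="consensus"`
mode restricts scoring to consensus-retained columns (the fixed-frame
variant) for sensitivity analysis; the default scores each sequence
over its full occupied length.

Pairwise similarity tables use end-to-end global alignment (same
scoring parameters, end gaps penalised) with identity over all
alignment columns.  Note that co-optimal global alignments can differ
by a few identity points; tests therefore pin the score exactly but the
identity only on unambiguous cases.

## Serology integration

Subjects are retained when sensitized: any analyte strictly above
0.35 kUA/L, the conventional assay positivity cutoff.  Analyte
correlation matrices are Pearson over subjects, on raw kUA/L by default
with a log10(x + 0.01) option (the transform changes r; both are
emitted by the pipeline via config).

Fish pairs shared between the expression-correlation and
sIgE-correlation matrices are labelled within/between by the fish
grouping; analytes without a transcriptome (e.g. an extra extract) are
dropped with a logged list.  The within-vs-between comparison is a
two-sided Wilcoxon rank-sum: exact null distribution when
min(n1, n2) ≤ 8 and the pooled values are tie-free, otherwise the
normal approximation with tie and continuity corrections.  Pair-level
correlations are not independent observations (each fish joins several
pairs), so this p-value is descriptive; the report carries that caveat.

The overall association between the two correlation structures is
Pearson r over the matched upper-triangle pairs with the two-sided
t-transform p (t = r·√((k−2)/(1−r²)), k pairs) and a least-squares
line.  Under a simulated null this p is calibrated (rejection rate
0.05 ± 0.02 at α = 0.05 over 2000 simulations, checked in tests).

## Diagnostic models

Single analytes are scored by ROC/AUC against OFC outcomes.  AUC is the
tie-corrected rank statistic, P(score_pos > score_neg) + ½P(tie); the
threshold-sweep curve's trapezoidal area equals it to 1e-12, and both
are computed.

Logistic regression is fitted by iteratively reweighted least squares
with an always-included intercept; step-halving guarantees the
log-likelihood never decreases; convergence requires a maximum
coefficient change below 1e-8.  Complete separation is detected as a
diverging coefficient norm (||β|| > 30) and reported as
`converged=False` with a warning rather than silently regularised.
Rank-deficient designs fail with the collinear columns named.  AIC is
2(k+1) − 2·loglik, counting the intercept.

Best-subset selection enumerates every predictor combination up to the
requested size (capped at 15 predictors = 32767 models; screen first
beyond that) and keeps the AIC-minimal subset per size, ties broken by
lexicographic predictor names.  Panel evaluation reports (i) the
single-analyte AUC table, (ii) best-subset trajectories with and
without the challenged fish's own extract, and (iii) the single
target-extract AUC as reference.  Predictors enter as log10(sIgE +
0.01) since titres span four orders of magnitude.  Panel AUCs are
in-sample (fitted probabilities), which is optimistic by construction;
a stratified k-fold cross-validated AUC is provided as the honest
companion.

## Synthetic data

The generators encode the study conditions:

* **Reference database** — 12 families named for the recurrently
  reported fish allergens (parvalbumin plus GAPDH, aldolase, enolase,
  creatine kinase, tropomyosin, LDH, TPI, PK, PG, GPI, α-actinin), two
  members each, founders independent uniform-residue proteins at
  near-real lengths (PV 110 aa; enzymes 250–450 aa), members mutated at
  5–15% of positions.  Independent founders keep cross-family identity
  far below the 50% scan threshold; uniform decoy composition
  guarantees the same for decoys.
* **Transcriptomes** — eight fish in two regimes across two replicate
  samples each: PV-high (cod, grouper, grass carp, tilapia, catfish;
  PV = 60% of allergen TPM, majors 6% each, minors ~1.7% each) and
  PV-low (tuna, salmon, halibut; PV = 6%, majors 14%, minors 4%), so
  the six top-expressed allergens always exceed 70% of allergen TPM and
  every minor allergen clears the 1% filter level.  Parvalbumin gets
  2–3 isoforms with a dominant top share of 0.7 (the [0.5, 0.9]
  regime); planted homolog identities cycle over 0.65–0.95 with
  parvalbumin at 0.90–0.96 (fish PVs are well conserved).  Planted
  proteins are reverse-translated with random synonymous codons,
  flanked by 30–90 nt random UTRs, and mixed with 20 random-CDS decoys
  per fish holding 70% of the TPM budget.  Samples are normalised to
  10⁶ TPM; replicates are jittered by log-normal noise (σ = 0.1,
  keeping replicate Pearson r ≈ 0.99).
* **Parvalbumin alignment** — family members and planted PV proteins
  share the founder's length, so stacking them is already a gap-free
  110-column alignment; three outgroup members mutated to 55–62%
  identity emulate amphibian/avian parvalbumins as low-conservation
  references.
* **Cohort** — 188 subjects, 9 fish-extract analytes plus two
  recombinant-parvalbumin analytes.  Latent log10 titres are
  multivariate normal with block correlation (0.8 within an analyte
  group, 0.2 across; group means −0.3/+0.3 log10 kUA/L, σ = 0.8);
  measured sIgE is 10^latent clipped to the assay range
  [0.01, 100] kUA/L.  OFC outcomes for grass carp (74 subjects) and
  salmon (72) are Bernoulli with logit α_fish + 1.5·z of the target
  analyte's standardised latent titre (α = +1.2 grass carp, −1.2
  salmon, yielding roughly three-quarters and one-quarter allergic).

Everything is driven by one integer seed through numpy Generators;
identical seeds reproduce byte-identical files.

What the generators deliberately do **not** emulate: assembly artefacts
(fragmented or chimeric transcripts, the collagen-repeat failure mode),
shared evolutionary descent between families, assay censoring at the
detection limit beyond hard clipping, repeated measures per subject,
and any dependence of OFC outcome on non-target analytes.  Passing
tests therefore demonstrate correctness of the analysis machinery under
the stated statistical structure, not robustness to real assembly or
assay pathology.

## Numerical and design choices

* Thresholds read literally: identity "threshold of 50%" as ≥ 50,
  coverage "exceeding 90%" as > 90, sensitization "> 0.35" and filter
  criteria "> 70%", "> 1%" as strict.
* Relative abundances are renormalised per sample and checked to sum to
  1 ± 1e-9; samples with zero allergen TPM get undefined (NaN) relative
  abundances, are flagged, and are excluded from clustering.
* Alignment ties, isoform TPM ties, AIC ties and primary-assignment
  ties all break deterministically (documented lexicographic rules), so
  reruns are byte-identical.
* Empty FASTA inputs warn rather than fail (decoy-free runs proceed).
* The pipeline stages communicate only via files in the run directory;
  every intermediate is inspectable and every threshold actually
  applied is logged at INFO.

## Problem sizes

Default desk-scale sizes: 24 reference allergens, ~270 transcripts over
16 samples, a 26-sequence/110-column parvalbumin alignment, 188-subject
cohorts, and exhaustive panels to size 5 over 11 analytes.  The
identifiability property of panel evaluation (the challenged fish's own
extract attaining the top single-analyte AUC) is tested on a
400-subject challenged arm: with within-group titre correlation 0.8, a
sister analyte can edge out the target by sampling noise in a
74-subject arm, so the property is checked where it has power.

## Known limitations

* One primary allergen per transcript; genuinely multi-family chimeras
  would be under-counted.
* The Karlin–Altschul constants are fixed, not fitted; E-values are
  rank-faithful but not calibrated tail probabilities.
* In-sample panel AUCs inflate with subset size by construction; use
  the cross-validated variant for honest comparison.
* The within/between Wilcoxon treats dependent fish pairs as
  observations, mirroring the analysis it reproduces.
* Conservation scores depend on family composition: adding or removing
  alignment members changes every score, so scores are comparable only
  within one alignment.
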