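# Methods

This note documents the models and procedures implemented in
`retrocall`, the assumptions behind them, the parameters that matter,
and the design choices made where the design was genuinely open.

## 1. The assay and its read structure

Each insertion locus is probed by two PCR reactions whose products are
sequenced together after sample barcoding:

* **E (empty site)** — locus-specific primers in the 5' and 3' flanks.
  Amplifies only alleles *without* the insertion (a full-length L1 of
  ~6 kb blocks amplification), except for short truncated elements
  (<200 bp), where the polymerase reads through.
* **G (junction)** — one family-wide primer near the TE 3' end plus the
  same 3'-flank primer.  Amplifies only insertion-bearing alleles.

Reads begin at the locus-specific primers because the universal tails
added in the first PCR serve as sequencing primers: read 1 starts at the
3'-flank primer and runs across the 3' flank toward (and past) the
insertion point; read 2 starts at the 5'-flank primer (E) or the TE
primer (G).  Default read lengths are 250 bp (read 1) and 69 bp
(read 2), the configuration of a 300-cycle paired-end kit.

## 2. Read sorting and specificity tags

A pair is assigned to a G amplicon when read 1 carries an **exact**
prefix match to some locus's 3'-flank primer and read 2 matches the
family TE primer with at most `te_primer_max_mm` (1) mismatches; to an E
amplicon when read 1 exactly matches a 3'-flank primer and read 2
exactly matches the *same* locus's 5'-flank primer.  Everything else is
unassigned — a value, never an error — and read-pair conservation
(`total = assigned + unassigned`) is asserted on every run.  Primer
matching is prefix-only at position 0; identical primers shared by two
loci make both unresolvable (such pairs are unassigned and counted).

Amplification can be unspecific, so assignment alone is not trusted:
from every assigned pair a `tag_length` (50 bp) *specificity tag* is cut
immediately after the matched primer — from read 2 for E reactions and
from read 1 for G reactions.  (The G-side source is a geometric
necessity: G read 2 is TE-internal sequence shared by every locus,
whereas G read 1 carries the locus's own 3' flank.)  Tags are aligned to
the reference with a k-mer-seed (k=16) + Hamming-verification index over
both strands; with three disjoint seeds per 50-mer, every alignment with
<=2 mismatches is found (pigeonhole), which covers the supported
relaxation range.  A tag is **specific** when it aligns uniquely (one
location within a 10-hit reporting cap) and its start sits within
`tag_slack_bp` (default 0) of the expected target start on the expected
strand.  Defaults replicate exact matching (`tag_max_mm = 0`,
`tag_slack_bp = 0`); the relaxed mode exists because exact matching is
blind to small variants in the tag region — a known 1-bp deletion
polymorphism in a tag makes a sample's E reads vanish from the specific
count and miscalls the genotype, and slack/mismatch relaxation recovers
it.

E-reaction reads are also scanned (read 1, all offsets) for the reverse
complement of the family diagnostic motif within `motif_max_mm` (6)
mismatches; the per-amplicon `motif_fraction` is the motif-positive
share of *specific* reads.

## 3. The read-count mixture model

Per amplicon, specific counts across samples separate into a high level
(amplicon present; PCR is exponential, so log counts are approximately
Gaussian) and a low level (absent; a handful of cross-contaminating
pairs).  Counts of 0 are set to 1 before the log10 transform.  The model
is a univariate Gaussian mixture with G ∈ {1, 2} components and unequal
variances, estimated by MAP-EM:

* **Mean prior** — each component mean is shrunk toward the grand mean
  with weight `prior_shrinkage` (κ = 0.1):
  μ_k = (n_k x̄_k + κ x̄)/(n_k + κ).
* **Variance prior** — inverse-gamma with scale `prior_scale` (ζ = 1)
  and ν = 3 degrees of freedom; the posterior-mode update is
  σ²_k = (ζ + Σ_s z_sk (x_s − x̄_k)²)/(ν + n_k + 3).  The prior is
  deliberately decoupled from the component mean (no
  (x̄_k − x̄)² coupling term): a legitimate singleton cluster far from
  the grand mean then keeps the prior-mode spread √(ζ/7) ≈ 0.38 rather
  than an inflated one.  With the coupled update, any locus whose
  cohort contains a 1–2 sample cluster — common whenever an allele
  frequency is high or low — would straddle the sd ≤ 0.5 QC limit, and
  the QC rule would fire on perfectly clean data.  The decoupled prior
  keeps the sd check what it is meant to be: a detector of genuinely
  failed cluster separation.
* **Weights** — maximum likelihood (n_k/n); no prior.
* **Initialization** — deterministic and restart-robust: EM is run from
  the 25th/75th-percentile init *and* from every split of the sorted
  data (per-side moments; capped at 64 quantile-spaced splits above
  n = 100), and the best converged likelihood wins.  For univariate data
  this candidate set covers every partition a randomly restarted EM
  could refine; the suite verifies equivalence with a 100-restart oracle
  on 50 random instances.
* **Model selection** — BIC on the observed-data log-likelihood at the
  MAP parameters (2 parameters for G=1, 5 for G=2), ties broken toward
  one component.  Single-Gaussian fits are how all-present and
  all-absent amplicons are detected.
* **Convergence** — absolute log-likelihood tolerance 1e-8, iteration
  cap 500, both recorded in the fit.  Zero-variance input falls back to
  a single component with status `forced_single` (never an exception).

Two **post-hoc rules** override pathological fits (disabled together by
`prior_only = True`, the mode that relies on the variance prior alone —
both modes are implemented because with ζ = 1 the prior already merges
close tight clusters at cohort-scale n, and the rules only add value on
larger cohorts or weaker priors):

* **Rule A** — all samples below `min_reads_all_absent` (10) specific
  reads → all calls absent (`forced_all_absent`).
* **Rule B** — two components closer than `cluster_merge_distance`
  (0.5 log10 units) → refit with one component (`forced_single`).

**Calling.**  In a 2-component fit the higher-mean component means
amplicon present; per-sample quality is log10(p_assigned/p_other),
capped at `quality_cap` (15) when the alternative posterior underflows.
A single-component amplicon is all-present when its mean is at least
`qc_high_mean_min` (3), else all-absent (the all-absent case is normally
captured by rule A first); its quality is the cap, as is the quality of
forced-all-absent calls — the model offers no within-cluster alternative
to score against, and the sentinel is documented in the output.  Calls
with quality below `quality_flag_threshold` (7) are flagged, never
removed.

**Quality control** drops amplicons (from combined calling, not from the
per-reaction call tables) when: the low-cluster mean exceeds
`qc_low_mean_max` (3); the high-cluster mean falls below
`qc_high_mean_min` (3); any component sd exceeds `qc_sd_max` (0.5); or
more than `qc_sample_frac_max` (80 %) of samples each have under
`qc_unique_frac_min` (80 %) of their tags uniquely aligned (unspecific
tag sequence).  Forced-all-absent fits skip the cluster checks — an
amplicon validly absent everywhere passes.

**Short-insertion override.**  After QC, passed E amplicons are checked
sample by sample: a motif fraction strictly above
`motif_fraction_threshold` (0.80) flips the call to absent (the E
product exists but spans the element, so in the diallelic sense the
empty-site amplicon is absent and the insertion present).  The override
applies only to E reactions and is recorded per call.

**Combination.**  Loci where both reactions passed QC yield diallelic
genotypes by the fixed truth table — (E present, G absent) → 0/0,
(present, present) → 0/1, (absent, present) → 1/1, (absent, absent) →
no call — with combined quality min(E, G).  Output is VCF 4.2 with a
symbolic `<INS:ME>` allele per locus plus TSV mirrors of calls, cluster
parameters and QC verdicts.  The manifest does not record the exact
insertion point, so POS anchors at the E-tag target end (the last
confidently empty-site base) — an anchor, not a breakpoint estimate.

## 4. Phasing

For a heterozygote, E and G reads originate from different alleles, so a
*monoploid* base call per reaction is meaningful.  Known biallelic SNVs
are collected from the supplied population VCF inside each locus's
3'-flank interval (derived from the manifest as the span between the two
tag targets).  Reads are anchored gaplessly — the amplicon start is a
design constant, so the read-1 offset of a reference position is
arithmetic — and the base over each SNP is piled up per reaction.  A
monoploid call requires depth >= `min_phase_depth` (10) and a majority
fraction >= `min_phase_fraction` (0.9); both thresholds are this
package's choice (the underlying idea presumes an external haploid
caller, which would bring its own).  A SNP is *informative* when the E
and G bases are distinct and equal, as a set, to the two recorded
alleles of the sample; the G base matching the first or second recorded
allele votes haplotype 1 or 2.  The majority over informative SNPs
assigns the insertion allele; `phase_quality` is the supporting fraction
over informative SNPs (on clean data every informative SNP votes
identically and the quality is 1.0); exact ties and zero informative
SNPs leave the sample unphased — conservative, never random.

Known limitation: samples carrying indels in the flank shift all
downstream pileup offsets; affected SNPs typically become uninformative
and are outvoted or leave the sample unphased, but they are not
realigned.

## 5. The synthetic-data generator

The generator builds a complete experiment — random reference, panel,
Hardy–Weinberg cohort, phased flank-SNP VCF, per-sample paired FASTQ and
truth tables — with the statistical structure the genotyper assumes.
It emulates: two reactions per locus with the read structure above;
well-separated log10 count clusters (present counts
round(10^N(μ, 0.15)) with μ ~ U(3.5, 4.5) per amplicon, i.e. ~10^4
pairs); cross-contamination for absent amplicons (Poisson(λ = 2) pairs
whose templates come from other samples that carry the amplicon — they
align specifically, so absence is a count-level, not sequence-level,
signal; the contamination level of real runs is not well characterized,
λ = 2 is this package's choice placing the low cluster at 0–1 log10);
uniform substitution errors (0.002/base); heterozygous flanking SNPs
(1–11 per locus, alt frequencies U(0.2, 0.8), phased per haplotype); and
four injectable failure modes — short 3'-anchored truncated insertions,
a primer-overlapping variant abolishing empty-allele amplification in
one cell (the affected genotype is forced heterozygous so the dropout is
consequential), a 1-bp deletion at the first base of the E tag window,
and E-tag duplication elsewhere in the reference.

Fixed geometry (constants in `retrocall.simulate`): 19-bp 5'-flank
primers (so primer + 50-bp tag exactly fills the 69-bp read 2), 22-bp
3'-flank primers, insertion junction 10 bp downstream of the E-tag end
(read-through E tags of short insertions therefore remain
target-specific), a 175-bp 3' flank (read 1 covers every SNP and, for
short insertions, the reverse-complement motif at 240 of 250 cycles),
and a TE consensus ending in motif + 20-bp poly-A with the TE primer
120 bp from the 3' end (a 150-bp truncated element still amplifies in
G; truncations under 120 bp lose the G product, as they would in
reality).  Flank SNPs are placed outside the G-tag window — a variant
inside the tag breaks exact matching, which is exactly the pathology the
dedicated tag-indel mode injects deliberately.  Read names encode
(sample, locus, reaction, source haplotype) as a debugging channel the
pipeline never reads; qualities are constant Q30 because no stage is
quality-aware.  All randomness derives from one seed through named
substreams; reruns are byte-identical.

What the simulator does **not** emulate — hence what passing tests do
not show about real data: PCR chimeras and primer dimers, barcode
hopping, per-cycle error profiles and quality decay, locus-specific
amplification bias beyond the per-amplicon mean draw, indel sequencing
errors, and reference mismapping beyond the planted duplications.

## 6. Problem sizes and runtime

The validation twins run at the published experiment sizes — 25 x 12 and
23 x 12 clean cohorts and an 18 x 24 cohort with one injected primer
failure — at full count scale (~5–8 M read pairs, a few GB of transient
FASTQ each, a minute or two per cohort).  Scale-free properties
(conservation, determinism, round-trips, rule fixtures) are tested on
small cohorts with a reduced count scale, and count-level properties
(cluster separation > 2 log10 units) are asserted on drawn counts
directly, without generating reads.  The per-amplicon mixture fit is
cross-checked in the suite against the R package the clustering is
modelled on (same prior settings) for model choice and means.

## 7. Generalization

`te_primers` and `te_motifs` are per-family maps: any variant class
assayable by a presence/absence PCR pair — other TE families, small
indels, viral integrations — can be genotyped by supplying its junction
primer and, where short-variant read-through is possible, a diagnostic
motif.  Copy-number genotypes, somatic low-fraction detection and joint
calling across runs are out of scope.
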