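# Methods

`mousecred` implements the computational stack for genomically credentialing
genetically engineered mouse tumor models (GEMMs) profiled with a targeted
amplicon panel: copy-number and arm-level aneuploidy calling under reduced
genomic coverage, strain-admixture estimation from a small SNP set,
cross-species hotspot-residue mapping, and the credentialing statistics built
on top of those calls. Everything is exercised end-to-end on synthetic data
with known ground truth; no external downloads are required.

## Copy-number model

A tumor of purity *p* and ploidy *ψ* mixed with diploid normal tissue has, at
a locus of tumor copy number *CN*, the expected copy-number ratio

    CNR = (p·CN + 2(1−p)) / (p·ψ + 2(1−p))

The simulator plants piecewise-constant integer CN over the genome and draws
per-amplicon counts as negative-binomial variables (Var = m + d·m², d = 0
gives Poisson, `noise=False` the exact expectations) with mean proportional
to CNR × amplicon efficiency × GC bias. Efficiencies are log-normal
(σ = 0.25) and fixed per panel under their own seed so tumor and matched
normal share them; the default GC curve is a gentle quadratic peaking near
45 % GC, which gives the loess corrector a real trend to remove.

Normalization stages, in order: (1) drop amplicons whose pooled-normal mean
total-normalized count falls in the bottom 5th percentile (the pool is the
equal-weight mean of total-normalized normals; per-normal weights are a
parameter); (2) divide each sample by its total count; (3) ratio against the
pooled normal; (4) log2; (5) subtract a per-sample loess fit of log2CNR on GC
(span 0.5, two robustifying iterations — the span is wide enough not to
absorb real CNAs); (6) median-center so a diploid background sits at 0. Zero
counts get a 0.5 pseudocount before the ratio so values stay finite.

Gene calls summarize amplicon log2CNR per gene (mean by default; median is
the convention for bin-level whole-exome reproductions and is available via
`summary="median"`). Significance is z against the pool of normals, two-tailed
normal p, and Benjamini–Hochberg q across genes within a sample. The noise
rule zeroes calls with q > 0.05 AND −0.2 < log2CNR < 0.2, read literally as a
conjunction; `zero_rule="or"` instead requires a call to be both significant
and large. Flox sites are split from their parent genes before any calling,
so an engineered deletion never contaminates the parent gene's copy number.

A caveat worth knowing: with a small normal pool the z scores are
overdispersed (each normal is part of the pool it is compared against, so the
normals' spread underestimates a held-out sample's). The effect shrinks as
1 ± 1/n; with eight or more normals the gene-call type-I error is comfortably
within 1.5× the nominal q, which is what the calibration tests assert.

Segmentation is circular-binary-segmentation-style: light outlier shrinkage
toward the local median, then recursive binary mean-shift splitting where the
best split (max two-sample t, exhaustive search) must survive a
within-segment permutation test (p < 0.01, 200 permutations, minimum 3
markers per side). Segments are annotated with the same z/q machinery and
zeroing rule as genes.

QC: MAPD is the median absolute difference of genomically adjacent log2CNR
after amplicon filtering; profiles with MAPD > 0.50 fail. Tumor content is
estimated from a flox site with expected biallelic loss as 1 − CNR (clipped
to [0, 1]); samples below 30 % are excluded from copy-number analyses.
`scale_cnr` inverts the purity/ploidy mixture to estimated tumor copy number,
clipping negative estimates at 0, with optional integer rounding.

Variant filtering applies the empirical flow-space rules: alt-allele strand
ratio within [0.2, 5.0] (reverse = 0 reads as +∞), flow-corrected depth
> 100, alt reads > 10, homopolymer run < 4, allele fraction > 0.1; every
failed rule is reported.

## Arm-level aneuploidy under reduced coverage

For an arm of length L and breadth-of-coverage c, the detection window is the
round(c·L)-long interval centered at the arm midpoint (floor of midpoint −
length/2, clipped to the arm). Mouse chromosomes are telocentric, so each
autosome is a single whole-chromosome arm; human layouts carry p/q arms from
a cytoband table. R_c is the fraction of the window covered by the union of
same-direction altered segments. Gains and losses are evaluated separately; a
direction is called when R_c ≥ threshold (default c = 0.6, R_0.6 ≥ 0.8) and —
with the directionality filter on — when the required fraction of the arm's
genes are altered that way (1.0 in panel mode, 0.3–0.5 for sparse-marker
whole-exome emulation; genes with state 0 count against the fraction, and
"genes on the segment" means genes overlapping the qualifying segments, with
a flag to use all genes on the arm). When both directions qualify the larger
R_c wins; an exact tie yields no call with a warning. Reference calls use
R_1.0 ≥ 0.8 with no gene filter.

On the threshold–performance relationship: with sensitivity (PPA over
reference-altered arms) the R_c threshold can only keep or lose true events,
so PPA is non-increasing in the threshold by construction. The quantity that
improves with stricter thresholds is agreement over positive calls
(precision/PPV), because loose thresholds admit partial-arm events absent
from the reference. `run_coverage_simulation` reports both, and the
calibration tests assert Spearman(threshold, PPV) > 0 together with
non-increasing PPA on a partial-arm-event cohort.

## Strain admixture

SNPs identical across the strains of interest carry zero entropy and are
dropped. Optional further reduction uses multiple correspondence analysis of
the strain × allele-indicator table (complete disjunctive coding, SVD of the
standardized residual matrix); a SNP's score is the sum over its indicator
columns of the column contribution to each retained dimension, weighted by
that dimension's share of retained inertia. On five synthetic strains, four
dimensions assign every strain a distinct factor-score coordinate; the
dimension count on real panels is an empirical property of the panel.

Admixture is supervised: reference allele frequencies are fixed (0/1 for
inbred strains, clamped to [1e−6, 1−1e−6] so vertex likelihoods stay finite)
and a sample's diploid genotypes are modelled per SNP as two independent
Bernoulli draws with frequency f_j = Σ_s Q_s f_js. The simplex-constrained
maximum-likelihood Q comes from EM started at the barycenter (deterministic;
convergence at relative log-likelihood change < 1e−8 or 2,000 iterations; the
log-likelihood is verified non-decreasing). Samples under the 80 % call-rate
floor are flagged as QC failures. Crosses are simulated without linkage —
markers on the emulated panel average ~1.5 Mb apart, so independent per-SNP
draws are the appropriate null — which means the generator does not reproduce
the long-range haplotype structure of real genomes, and admixture tests green
here say nothing about linkage-induced error.

## Cross-species hotspot mapping

Amino-acid positions convert to genomic codon coordinates through exon-walk
CDS models (0-based half-open exons; minus-strand transcripts walk exons in
reverse genomic order), with the inverse mapping for genomic positions. A
human position is a *shared* hotspot in mouse when (i) the focal residues are
identical and (ii) the mean per-column score of a global alignment of the two
±14-residue windows is positive. The substitution matrix is a parameter; the
default is PAM10 — a short-evolutionary-distance log-odds matrix whose
strongly positive diagonal and negative off-diagonals make the mean window
score a sharp conserved-vs-chance classifier, the role the rule requires.
Window gap penalties default to open 10 / extend 1 in matrix units. When no
candidate mouse position is supplied (no coordinate-map table), one is taken
from a global alignment of the full peptides with deliberately stiffer gaps
(open 25 / extend 2): at PAM10 mismatch magnitudes, cheaper gaps would let
the aligner route around single substitutions instead of keeping orthologous
positions in register. Mouse transcript choice ranks candidates by
conserved-position count, tie-broken by principal-isoform rank, with a
per-position fallback to any transcript where the position is conserved.

The conservation factor regression is a logistic model of the shared outcome;
continuous predictors are centered at the median and scaled by two SDs so
their odds ratios are comparable with binary predictors. Separation (or any
unstable fit) suppresses the CIs and flags the result.

## Credentialing statistics

- **FGA** — genes with |log2CNR| strictly above 0.2 over genes measured
  (order-free; flox targets excluded via the gene set).
- **Copy-state score** — per arm, the number of maximal runs of identical
  state spanning ≥ 2 adjacent genes, summed over arms, so an unaltered genome
  scores one per arm (≥ 2 genes). A `mode="distinct"` flag counts distinct
  qualifying states instead.
- **Flox ratio** — Trp53-flox over Apc-flox log2CNR. With biallelic Apc loss
  this is exactly 1 for homozygous Trp53 flox deletion, exactly 0 when the
  Trp53 flox is intact, and log2(1−p/2)/log2(1−p) → 0.5 in the low-purity
  limit for heterozygous deletion. The direction is fixed as Trp53:Apc; it is
  the only direction consistent with all three expectations. A cell-means
  linear model relates genotype groups to the ratio.
- **Fisher exact** — p from the hypergeometric distribution (two-sided: sum
  of outcome probabilities ≤ the observed one) with the conditional-MLE odds
  ratio, via scipy; a zero margin reports an undefined OR and p = 1.
- **Recurrent aneuploidy** — within-sample permutation test: each sample's
  arm labels are shuffled without replacement; the statistic per
  arm/direction is the absolute two-proportion z of that arm's rate against
  the other arms pooled (tested arm excluded from the pool); empirical p uses
  the +1 correction so it is never exactly 0; BH q across arms × directions.
- **Arm specificity** — per-arm Fisher tests of the target cohort against
  each comparison cohort, BH across all tests; arms more frequent in the
  target than at least half the comparisons (significantly) are flagged, and
  pairwise co-occurrence among flagged arms is tested the same way.
- **Synteny scenarios** — for a human arm with syntenic mouse chromosome set
  S: scenario 1 = all of S gained, 2 = a proper nonempty subset (an
  exactly-one variant by flag), 3 = none. The statistic is the log odds of
  the joint human-gain × mouse-scenario event with Haldane continuity
  corrections on each frequency. Nulls come from within-sample permutation of
  both matrices. Because a genuinely enriched human arm deflates every
  scenario's own null equally, the 2-vs-1, 3-vs-1 and 2-vs-3 decisions use
  permutation tests on log-OR *differences*, where the human factor cancels;
  scenario 1 is favored only when it is itself enriched, neither alternative
  beats it, and its log OR dominates. On independent matrices the favored
  rate sits at the α level of this five-test family (~5–15 %), which is what
  the null-calibration test asserts.

## Synthetic worlds and their limits

Generator defaults are the stated conditions of the system being emulated:
mm10 autosome lengths, five inbred founder strains, cohorts of ~28 samples
for the permutation tests, read depths of 300–500×, negative-binomial
dispersion 0.02–0.15. The generators do not emulate FFPE artifacts,
mappability or off-target reads, linkage, or allele-specific signal; green
tests establish the correctness and calibration of the algorithms on their
stated model, not robustness to those real-data effects. Headline numbers
that depend on external cohorts (TCGA, CCLE, genotyping arrays, transcript
databases) are covered by property-based analogues only, and the fixture
peptides used for the named hotspot mappings are constructed synthetic
stand-ins reproducing the documented index structure, not database sequences.

## Numerical choices

0-based half-open coordinates internally (SEG converted on IO); window
rounding floor/round as above; EM tolerance 1e−8; permutation defaults
10,000 (scaled to 300–1,000 in tests to stay within CI budgets, stated per
test); BH everywhere a multiple-testing correction is needed; all randomness
flows from explicit seeds through `numpy.random.default_rng`.
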