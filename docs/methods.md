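# Methods

`crossmeth` compares whole-genome bisulfite (WGBS) methylomes quantified
against two different genome assemblies of the same species — the situation
that arises when two breeds or subspecies each have a high-quality reference
(e.g. an indicine and a taurine cattle assembly) and every sample could
legitimately be mapped to either. Two questions drive the design: which CpG
sites even exist in both assemblies, and how much of any observed
methylation difference is an artifact of the reference choice rather than
biology.

## Cross-assembly CpG classification

A CpG site is one forward-strand CG dinucleotide (methylation is symmetric,
so the two strand cytosines are one biological site). For each site of the
query assembly we take the 1,002-bp flank (500 bp each side of the 2-bp
site; sites within 500 bp of a contig end are excluded and counted), map it
onto the other assembly, keep alignments with at least 900 aligned bases on
the same chromosome, and then locally align the two 102-bp windows centered
on the midpoints (Smith–Waterman; match +1, mismatch −1, gap open −2, gap
extend −0.5). The classification is:

* **shared** — target dinucleotide under the site is CG and the midpoint
  alignment is confident;
* **snp_affected** — exactly one site base differs and no gap touches the
  site (the typical case is C>T / G>A from deamination of methylated C);
* **breed_specific** — the flank has no homologous placement at all (the
  region is absent from the other assembly); in summary accounting the
  breed-specific set is `breed_specific ∪ snp_affected`;
* **unresolved** — everything else (failed 900-bp filter, low-confidence or
  gapped midpoint, both bases changed, multi-mapping flank).

"Confident" is operationalized as ≥ 90 of 102 query columns aligned,
identity ≥ 0.95, and no gap within ±2 bp of the site; these thresholds are
exposed in `CrossmapConfig`.

### Mapper

The built-in mapper is seed-and-extend: 2-bit encoded 21-mers sampled every
8 bp on the target form a unique-k-mer index (repetitive k-mers are dropped
but remembered for multi-map detection); query k-mers are sampled every
3 bp — the two strides must be coprime, otherwise anchors exist only on
diagonals divisible by their gcd — and the largest co-diagonal anchor
cluster places the flank. Placement is extended with edlib's banded
bit-parallel DP. Flanks whose anchors lie on a single exact diagonal (the
overwhelming majority away from indels) are resolved by direct base
comparison, which equals what the DP would produce for a gapless alignment;
everything else takes the full DP route. Minus-strand hits
reverse-complement the flank (the CG midpoint is strand-symmetric, so
classification is orientation-invariant). For full-scale runs the mapper is
pluggable: minimap2 PAF records (with or without cs tags) keyed by flank id
`chrom:pos0` are ingested instead, and the test suite checks that the two
routes agree.

## Variant calling and enrichment statistics

Assembly-to-assembly variants come from the same anchor machinery: anchors
are chained into colinear blocks, block interiors are aligned with banded
DP, and block junctions — where indels live — are re-aligned with an
affine-gap aligner (match +2, mismatch −4, open −24, extend −1) so gaps come
out consolidated rather than fragmented across chance matches, which is
what unit-cost DP does to long gaps. Balanced insertion/deletion pairs that
unit-cost DP substitutes for clustered SNPs are rewritten as substitutions.
Substitutions become SNP records; indels ≥ 50 bp become SVs; 1–49-bp indels
are recorded but excluded from both statistics (standard SV size
convention). Callers can also ingest PAF+cs or VCF.

Three statistics follow:

* **CpG SNP enrichment** — per chromosome, a 2×2 chi-square of SNP status ×
  CpG-base status (a SNP "affects" a CpG if it falls on either base of the
  dinucleotide), BH-corrected across chromosomes, without Yates correction
  (counts are large in intended use; a flag enables it). Fold =
  (CpG-base SNP rate)/(non-CpG-base SNP rate); a site-level companion fold
  is also reported, base-level being primary.
* **Substitution spectrum** — substitution types restricted to CpG-affecting
  SNPs; the deamination fraction is (C>T + G>A)/total.
* **SV CpG enrichment** — per-chromosome CpG density inside SV material
  (inserted sequence; deleted reference sequence) versus the non-SV
  complement, compared with a two-sided Mann–Whitney U; the pooled density
  ratio is the fold.

## Reference-bias quantification

For one sample quantified against both references, the two percent-
methylation vectors (sites with ≥ 10× coverage) are compared after randomly
down-sampling the larger to the smaller's length — one draw, without
replacement, under a mandatory seed. The primary statistic is the
two-sample Kolmogorov–Smirnov test with a Wilcoxon rank-sum companion (the
source analyses report both), BH-adjusted across samples or groups; group
comparisons concatenate the per-sample vectors, which ignores within-sample
correlation but mirrors the pooled design being reproduced. Matched shared
CpGs additionally give an RMSE (proportion scale) and counts of sites
diverging by > 10 / > 50 percentage points ("variable CpGs"). Homologous
100-kb windows (located by the anchor index; CpGs paired through the shared
map; per-CpG value = group mean) are tested with a Wilcoxon signed-rank on
the paired differences, BH across windows, skipping windows with < 10 pairs.
The breed-specific-vs-background methylation shift uses a two-sample
rank-sum test: the sets are unpaired and of unequal size, so a signed-rank
test is not defined for them.

## Differential methylation

The caller follows the methylKit-style pipeline on shared CpGs: per-sample
coverage filter (≥ 10× and ≤ the sample's 99.9th coverage percentile,
applied before normalization), median-scaling normalization (counts scaled
by median-of-medians over the sample's median, rounded half-up, proportions
preserved), destranded uniting with `min_per_group` (5 of 6 for the breed
contrast, 10 of 12 for parent-of-origin contrasts), optional 1-kb
non-overlapping tiling, and per unit a binomial logistic regression

    logit(P_i) = β0 + β1·T_i + a_sex·Sex_i

with T = 0 for the control group (the breed matching the reference
genome), 1 for treatment, and Sex 0 = male / 1 = female. Significance is
the 1-df likelihood-ratio chi-square for β1; the effect size is the pooled
treatment-minus-control proportion difference in percentage points; DMRs
(or DMCs, without tiling) require |diff| ≥ 10 points and q ≤ 0.01.
q-values are Benjamini–Hochberg. The three standard contrasts are breed
(BIBI vs BTBT), dam-of-origin ({BIBI,BTBI} vs {BTBT,BIBT}) and
sire-of-origin ({BIBI,BIBT} vs {BTBT,BTBI}); group labels are sire breed +
dam breed.

The per-unit fits are a batched IRLS written here (all units share the
design matrix and advance through vectorized Newton steps; samples missing
a unit enter with zero trials and hence zero weight). statsmodels' GLM is
the independent oracle in the tests, never the implementation. Units that
fail to converge — complete separation, typically — fall back to a Fisher
exact test on the pooled 2×2 table and are flagged. The plain logistic test
assumes binomial noise; under overdispersed counts it is anticonservative,
and an optional flag scales the LR statistic by a per-unit Pearson
dispersion estimate (floored at 1). No correction is applied by default,
matching common tool defaults.

## Liftover and gene linkage

DMRs lift between assemblies through a block coordinate map (ground truth
in simulation; chain-like TSV otherwise): a DMR lifts when ≥ 90% of its
bases map to a single target chromosome, and lifted DMRs pair with
target-side DMRs under reciprocal ≥ 90% overlap of each length; pairs whose
hypo/hyper direction flips are reported as direction changes. Around each
gene, five strand-aware region classes are built: gene body, 5-kb flanks,
and the distance-defined 125-kb "putative enhancer" windows running from
130 kb to 5 kb away on each side, clipped at contig edges (clipping
truncates rather than drops, preserving gene counts). DMR-to-region
assignment uses the bedtools `-f 0.9 -F 0.9 -e` OR semantics: the overlap
must cover ≥ 90% of the DMR or ≥ 90% of the region. Class totals are
normalized to DMRs per Mb of merged region length; the upstream 5-kb window
serves as the promoter proxy where a promoter-normalized comparison is
wanted, since no separate promoter definition exists in this design.
Imprinted-gene summaries count hypo/hyper DMRs per gene (zero rows kept)
with DEG direction attached.

## Synthetic data

The generator produces the study conditions every stage is tested under:

* **Genomes** — i.i.d. chromosomes at G+C 0.42 (the cattle-like default).
  Random sequence is not CpG-depleted the way real mammalian genomes are,
  so absolute CpG counts are higher than reality at equal G+C; all
  downstream checks are about recovery of planted structure, not absolute
  counts.
* **Divergence** — substitutions at 0.004/bp on non-CpG bases and 13× that
  on CpG bases; CpG-base substitutions are the deamination change (C>T or
  G>A) with probability 0.81, otherwise uniform over the two
  non-deamination alternatives. SVs (default 20 per pair at default size
  50–2,000 bp; the big test pair uses 100 over 10 Mb) are half insertions —
  drawn at G+C × √1.18 so the inserted CpG density is 1.18× background in
  expectation — and half deletions, whose loci are chosen among candidates
  so the deleted material also carries ≈ 1.18× background CpG density
  (real SVs are CpG-enriched whichever assembly carries them). SNPs avoid
  SV footprints so the truth stays unambiguous, and applying the recorded
  edits to the source reproduces the derived genome byte-for-byte; a block
  coordinate map is emitted alongside.
* **Methylomes** — per distinct biological CpG one latent level: bimodal
  baseline (60% Beta(8,2) high, 40% Beta(2,8) low, global mean ≈ 0.56,
  matching the 47–62% liver means the design targets) or a constant;
  planted DMR deltas per group; a configurable offset at breed-specific
  sites. Both strands are emitted with independent Poisson coverages at
  mean_coverage/2 each (floored at 1 read), so destranded site depth
  averages the configured 30×; methylated counts are beta-binomial with
  dispersion ρ (default 0.02; ρ→0 is binomial). Calls appear in the
  coordinates of both references through the map; breed-specific sites
  appear only in the reference that carries them. Not modeled: read-level
  bisulfite conversion, non-CpG contexts, coverage biases along the genome
  — so passing tests demonstrate correctness of the statistical machinery
  under the stated noise model, not robustness to every artifact of real
  WGBS.
* **Genes/DEGs** — non-overlapping stranded gene bodies (2–20 kb) and a DEG
  subset with directions, for exercising the linkage stage.

Every operation takes an explicit integer seed and is a pure function of
(inputs, seed); one `numpy` Generator is created per call, never global
state.

## Numerical and testing choices

* Internal coordinates are 0-based half-open everywhere; VCF/GTF are
  1-based only at the I/O boundary. Flank retention is `pos0 ≥ 500 and
  pos0 + 502 ≤ contig length`. Soft-masked bases are uppercased.
* IRLS: intercept initialized at the pooled logit, linear predictor clipped
  at ±30, steps clipped at ±8, ridge 1e-8 on the information matrix,
  convergence at max |step| < 1e-10 (60 iterations cap).
* The null-calibration acceptance check runs the generator at ρ = 0: a
  binomial-model LR test is only calibrated under binomial noise. DMR
  recovery runs at ρ = 0.02.
* Planted deltas are clipped into [0, 1] per site, so a +0.30 delta
  realizes as ≈ +23 points on the bimodal baseline — still comfortably
  beyond the 10-point DMR threshold.
* One-shot stochastic acceptance checks use ~3-SE / 99% bands so their
  false-alarm rate is at the 1% level; tolerances are never adjusted per
  seed.
* Problem sizes in the acceptance tests: 1 Mb for the SNP-caller
  validation, a 10-Mb five-chromosome pair for classification and the
  enrichment estimators, 400 kb × 12 samples for DMR recovery, ≥ 2,000
  united sites for null calibration. These sizes make the whole suite run
  in about a minute while leaving every estimator's sampling error far
  smaller than the tolerances being checked.

## Known limitations

* The built-in mapper assumes mostly colinear assemblies; translocated
  segments surface as unresolved/breed-specific rather than being chased
  across chromosomes, and whole-genome alignment chaining is out of scope.
* SV breakpoints inherit the left/right ambiguity of gap placement in
  repetitive context (a called insertion can sit 1 bp off the planted
  coordinate when flanking bases repeat).
* Group-wise bias pooling ignores within-sample correlation (deliberately,
  to reproduce the pooled design); treat group-level p-values accordingly.
* SLIM-style q-values are not implemented; BH is used throughout.
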