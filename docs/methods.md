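# Methods

## Problem and model

A targeted NGS (tNGS) assay sequences a few hundred kilobases deeply. Within
those regions, common germline SNPs act as a per-individual fingerprint: at
a biallelic SNP a diploid genome is hom-ref, het or hom-alt, and the variant
allele fraction (VAF = alt reads / (ref + alt reads)) of a pure sample
clusters near 0, 0.5 or 1. Two aliquots of the same genome agree at
essentially every fingerprint SNP; two unrelated genomes agree only by
chance. With k independent SNPs of intermediate allele frequency, the
chance-agreement probability per locus is roughly 0.37–0.5, so the
probability that unrelated samples agree at ≥ 80 % of ~28 loci is
negligible while same-donor pairs sit at ≈ 1. That separation is what the
scan exploits in both directions: unexpected cross-patient matches reveal
swaps and duplicated identities, and expected same-patient pairs that fail
to match reveal the complementary half of the same mistakes.

## Panel selection

Input is a cohort variant matrix (candidate variant × sample VAFs, absent
values marked) plus population allele frequencies and precomputed linkage
groups. Stages, in order:

1. **Population-AF window** — keep candidates with at least one population
   AF annotation (genome- or exome-derived) inside [0.1, 0.9]; the window
   is inclusive at both bounds (the boundary values are still informative,
   and exclusion would be an arbitrary strictness). Candidates with no AF
   annotation cannot be assessed and are dropped with a warning.
2. **Artefact removal** — a genuine SNP segregates (VAFs near 0/0.5/1
   across carriers); a "variant" present in ≥ 90 % of samples whose present
   VAFs have standard deviation ≤ 0.05 is a systematic assay artefact.
   Both knobs are configurable; the qualitative criterion ("similar VAF in
   all samples") admits no unique quantification, and these defaults flag
   tight clusters while never flagging a segregating pattern.
3. **Prevalence filter** — candidates carried (VAF ≥ 0.1) by fewer than 5 %
   of samples contribute almost no pairwise discrimination and are dropped.
   The 5 % default is a declared assumption, configurable and logged.
4. **Linkage pruning** — linkage groups are an *input* (e.g. from pairwise
   r² against a reference population); computing LD is out of scope. From
   each group the member whose mean cohort VAF is closest to 0.5 (maximum
   heterozygosity, hence maximum information) is kept; ties break to the
   lowest genomic coordinate for reproducibility. Ungrouped candidates are
   kept.

The pipeline is a pure function of its inputs and logs the candidate count
after each stage. Panel files are BED-like TSV (0-based half-open on disk,
1-based in memory), columns chrom/start/end/rsid/ref/alt with optional AF
columns.

## Genotyping

Per BAM and panel locus, a pileup (via pysam/htslib) counts reads with
mapping quality ≥ 10 and base quality ≥ 20, excluding duplicate, secondary,
supplementary, unmapped and QC-fail alignments; overlapping mate pairs
count once per fragment. Bases are split into ref / alt / other; VAF uses
ref+alt only, keeping it interpretable as a biallelic allele fraction
(other-base counts are reported for QC). Genotypes are discretised as

    depth < 30      -> NO_CALL
    VAF  < 0.1      -> HOM_REF
    0.1 ≤ VAF ≤ 0.9 -> HET
    VAF  > 0.9      -> HOM_ALT

The het window mirrors the panel's population-AF window and the {0, 0.5, 1}
anchors; at depth 30 the binomial miscall probability of a true het
(|VAF − 0.5| > 0.4) or a true hom (VAF crossing 0.1 at error rate ~10⁻³) is
far below 10⁻³ per locus. All thresholds live in one `QualityConfig`.

## Pair comparison and classification

For a pair, loci with NO_CALL in either sample are excluded. Reported per
pair: the number of jointly callable ("evaluable") loci, the fraction of
concordant genotype calls, the Pearson correlation of the two VAF vectors
over evaluable loci, and the exact positions of discordant loci (so flagged
pairs can be inspected SNP by SNP). A pair with zero discordant loci is a
normal result — the comparison completes with an empty discordance list.

Correlation is computed on VAFs rather than discretised genotype codes:
VAF is what the readcounts report stores, and continuous VAFs are what make
copy-number-driven borderline cases explainable. When either VAF vector is
constant, Pearson correlation is undefined; the degenerate rule returns 1
if the vectors agree elementwise within 0.1 and 0 otherwise, which keeps
self-comparison of an all-hom-ref profile sane. Fewer than two evaluable
loci give an undefined (NaN) correlation, and a NaN never matches.

Classification uses two thresholds that must both hold: correlation ≥ 0.9
and concordance ≥ 0.8 → MATCH; concordance in [0.7, 0.8) at r ≥ 0.9 →
BORDERLINE_MATCH. The borderline band exists because genuine same-donor
pairs fall below 0.8 concordance for benign reasons — clones with
chromosome aberrations changing size between timepoints shift het VAFs on
one chromosome, and low coverage adds stochastic miscalls — while their VAF
correlation stays high. Collapsing the band
(`concordance_match == concordance_floor == 0.7`) reproduces a
single-threshold matcher. Pairs with fewer than 10 evaluable loci are
reported but flagged UNEVALUABLE rather than silently classified. Values
are kept at full precision internally and rounded to 3 decimals only in CSV
output.

## Cohort scan and reports

The scan compares all n(n−1)/2 pairs. Internally the per-pair counts and
correlations are computed with masked-sum matrix products (for each pair,
sums of VAFs, squared VAFs and cross-products over the joint callable mask
are all expressible as matrix multiplications), which keeps 400-sample
batches around a second; pairs hitting the degenerate-variance case are
recomputed through the scalar rule. The scalar `compare_pair` remains the
reference implementation and the test suite asserts both routes agree
exactly. The scan is quadratic by design; a warning is emitted beyond
5,000 samples.

Expected same-patient pairs are derived from sample names: the default
patient-id extractor captures the first maximal digit run (names like
`CLL-68035557-02S65286-TP1`), overridable by regex or an explicit pair
list. Verdicts: CONCORDANT (MATCH), REVIEW (BORDERLINE_MATCH), DISCORDANT
(NO_MATCH or UNEVALUABLE).

Reports use the fixed naming scheme `Pairwise_concordance_[suffix]_[ts].csv`
(matching pairs first, then descending correlation),
`SNP_readcounts_[suffix]_[ts].csv` (one row per sample × locus),
`Expected_concordant_pairs_[suffix]_[ts].csv` (descending correlation, so
broken pairs sink to the bottom) and an optional heatmap PNG of the
symmetric correlation matrix on a fixed [−1, 1] scale. Timestamps
(`YYYYMMDD-HHMMSS`) are injectable so outputs are byte-reproducible.

## Subset power and contamination

`subset_sensitivity` redraws uniform random panel subsets (one deterministic
RNG per (master seed, size, iteration), spawned via `SeedSequence` so runs
are reproducible and independent across cells) and re-runs the scan,
recording detected planted unexpected pairs, detected broken expected
pairs, and false positives. A false positive is a MATCH between samples
that share no patient label and are not a planted same-donor pair;
borderline matches count toward detection but not toward false positives.

The contamination score of a sample is the mean over callable loci of the
distance from its VAF to the nearest anchor {0, 0.5, 1}; loci deviating by
more than 0.1 are listed and the sample is flagged above 0.05. A fraction f
of foreign DNA shifts VAFs by ~f/2 at loci where the two genotypes differ
(~half the panel for unrelated individuals), so the expected score is
roughly 0.25·f·d where d is the genotype-difference fraction: at depth 500
the score separates cleanly from the clean baseline (~0.007) from f ≈ 5 %
onward, while the default 0.05 flag threshold corresponds to f ≈ 20 %.
Lower the threshold (e.g. 0.02) to flag milder admixture at the cost of
sensitivity to noise at low depth.

## Synthetic cohorts

The generator emulates the structure of a longitudinal tNGS study: P
patients × T timepoints (default 2, mirroring diagnosis + follow-up).
Genotypes are drawn per patient and locus under Hardy–Weinberg equilibrium,
(1−p)², 2p(1−p), p² for the locus population AF p. Read counts per locus:
depth ~ negative binomial with mean 100 (dispersion parameter default 1000,
i.e. near-Poisson; real tNGS depth is overdispersed and the parameter is
exposed), alt reads ~ Binomial(depth, μ) with μ = e, 0.5, 1−e for
hom-ref/het/hom-alt and per-read error e = 0.001. Timepoints share the
genotype row but draw independent noise.

Planted errors: *swap* exchanges two sample labels; *mislabel* rewrites the
patient-id span of one name; *contaminate* resamples a sample's counts from
a (1−f)/f mixture of its own and a donor's expected allele fractions at
unchanged depths; *cna_shift* moves the expected het VAF on one chromosome.
The true genotype matrix is never altered. Ground truth is derived
generically from (DNA donor, labelled patient id) per profile — unexpected
pair = same donor, different label; broken expected pair = same label,
different donor — which stays correct when errors interact (e.g. a mislabel
of a sample already involved in a swap renames the implied pair rather than
double-counting it).

The standard validation scenario (`validation_cohort_config`) uses 200
patients × 2 timepoints, depth 100, e = 0.001, the bundled 28-SNP panel,
3 TP2 swaps and 1 mislabel-to-fresh-label of a swap-affected patient's TP1,
implying exactly 6 unexpected pairs and 5 broken expected pairs. 200
patients (400 samples, 79,800 pairs) is large enough that chance
false-positive matches would show up while a full scan still takes about a
second.

Miniature BAM fixtures: a synthetic reference with one small contig per
panel chromosome is written as FASTA; each read (100 bp, MAPQ 60, base
quality 40) covers exactly one locus and carries its ref or alt base, so a
pileup reproduces the simulated counts exactly. Loci closer together than
the read length are rejected (a read for one locus would otherwise pile up
on its neighbour). Optional duplicate-flagged decoy reads exercise the
duplicate filter.

What the generator does **not** emulate: alignment/mapping ambiguity,
indels, strand or cycle-dependent error profiles, GC-driven coverage bias,
related individuals, or tumour clonal evolution beyond the single-
chromosome VAF shift. Passing tests therefore demonstrate the logic of
selection, genotyping, matching and bookkeeping — not robustness to every
artefact of real sequencing data.

## The bundled panel

`snptrace/data/panel28.synthetic.bed` carries the 28 rsIDs of a published
CLL tNGS fingerprint set, but its coordinates, alleles and allele
frequencies are synthetic stand-ins (two loci per synthetic chromosome at
small positions, AFs spread over [0.15, 0.85]) so that BAM fixtures remain
tiny; the file and `default_panel()` say so explicitly. For real use, load
your own panel BED.

## Numerical and degenerate-input choices

- Genomic ordering is natural (chr1 < chr2 < … < chr10 < chrX); panels
  reject duplicate (chrom, pos) records and non-single-base BED records.
- VAF at zero informative depth is NaN and the locus is NO_CALL.
- The vectorised scan recomputes a pair through the scalar path whenever
  the centred sum of squares falls below 10⁻⁹ of its scale, so floating-
  point cancellation can never silently misclassify a constant vector.
- Empty inputs degrade softly (empty panel file → empty panel with a
  warning; empty profile list → header-only CSV); precondition violations
  (missing BAM index, chromosome-naming mismatch, duplicate sample ids,
  oversized subsets, a sample in two swaps) raise errors naming the
  offender.

## Known limitations

- Genotype calls are hard threshold calls, not likelihood-based; very low
  depth loci are simply excluded by `min_depth` rather than modelled.
- The matcher is designed for same-individual identity, not relatedness:
  first-degree relatives will land between the match and no-match regimes
  and are not explicitly handled.
- Contamination scoring detects admixture but does not identify the source
  sample.
- The scan holds all pairwise results in memory; for cohorts far beyond
  5,000 samples a streaming design would be needed.
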