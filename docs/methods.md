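# Methods

## Data model and conventions

All coordinates are 0-based half-open (BED convention) throughout. A
*tag* is one aligned immunoprecipitation fragment; for every counting
operation a tag is assigned to the single base at its fragment midpoint,
`(start + end) // 2`, ignoring strand. MeDIP fragments cover the
captured methylated site roughly symmetrically, and no fragment
shift/extension model is assumed; midpoint assignment is the simplest
convention consistent with that, and the simulator emits full fragment
intervals so an overlap-based convention could be compared if wanted.
Each library records its total mapped tag count `N`, the denominator of
every density.

Density is RPKM: `count * 1e9 / (region_length_bp * N)` — reads per
kilobase of region per million mapped tags. The formula is the standard
one; it makes densities comparable across regions of different length
and libraries of different depth (doubling every tag and `N` leaves it
unchanged).

## Peak calling

Each IP library is tested against its own sample's input library with a
sliding window (default 200 bp window, 50 bp step — window on the order
of the sonicated fragment size, which is bounded at 500 bp). Under the
null the IP count in a window is Poisson with mean equal to the
depth-scaled input count; the mean is floored at the genome-wide IP
background rate times the window length so that empty input windows
cannot yield a zero-mean null (a zero mean would make any IP tag
infinitely significant). The per-window p-value is the exact upper tail
`P(X >= k)`; FDR is Benjamini–Hochberg across all scanned windows of
the library pair. Windows passing *both* `p < 1e-5` and `q < 0.01` are
merged into peaks when separated by at most `merge_gap` (100 bp)
— thresholds are the conventional MACS-style cut-offs for this assay
family. This caller deliberately omits MACS's model building, local
lambda cascade and shift estimation: it is a transparent stand-in whose
null is exactly calibrated on the simulator's uniform background, and
whose p-values are testable against a closed-form oracle.

A known tension in the thresholds: published summaries of such peak
sets sometimes quote FDR ≤ 5 % while the analysis text states
FDR < 0.01. This implementation takes `p < 1e-5` and FDR < 0.01 as the
defaults; both are configurable.

## DMR/DHMR identification

The candidate-region universe for one mark is the overlap-merged union
of all libraries' peaks of that mark (a consensus-union, as in
affinity-based differential binding tools); each candidate records its
contributing libraries. The region × library RPKM matrix is computed
with the counting rules above, and per region a two-sided
pooled-variance Student t-test compares the case and control RPKM
values (minimum two libraries per group). A region is called
differential when `p < alpha` (default 0.05) *and* the pseudo-counted
group-mean ratio reaches `fold_min` (default 2):
`|log2((mean_case + eps) / (mean_control + eps))| >= 1`.

Numerical choices:

* `eps = 0.5` RPKM is added to both group means *only* for the fold
  change (and MA coordinates), never inside the t-test; it guards
  against division by an empty control mean and damps foldchanges of
  near-empty regions. It is configurable.
* Regions with zero variance in both groups and equal means carry no
  information and are skipped with a diagnostic; zero pooled variance
  with unequal means is resolved to p = 0 (and p = 1 for equal means)
  with a warning.
* No multiple-testing correction is applied to the per-region p-values;
  the region-level threshold *is* the analysis definition here. This is
  anti-conservative and users comparing many thousands of candidate
  regions should prefer an FDR-controlled variant; the per-region
  p-values are reported so this can be applied downstream.

The MA transform reports, per region, `A` = pseudo-counted mean RPKM
over all libraries and `M` = the pseudo-counted log2 group-mean ratio,
plus the called flag under the same thresholds. Genes carrying both a
5mC and a 5hmC differential region are the set intersection of the two
marks' associated-gene sets.

## Annotation

The promoter is TSS ± 2 kb, strand-aware (TSS = transcript start on
'+', transcript end on '−'), clipped at chromosome bounds — width is
exactly 4 kb except at edges. Feature classification uses the region
*midpoint* with precedence promoter > 5'UTR > 3'UTR > exon > intron >
intergenic, so every region receives exactly one category and category
fractions over a region set sum to one (as needed for pie-style genomic
distribution summaries); multi-feature tie-breaking is otherwise
arbitrary and this fixed precedence makes it deterministic and
order-independent. Gene *association* is deliberately different:
any-overlap of the region against transcript ∪ promoter, reporting the
location as promoter and/or body — a region may associate with several
genes, and summaries count genes with promoter hits, body hits and
both. Gene models are collapsed single-transcript models; UTRs exist
only where a CDS is annotated.

## Coverage profiles

The metagene profile rescales each gene body to 100 equal bins with
flanks spanning 20 % of that gene's own length per side (20 bins each),
computes per-bin density `count / bin_length / N * 1e9`, reverses
minus-strand genes so bin 0 is always upstream, and averages over
genes. Genes shorter than the body bin count in bp are dropped (sub-bp
bins) and the dropped count reported. The TSS profile averages density
in fixed 100 bp bins over a strand-oriented ±5 kb window around each
TSS. Both accept a gene-subset argument so profiles can be restricted
to, e.g., genes associated with differential regions — whether such
figures are computed over all genes or affected genes only is an
analysis choice the caller makes explicitly.

## Validation statistics

* Comparative-Ct enrichment: `2^(Ct_input − Ct_IP)`; equal cycles give
  1, and the measure is reciprocal under swapping.
* MassARRAY-style amplicon summaries: inapplicable (missing) readings
  are dropped listwise per CpG unit, never imputed; per sample the
  amplicon mean is taken over its non-missing CpG units, per group the
  mean of sample means; per CpG unit a pooled t-test compares groups.
  An amplicon missing an entire group is skipped with a diagnostic.
* Two-group tests: the default is the pooled-variance Student t
  (df = n1 + n2 − 2). The Mann–Whitney U test is provided exact — full
  enumeration of all C(n1+n2, n1) group assignments with midrank ties,
  feasible for n1 + n2 ≤ 12, two-sided by deviation of U from its mean
  — and asymptotic, with tie-corrected variance and no continuity
  correction (the convention of classic SPSS-era software). The clinical
  table driver applies the pooled t per characteristic with per-row test
  overrides, mirroring designs that report "Student's t or
  Mann–Whitney" per row without stating which rows used which. At
  n = 6 + 6 the normal approximation deviates from the exact law by up
  to ≈ 0.07 in p (mean ≈ 0.04); the exact branch should be preferred at
  these sizes.

## Synthetic data generator

The generator emulates a two-group placental immunoprecipitation study:
per sample one 5mC-IP, one 5hmC-IP and one input library, default 4
case + 4 control samples, fragments uniform in [100, 400) bp (< 500 bp
sonication bound). Tag midpoints are drawn from a categorical mixture:
uniform background over the genome plus spiked regions. A region of
fold `f` contributes extra weight `(f − 1) × length`, so its expected
tag rate is exactly `f ×` background — closed-form expectations for
every region, which the tests exploit (χ² goodness-of-fit of region
counts against the mixture weights). Shared enriched regions have
`enrichment_fold` (default 8) in every IP library, emulating
constitutive methylation peaks present in both groups; differential
regions give the favoured group `enrichment_fold × differential_fold`
and the other `enrichment_fold`, so the between-group density ratio is
`differential_fold` (default 4, split evenly case-up/control-up) while
both groups remain peak-callable there. Input libraries draw background
only. When gene models exist, alternating differential regions are
planted inside a random gene's promoter or body so annotation has known
positives.

Defaults: 2 Mb genome (two 1 Mb chromosomes), 60 genes of 5–15 kb, 30
shared + 20 differential regions of 0.6–1.5 kb, and 1,000,000 tags per
library. Depth is a free parameter of the design (real studies report
only aggregate throughput); 0.5 tags/bp puts per-window (~100 tags) and
per-profile-bin (~thousands across genes) counts deep enough that
law-of-large-numbers properties — flat uniform metagene profiles
(max/min bin ratio < 1.2), density ratios near their expectations —
hold at this miniature genome scale, which is the regime a deeply
sequenced mammalian library occupies on its own genome.

Determinism: gene models and truth regions depend only on the config
seed (plus an optional stream index, used to draw independent 5mC and
5hmC truth sets); each library additionally takes a replicate seed, and
a fixed (seed, replicate seed) pair is byte-identical.

What the simulator does **not** model: sequence content (no FASTQ or
error model), CpG-density-dependent antibody efficiency, copy-number
or mappability structure, duplicate reads, fragment-length biases, or
correlated biological replicate variability beyond sampling noise.
Passing recovery tests therefore demonstrate the pipeline's correctness
under its own statistical assumptions — uniform background, independent
sampling — not robustness to the enrichment biases of real MeDIP data.

## Problem sizes in the tests and acceptance script

The test suite and `scripts/acceptance.py` run the default scenario at
the 2 Mb / 1M-tag scale (seconds per run), null calibrations over
20–50 seeded replicates at a reduced 200–400 kb / 20–40k-tag scale, and
the χ² mixture check over 100 replicates at 20k tags. These sizes were
chosen so each check has ample statistical resolution at desk scale;
headline counts from genome-scale studies (hundreds of DMRs over hg19)
are not reproducible at this scale and are not targets.

## Known limitations

* The Poisson window caller ignores overdispersion between biological
  replicates at the peak-calling stage; between-sample variability
  enters only at the t-test stage.
* Per-region p-values are uncorrected (see above).
* Candidate regions derive from peaks, so a region differential in one
  group but below peak threshold in *both* groups is invisible.
* The exact Mann–Whitney is limited to n1 + n2 ≤ 12 by enumeration;
  beyond that the tie-corrected asymptotic branch is used.
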