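# Methods

`h3k4seq` analyzes genome-wide histone H3 lysine-4 methylation (H3K4me1/me2/me3)
ChIP-Seq in two conditions (watered vs dehydration-stressed), from
uniquely-aligned read positions to peak calls, gene-level mark tables, metagene
profiles, differential methylation, and a profile-broadness test. This note
records the models, conventions, and numerical choices, and what the synthetic
data used for testing does and does not establish.

## Coverage model

Coverage c(x) is the number of uniquely-aligned 35 bp read footprints
overlapping base x. Uniqueness and the mismatch limit are an upstream contract
of the aligner output this package consumes; no re-filtering is done here. Raw
tracks conserve mass (sum = reads x footprint length after end clipping). An
optional 3' extension models fragment length; the default is 0 (footprints as
aligned) because no fragment-extension model is part of the published
procedure.

Input-DNA normalization divides the depth-scaled ChIP track by the smoothed
input profile:

1. scale the ChIP track by `input_library / chip_library` (read counts when
   known, otherwise coverage mass — equivalent at equal read length);
2. divide position-wise by the input coverage smoothed with a 500 bp centered
   moving average and rescaled to genome-wide mean 1, floored at 0.25 of that
   mean so sparse input positions cannot produce division spikes.

A flat input at matched depth is therefore the identity. The exact arithmetic
behind published input normalizations of this kind is rarely stated; the
formula above is this package's declared convention, and `mode="scale"`
(library-size scaling only) is available as an alternative.

## Background and peak calling

Background b is the mean coverage of intergenic space (the genome minus the
union of annotated gene spans), estimated once per track; for runs of this
assay type it falls around 1–3x coverage.

Peaks are **all maximal scoring segments** of the score s(x) = c(x) − b, i.e.
the Ruzzo–Tompa all-maximal-scoring-subsequences problem — the standard
formalization of the local-alignment/HSP analogy: disjoint segments with
positive total score that can be neither extended nor trimmed to score higher.
Local drops below background inside a peak are tolerated exactly when
compensated by subsequent above-background stretches. Properties that follow
and are enforced by tests: segments begin and end strictly above background;
adding a constant to both coverage and background changes nothing; raising b
can only shrink, split, or delete peaks. Ties (zero-sum extensions) resolve in
favour of the shorter segment (leftmost start, earliest end at the maximum
cumulative score). Chromosomes are processed independently.

The implementation runs in linear time over sign-runs of s(x); a quadratic
recursive-extraction enumerator is kept in the test suite as an independent
oracle and the two are compared exactly on hundreds of random score vectors.

Reported peaks must have cumulative score ≥ `min_score` (default **200**) and
length ≥ `min_length` (default 50 bp). The score floor is calibrated to the
assay's background levels: with b ≈ 2.5 and 35 bp reads, a single chance extra
read above background already accumulates a score near 35, and clustered-read
excursions reach ~80, while genic enrichment scores run 10^3–10^4; 200
separates the two regimes by an order of magnitude on each side. Both knobs
are config-exposed (`peaks.min_score`, `peaks.min_length`).

A practical consequence of maximal-segment semantics worth knowing: two
enriched regions merge into one peak exactly when the score drop between them
is smaller than **both** flanking segment scores. In gene-dense regions broad
gene-body marks (me1/me2) therefore form multi-gene domains, which matches how
those marks blanket most genes; gene-level counting is unaffected for marked
genes but can overcount unmarked genes that sit inside a domain.

## Gene-level marks

A peak marks a gene when it overlaps ≥ `min_overlap` bp of the gene span
(default 1 bp; an optional upstream promoter flank, default 0, extends the
span on the 5' side). A peak overlapping several genes marks all of them but
counts once in the genic fraction. The summary table reports, per mark and
condition, gene counts and percentages of all supplied genes, plus the union
row ("one or more types", union over marks **and** conditions — flagged in the
report header) and its complement.

## Metagene profiles

**Anchored profiles** aggregate normalized coverage at fixed offsets around
the TSS or stop-codon anchor on the gene's strand-oriented axis (downstream
positive for both strands), default window −1000..+1000, mean aggregate.
Offsets falling off the chromosome are excluded per-offset; genes shorter than
the window are retained, reading whatever lies beyond them, as a browser-style
metaplot does. Neighboring genes are *not* masked; in dense genomes the outer
flanks therefore include neighbor signal.

**Length-normalized profiles** rescale each gene body to a standard 1500 bp
axis by linear interpolation (nodes at base centers, samples at
(i+0.5)/1500·L), restricted to genes of 1000–2000 bp so the distortion stays
modest, with 500 bp native-scale flanks; the per-position aggregate is the
median. Bin-mean resampling is available behind a flag.

**Expression quintiles** sort genes ascending by transcript level and split
them into five contiguous blocks (sizes differing by at most one, larger
blocks first; ties broken by gene id, so the split is deterministic).
Quintile 5 is the most expressed.

`peak_normalize` rescales a profile by its maximum (shape comparison);
`profile_peak_position` returns the offset of the maximum (smallest offset on
ties; flat profiles raise).

## Differential methylation

Responsive genes: |fold| ≥ 4 and p ≤ 0.001, both inclusive, on a signed-fold
convention (−4 means a 4-fold decrease; |fold| ≥ 1 always). The expression
p-values are inputs from the upstream microarray analysis; they are never
recomputed. Up- and down-regulated genes are quintiled independently on
|fold| (+1..+5 and −1..−5; 5 = biggest change). The per-gene methylation
change is the **mean** per-base normalized coverage over the gene span,
stressed minus watered — a mean so the statistic is length-independent (a sum
is available behind a flag). Per quintile and mark, the median and standard
deviation of member deltas are reported.

The stability control takes genes with |fold| ≤ 1.2 and p > 0.5 (a declared
convention; the source analysis does not define its unchanged set) and
computes the Pearson correlation of per-gene mean coverage between conditions,
one value per mark.

## Broadness test

Each gene's length-normalized body profile is divided by its own maximum and
summed: the **broadness score**, the area under the max-1 profile, in
(0, 1500]. A flat-at-max profile scores 1500, a one-position spike scores 1.
Per-gene peak normalization is deliberate — it makes the score compare shapes,
not heights; cohort-level peak normalization is only a display step. Cohorts
(dehydration-induced genes vs all expressed genes, the latter defined as genes
above the 20th percentile of watered transcript level) are compared with a
two-sided Wilcoxon rank-sum test.

The rank-sum test uses mid-ranks for ties; the two-sided p is exact by full
enumeration when n ≤ 12 without ties, otherwise a normal approximation with
tie-corrected variance and 0.5 continuity correction (cross-checked against an
independent implementation in the tests; exact and normal branches agree
within 0.02 at moderate n). The exact-enumeration cutoff balances cost against
coverage of small fixtures. Sidedness is two-sided by declared convention.

## Synthetic data

The generator produces a deterministic desk-scale study from a single seed:
2 chromosomes x 500 kb, 500 non-overlapping single-exon genes (lengths
log-uniform 800–3000 bp, heavy-tailed intergenic gaps with a 200 bp floor),
log-normal transcript levels defining quintiles, 5% up- and 5% down-regulated
genes with |fold| log-uniform in [4, 150], and reads for 4 marks + input in
both conditions by inhomogeneous Poisson sampling (read centers drawn from the
per-base intensity; an optional negative-binomial switch overdisperses totals).

Planted structure, mirroring the biology the pipeline must recover:

- **me3**: 5' peak at TSS+300 (exponential rise 150 bp, decay 400 bp), height
  saturating with transcript level (Michaelis form, max 9, K = 15 — methylation
  cannot exceed full nucleosome occupancy, and the cap keeps single-gene
  segment scores below the score drop across an unmarked neighbor, which is
  what separates peaks under maximal-segment semantics). Present on the top
  two quintiles, 80% of Q3, 30% of Q2, none of Q1.
- **me1**: gene-body plateau (log-normal per-gene level around 4) with a 5'
  elevation confined to the low-expression quintiles.
- **me2**: flat per-gene body level, independent of expression and condition.
- **H3**: near-uniform genome-wide, slight genic enrichment, and a Gaussian
  nucleosome-depleted dip centered 150 bp upstream of the TSS for the top
  three quintiles.
- **Intergenic space of the methylation ChIPs**: a low nonspecific floor
  (0.25x) plus scattered nonspecific "sticky" islands that raise the
  intergenic *mean* to the configured background (default 2.5, within the
  assay's 1.1–3.25 run range). This reflects targeted-ChIP reality — the marks
  are essentially absent between genes, yet the run's intergenic mean is a few
  reads deep and a minority of called peaks is intergenic. A flat intergenic
  rate equal to the background would make every inter-gene drop compensated
  and chain all maximal segments genome-wide.
- **Condition response**: up-regulated genes gain, and down-regulated genes
  lose, me3 in proportion to log2|fold|, parameterized in per-gene
  mean-coverage units (1.6 per log2-fold; the height shift is rescaled by gene
  length over the shape area so the planted mean-coverage change tracks the
  fold change rather than the gene's size). me1 shifts slightly in the
  opposite direction; me2 does not change. Half of the up-regulated
  ("inducible") genes carry a 3x longer me3 decay — the broad profile — in
  *both* conditions.
- ~10% of genes, concentrated in the lowest quintiles, are silent (no marks).

What passing tests on this data establish: the pipeline recovers planted
backgrounds, enrichment calls, quintile orderings, response monotonicity, and
broadness differences under independent-read Poisson noise. What they do not:
robustness to duplicate-read artifacts, mappability holes, GC bias, antibody
cross-reactivity, or replicate variation — none of which the generator models.

## Degenerate inputs and tie-breaks

Empty read sets give all-zero tracks; an all-zero input track cannot be used
for normalization (error). A genome fully tiled by genes has no background
(error). Zero peaks make the genic fraction undefined (reported absent).
Fewer than 5 genes cannot be quintiled; a response direction with fewer than
5 genes is left unbinned with a warning. All-zero gene profiles are excluded
from broadness scoring with a warning. Flat profiles have no peak position
(error). Genes on chromosomes absent from the genome are dropped with a
warning, not an error.

## Problem sizes used in the checks

The automated checks run the full analysis on the default 500-gene, 1 Mb
study; background recovery is verified at three rates spanning 1.10–3.25;
the peak-caller/oracle comparison uses hundreds of random vectors of length
≤ 60; test calibration uses 2000 null replicates at n = 50 + 50; broadness
power uses replicates of 200 broad vs 2000 normal gene profiles drawn from
the generator's profile-level sampler. These sizes were chosen so every
planted effect is measured with comfortable statistical margin while the whole
suite stays desk-scale.

## Known limitations

- Exon structure, UTRs, and alternative TSSs are ignored throughout; the gene
  span is the unit of analysis.
- The published headline numbers from the original deposited datasets (mark
  percentages over 27k genes, 640/525 responsive genes, the exact broadness
  p-values) depend on the full-genome data and a proprietary microarray error
  model, and are not reproducible at desk scale; the package reproduces the
  *patterns* and exposes the full-data path through the same file interfaces.
- Under maximal-segment semantics, gene-body mark domains chain across short
  gaps; gene-level percentages for me1/me2 are upper bounds at high packing
  density.
- The metagene windows do not mask neighboring genes (noted above); outer
  flank values in dense regions mix in neighbor signal.
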