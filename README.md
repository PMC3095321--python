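# h3k4seq

Genome-wide analysis of histone H3 lysine-4 methylation (H3K4me1, H3K4me2,
H3K4me3) ChIP-Seq across two conditions — watered and dehydration-stressed —
for people studying how chromatin marks track transcriptional reprogramming:
which genes carry which marks, how mark profiles align with expression level,
how they shift when transcription changes, and whether stress-inducible genes
carry atypically *broad* H3K4me3 distributions.

The pipeline consumes uniquely-aligned read positions (BED), gene annotations
(GFF3/BED), and an expression table (TSV), and produces browser-loadable
tracks and peak calls plus the numeric tables behind the classic figures of
this analysis style. A seeded synthetic-data generator replaces the original
deposited raw data, so the entire pipeline is testable at desk scale.

## The method

**Coverage and normalization.** Per-base coverage c(x) counts 35 bp read
footprints over each base. ChIP tracks are depth-scaled to the input-DNA
library and divided position-wise by the smoothed input profile (500 bp
moving average, rescaled to mean 1, floored at 0.25 of the mean).

**Peak calling.** Background *b* is the mean coverage of intergenic space,
estimated per sequencing run. Peaks are **all maximal scoring segments** of
the score

&nbsp;&nbsp;&nbsp;&nbsp;s(x) = c(x) − b

in the Ruzzo–Tompa sense — disjoint segments of positive cumulative score
that can be neither extended nor trimmed to score higher, the same structure
as high-scoring segment pairs in local alignment. Local drops below
background are absorbed exactly when compensated by later above-background
stretches. The linear-time algorithm is verified against an exhaustive
enumeration oracle in the tests.

**Gene-level marks.** A peak marks every gene it overlaps (≥1 bp by default);
the summary table reports per-mark gene percentages, the "one or more types"
union, and its complement.

**Metagene profiles.** Genes are split into expression quintiles; coverage is
aggregated at fixed offsets around the TSS/stop anchor (strand-oriented), or
over gene bodies rescaled to a standard 1500 bp with 500 bp native flanks
(genes of 1–2 kb, median aggregate).

**Differential methylation.** Responsive genes (|fold| ≥ 4, p ≤ 0.001) are
quintiled by |fold| per direction; the per-gene change is the mean per-base
normalized coverage over the gene span, stressed − watered. Unchanged genes
(|fold| ≤ 1.2, p > 0.5) provide a stability control via Pearson correlation
of per-gene coverage between conditions.

**Broadness test.** Each gene's length-normalized body profile is divided by
its own maximum and summed (area under the max-1 profile, in (0, 1500]); the
broadness scores of dehydration-induced genes are compared against all
expressed genes with a two-sided Wilcoxon rank-sum test (exact for small
tie-free samples, tie-corrected normal approximation with continuity
correction otherwise).

Details, conventions, and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a small study and run the full pipeline (everything is deterministic
under the seed):

```sh
h3k4seq simulate --seed 7 --outdir demo/data --config demo.yaml   # small sizes
h3k4seq run --config demo/data/pipeline.yaml --outdir demo/report
```

or equivalently from Python:

```python
from h3k4seq.synthetic_data import SyntheticConfig, write_dataset
from h3k4seq.pipeline import PipelineConfig, run_pipeline

cfg = SyntheticConfig(seed=7, n_chrom=2, chrom_len=120_000, n_genes=80,
                      gene_length_range=(1000, 2000), frac_up=0.1, frac_down=0.1)
write_dataset(cfg, "demo/data")
run_pipeline(PipelineConfig.from_yaml("demo/data/pipeline.yaml"), "demo/report")
```

`demo/report/gene_mark_summary.tsv` then contains:

```text
row                                               n_genes  pct_genes
watered: H3K4me1                                  77       96.2
watered: H3K4me2                                  78       97.5
watered: H3K4me3                                  54       67.5
stressed: H3K4me3                                 61       76.2
Genes with one or more types of H3K4 methylation  80       100.0
```

— the tri-methylation mark is the selective one (67.5% of genes, rising under
stress as induced genes gain it), while me1/me2 blanket nearly all expressed
genes. `broadness_test.tsv` holds the profile-shape comparison of induced vs
expressed genes:

```text
condition  U      n_induced  n_expressed  z        p            method
watered    379.5  8          64           2.20403  0.0275225    normal
stressed   440.5  8          64           3.29708  0.000976956  normal
```

— induced genes have broader H3K4me3 profiles than typical expressed genes
*already in the watered state*, and the separation sharpens after stress.
`stability_correlation.tsv` shows the control: genes whose expression did not
change keep their methylation (Pearson r = 0.95 / 0.97 / 0.95 for
me1/me2/me3 between conditions). `manifest.json` records the resolved
configuration and the per-sample intergenic backgrounds (2.4–2.6 here), so a
rerun with the same config is byte-identical.

The report directory also contains the peak BEDs per sample, the
quintile-resolved metagene table (`metagene_quintiles.tsv`, showing the
H3K4me3 peak ~300 bp downstream of the TSS ordered by expression quintile),
and the per-change-quintile methylation deltas (`quintile_delta_summary.tsv`).

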