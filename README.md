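# pioneerlink

Pioneer transcription factors bind their motifs inside closed,
nucleosomal chromatin and open it; most other factors need chromatin that
is already accessible. Distinguishing the two behaviors for an endogenous
factor requires integrating several genome-wide assays: where the factor
binds (ChIP-seq), which of its sites are accessible (ATAC-seq), how
accessibility changes when the factor is knocked out or when a
chromatin-remodeling complex (mSWI/SNF) is inhibited, and how those
chromatin changes propagate to gene expression through enhancer–gene
links.

`pioneerlink` implements that integrative analysis as a reusable, tested
pipeline for epigenomics researchers:

- **Interval algebra** on BED-convention coordinates (1-bp overlap,
  merging, nearest-TSS, promoter/genic/intergenic annotation).
- **Differential counts**: median-of-ratios normalization (with a
  control-region refit), a moderated negative-binomial Wald test
  (Var = μ + αμ²), and Benjamini–Hochberg q-values; calls at
  |FC| ≥ 1.5, q ≤ 0.05.
- **Activity-by-contact (ABC) enhancer–gene links**: candidate elements
  from summit-recentered consensus ATAC peaks (top 150,000, ±275 bp)
  merged with 500-bp promoter windows; activity
  A = √(ATAC × H3K27ac); contact C(d) = max(d, 5 kb)^(−1.024); score
  ABC(E,G) = A·C / Σ A·C over elements within 5 Mb of the TSS, kept at
  score ≥ 0.022.
- **Site taxonomy**: open/closed chromatin state, knockout dependency
  (opens / represses / static), pioneer mode (classical pioneer — no
  residual accessibility without the factor — vs permissive), prebound
  early-state consistency, remodeler cobinding, knockout/inhibitor
  codependency (relaxed q < 0.5, sign-concordant inhibitor response) and
  partner-binding change (unchanged / decreased / absent).
- **Gene-level concordance** between accessibility direction and
  differential expression.
- **A synthetic-study generator** that plants all of the above classes
  with known truth, so every stage is testable end to end without
  external data.

## Worked example

Run the full pipeline on the default simulated study (2,000 TF sites,
200 genes, four ATAC conditions × 3 replicates) and read the summary:

```bash
pioneerlink run --simulate --seed 7 --preset paper --outdir demo/
```

```python
import pandas as pd
s = pd.read_csv("demo/summary.tsv", sep="\t").set_index("metric")["value"]
```

Selected lines of `demo/summary.tsv`:

```
n_sites                       2000.000000
n_open                        1357.000000
frac_open                        0.678500
n_dependent                    320.000000
frac_dependent_of_open           0.235814
n_decreasing                   162.000000
n_classical_pioneer             71.000000
frac_classical_of_decreasing     0.438272
frac_cobound_open                0.548268
prebound_consistency             0.715556
n_codependent                  153.000000
fc_correlation_r                 0.566730
concordance_down                 0.793478
concordance_up                   0.714286
```

Reading: of 2,000 simulated TF sites, 1,357 (67.9%) overlap wild-type
ATAC peaks (the generator plants 68.3%); 23.6% of the open sites change
accessibility in the knockout (planted 23.9%); 162 of those lose
accessibility, of which 71 (43.8%) are classified classical pioneer —
completely closed without the factor (planted 50.3%, recovered within
binomial sampling error of the 162-site denominator); 54.8% of open
sites are cobound by the remodeler (planted 54.9%). 71.6% of sites
already closed in the early, factor-naive condition are also
knockout-dependent (planted 74.7%), knockout and inhibitor fold changes
correlate r = 0.57 at dependent sites, and decreased element
accessibility coincides with decreased expression for 79.3% of linked,
differentially expressed genes (planted concordance 0.8).

The report directory also contains `inputs/` (the simulated bundle with
its truth tables), `tables/` (per-stage TSVs: differential results, ABC
elements and links, per-site classification, gene-level results) and
`run.log` (config echo, seed, SHA-256 checksums per stage). Identical
config and seed reproduce the directory byte for byte.

Library use mirrors the CLI:

```python
from pioneerlink import StudyConfig, PipelineConfig, run_pipeline
run_pipeline("demo", PipelineConfig(study=StudyConfig(seed=7)))
```

and the individual stages (`pioneerlink.intervals`,
`pioneerlink.differential`, `pioneerlink.abc_model`,
`pioneerlink.classify`, `pioneerlink.simulate`) are importable on their
own; `pioneerlink simulate / diff / abc / classify / report` expose them
from the shell.

## Documentation

`docs/methods.md` describes the statistical models, the generator's
design and its limitations, and every numerical convention (tie-breaks,
pseudocounts, degenerate inputs).
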