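# meiochip

Stage-resolved chromatin and transcriptome profiling of mouse
spermatogenesis: germline stem (GS) cells → pachytene spermatocytes (PS)
→ round spermatids (RS).

During the mitosis-to-meiosis transition the male germline switches on
late spermatogenesis genes and transiently shuts off somatic/progenitor
genes, while the X chromosome undergoes meiotic sex chromosome
inactivation (MSCI) with a small set of escape genes reactivated
postmeiotically. `meiochip` implements the computational side of this
analysis as a tested, reusable library and CLI for people working with
stage-fractionated RNA-seq and ChIP-seq data:

- **Stage classification of genes** from three-stage RPKM tables. A gene
  is called "up" in stage *X* vs *Y* when RPKM_X ≥ 4·RPKM_Y, the
  BH-adjusted p-value of an exact conditional binomial test on the raw
  count pair is ≤ 0.05, and max-stage RPKM ≥ 5; the joint up/down calls
  over the GS/PS, GS/RS and PS/RS comparisons define PS/RS active,
  PS active, RS active and the mirror-image inactive classes.
  Constitutive classes are level-only: active = RPKM > 5 in all stages
  with < 2-fold spread, inactive = RPKM < 3 in all stages. An
  "expressed" filter (RPKM > 3 in ≥ 1 stage) is available separately.
- **ChIP-seq tag-density profiling.** Fragment length is estimated by
  strand cross-correlation (Pearson correlation of plus- vs shifted
  minus-strand 5'-end counts, maximised over 50–500 bp lags); tags are
  shifted by half the fragment length; densities (tags/kb/million) are
  computed in 200-bp windows around TSSs (± 5 kb), as sortable per-gene
  heatmap matrices, as smoothed gene-set average tag density (ATD)
  curves, and as scaled gene-body metagenes (TSS→TES in 60 fractions,
  ± 5 kb flanks in 200-bp bins).
- **Chromosome-stratified statistics.** Chi-square (2×2, df = 1, no
  continuity correction) for X-enrichment of a gene class, and
  two-sided Wilcoxon rank-sum tests on per-gene region read counts
  (e.g. −1 kb from TSS to TES, or ± 500 bp around the TSS) between
  genotypes.
- **A synthetic data generator** that plants all of the above
  structures — stage classes (with an excess of RS-active genes on the
  X), mark-specific spatial enrichment shapes (TSS-focal vs gene-body
  broad vs background), and a fixed fragment-length offset between
  strands — so the entire pipeline is testable offline, with truth
  labels to score against.

## Worked example

```python
from meiochip import (SyntheticSpec, make_annotation, simulate_expression,
                      classify_genes, class_summary, chisq_enrichment)

spec = SyntheticSpec(seed=42)          # 900 autosomal + 100 X-linked genes
genes = make_annotation(spec)
table, truth = simulate_expression(spec, genes)

result = classify_genes(table, genes)
print(class_summary(result, genes))

enr = chisq_enrichment(result, genes, "RS active")
print(f"X-linked RS-active: {enr.x_in_class}/{enr.x_total} = {enr.x_percent} %, "
      f"chi2 = {enr.test.statistic:.1f}, p = {enr.test.p_value:.2g}")
```

prints

```
                         autosomal   X
PS/RS active                   181  17
PS/RS inactive                 147  14
PS active                       34   6
RS active                       19  10
PS inactive                     30  10
RS inactive                     23   3
constitutively active           53   5
constitutively inactive        410  35
unclassified                     3   0
X-linked RS-active: 10/100 = 10.0 %, chi2 = 19.9, p = 8.2e-06
```

The summary table partitions every gene's primary class by chromosome
(Y-linked genes are excluded by convention). Here the generator planted
RS-active status on 10 % of X genes versus 2 % of autosomal genes; the
classifier recovers them and the chi-square test flags the X excess —
the same computation that, on the real data, shows postmeiotic escape
genes concentrated on the X chromosome (10.3 % of X-linked genes).

Continuing with chromatin:

```python
from meiochip import (estimate_fragment_length, shift_tags, ProfileParams,
                      tss_density_matrix, average_profile, smooth_profile)
from meiochip.synthetic import simulate_tags
import numpy as np

tags = simulate_tags(spec, genes, truth, "H3K4me3", "GS")
est = estimate_fragment_length(tags)
params = ProfileParams()
matrix = tss_density_matrix(shift_tags(tags, est.length), genes, params,
                            bin_width=params.step)
atd = smooth_profile(average_profile(matrix, [g.gene_id for g in genes
                                              if not g.is_x]),
                     window_bp=params.window)
print(f"estimated fragment length: {est.length} bp")
print(f"ATD peak at {atd.x_offsets[np.argmax(atd.values)]:+.0f} bp from the TSS")
```

```
estimated fragment length: 182 bp
ATD peak at +25 bp from the TSS
```

H3K4me3 is simulated as a TSS-focal mark, and its smoothed ATD indeed
peaks at the TSS (the +25 bp is the centre of the first 50-bp sampling
bin downstream of it). The fragment estimate is noisy here (planted:
150 bp) because the default promoter-mark placement spread is broad;
see `docs/methods.md`.

## Command line

```
meiochip simulate  --out sim/ --seed 1
meiochip classify  --expression sim/expression.tsv --annotation sim/annotation.bed --out cls/
meiochip fraglen   --tags sim/tags_H3K4me3_GS.bed
meiochip profile   --tags sim/tags_H3K4me3_GS.bed --genes sim/annotation.bed --out atd.tsv
meiochip metagene  --tags sim/tags_H3K4me2_RS.bed --genes sim/annotation.bed --out meta.tsv
meiochip regionstats --tags-a wt.bed --tags-b ko.bed --genes sim/annotation.bed \
                     --region body:-1000 --out counts.tsv
meiochip enrichment --classification cls/classification.tsv --annotation sim/annotation.bed
meiochip run-all   --config config.yaml --out run/
```

`run-all` executes the whole chain from one YAML config and writes a
`manifest.json` of content digests; two runs with the same config and
seed produce byte-identical outputs.

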