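# altiscan

A genome-scan toolkit for detecting the genetic basis of microgeographic
local adaptation along an altitudinal transect. It screens genome-wide SNPs
for unidirectional allele-frequency clines across four altitude-ordered
demes, ranks hitchhiking regions ("genomic islands"), tests GO-term
enrichment of the screened set, and computes resampling-based empirical
p-values for candidate-gene overlap between two independent transects.

The intended users are population geneticists working with individual-based
resequencing of continuously distributed populations on an environmental
gradient — settings where gene flow is high, differentiation is weak, and
classical two-population outlier tests fit poorly.

## The statistics at the core

For each SNP, with focal-allele frequencies F_L, F_M1, F_M2, F_H in the
lowest, lower-middle, higher-middle, and highest demes (the focal allele is
the one maximizing |F_L − F_H|), three indices are computed:

1. **Unidirectionality index**

   U = |F_L − F_H| + (|F_L − F_H| − |F_L − F_M1| − |F_M1 − F_M2| − |F_M2 − F_H|) / 2

   U ∈ [−1, 1]; U = 1 only for a monotone cline spanning the full frequency
   range, 0 for a flat profile, −1 for the maximal zigzag.

2. **Hedrick's standardized G′ST** between the lowest and highest demes:
   G′ST = G_ST (k − 1 + H_S) / ((k − 1)(1 − H_S)) with k = 2 demes, which
   rescales G_ST to its maximum attainable value given within-deme
   diversity.

3. **Derived-allele-frequency increment**
   ΔD′ = |D_H − D_R| (1 − D_R), where the derived allele is the minor
   allele of the pooled low-altitude reference demes, D_R its pooled
   reference frequency (∈ [0, 0.5]) and D_H its frequency in the highest
   deme. The (1 − D_R) factor weights by the probability the allele really
   is derived.

Each index is averaged over a 4-kbp window (2 kbp each side). A SNP is
**screened** when all three windowed indices exceed their genome-wide Tukey
upper fence (Q3 + 1.5·IQR). The windowed-U curve is then segmented into
positive regions bounded by interpolated x-intercepts (terminated at
inter-SNP gaps > 4 kbp); each region's area ranks it, regions with fewer
than two screened SNPs are dropped, and genes overlapping or within 5 kbp
of a screened SNP become candidate genes. GO enrichment uses one-tailed
Fisher 2×2 tests (SNP-based and gene-based units) with Benjamini–Hochberg
q < 0.05. Finally, candidate lists from two transects are compared by
Monte-Carlo resampling from the SNP-tagged gene universe.

A synthetic-data module generates linear stepping-stone transects (4
altitude demes + 4 pooled reference demes) with neutral drift, monotone
clines at selected loci, exponentially decaying hitchhiking, and annotated
genes with a known truth table, so the whole pipeline is testable without
any external download.

## Worked example

```python
from altiscan import (PipelineConfig, SelectedLocus, SimulationConfig,
                      run_scan, simulate_scan_dataset)

cfg = SimulationConfig(n_scaffolds=1, scaffold_length=1_000_000,
                       selected=[SelectedLocus(0, 500_000)], seed=1)
table, design, annot, truth = simulate_scan_dataset(cfg)
res = run_scan(PipelineConfig(seed=1), dataset=(table, design, annot),
               write=False)
```

This simulates one 1-Mbp scaffold (2,088 SNPs at ~484 bp mean spacing) with
a single selected locus at 500 kbp whose allele climbs from frequency 0 in
the lowest deme to 1 in the highest, and runs the full scan. It prints:

```
screened SNPs: 11
fences: {'u_bar': 0.1951, 'gst_bar': 0.2251, 'ddprime_bar': 0.1959}
top island: scaffold_1 [490001, 515164] area=4026.3 screened=10
candidate genes: ['scaffold_1_g0099', 'scaffold_1_g0100',
                  'scaffold_1_g0101', 'scaffold_1_g0102']
```

Eleven SNPs exceed all three fences; ten of them fall in the rank-1 island,
a ~25-kbp positive stretch of the windowed-U curve straddling the selected
locus, and its candidate genes are exactly the tiles around 500 kbp. The
SNP-based GO enrichment flags the two terms planted near the selected locus
(fold enrichment 4.4 and 3.7, q < 10⁻⁵) and nothing else.

The same stages are available from a shell:

```bash
altiscan simulate --out-dir demo --scaffolds 1 --scaffold-length 100000 \
    --seed 2 --selected 0:50000
altiscan stats   --vcf demo/genotypes.vcf --popmap demo/popmap.tsv --out demo/stats.tsv
altiscan screen  --stats demo/stats.tsv --bed demo/exons.bed --out demo/screened.tsv
altiscan islands --screened demo/screened.tsv --out demo/islands.tsv
altiscan overlap-p --universe 22395 --n1 38 --n2 32 --observed 2 --seed 7
```

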