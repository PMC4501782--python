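# Methods

## The scan model

The pipeline targets a sampling design of four altitude-ordered demes
(lowest L, lower-middle M1, higher-middle M2, highest H; 5 diploids each)
along one mountain transect, plus several low-altitude reference demes
(4 demes × 4 diploids by default) whose allele counts are pooled into a
single reference group. Population structure is assumed to approximate a
linear stepping-stone: gene flow connects altitude neighbors, so neutral
allele frequencies drift coherently along the transect while an allele
under altitude-dependent selection develops a monotone frequency cline.

Three per-SNP indices capture that signature:

* **U** rewards a large L-vs-H frequency difference achieved monotonically.
  With d = |F_L − F_H| and s the sum of the three neighbor steps,
  U = d + (d − s)/2. Since s ≥ d (triangle inequality), U ≤ d, with
  equality exactly when the profile is monotone; the range is [−1, 1].
  A flag (`halved=True`) exposes the alternative algebraic reading that
  divides the entire expression by 2 (range [−0.5, 0.5]); the default is
  the reading consistent with the documented [−1, 1] range.
* **G′ST** (Hedrick 2005) between L and H, k = 2: H_S is the unweighted
  mean of the two expected heterozygosities, H_T uses the unweighted mean
  frequency vector, and G_ST = (H_T − H_S)/H_T is divided by its maximum
  (k − 1)(1 − H_S)/(k − 1 + H_S). No small-sample (Nei–Chesser) correction
  is applied. H_T = 0 (both demes fixed for the same allele) returns 0.
* **ΔD′** = |D_H − D_R|(1 − D_R). The derived allele is the minor allele
  of the pooled reference group (ties to the lower allele index), so
  D_R ∈ [0, 0.5] at biallelic loci. At tri/tetra-allelic loci the derived
  frequency is 1 − (major-allele frequency), computed separately in the
  reference pool and in H. That multiallelic rule can exceed 0.5 when no
  reference allele holds a majority; the scalar operation therefore guards
  D_R ≤ 0.5 by default and the pipeline calls it with the guard relaxed to
  [0, 1], where the formula stays within [0, 1].

Reference pooling is by chromosome counts (sample-size weighted): allele
counts are summed over reference demes before dividing.

### Windowing, screening, islands

Each index is averaged over all SNPs within ±2 kbp of the focal SNP
(4-kbp window, focal included, membership inclusive at the boundary).
Windows never cross scaffold boundaries; at scaffold edges the window
simply shrinks (no padding). Screening thresholds are genome-wide Tukey
upper fences, Q3 + 1.5·IQR, with quartiles by linear interpolation
(numpy's default, type 7); the comparison at the fence is strict ">"
(configurable). Only SNPs exceeding all three fences are screened.

Island segmentation connects consecutive same-scaffold SNPs by straight
lines unless they are more than 4 kbp apart; maximal stretches with
windowed U > 0 form islands. Boundaries are linearly interpolated
x-intercepts; a SNP with windowed U exactly 0 terminates an island as a
boundary point, not a member. At a gap break the island ends at the last
observed SNP (no extrapolation into unobserved sequence), so a single
isolated positive SNP yields a degenerate zero-width island that can never
survive the ≥2-screened-SNP filter. Area is the trapezoid integral of the
positive piecewise-linear curve in bp·U units; only relative order matters,
so no normalization is applied. Ranking is by area descending, ties broken
by (scaffold, start). Candidate genes of an island are the union of genes
linked to its screened member SNPs; a SNP links to a gene when it overlaps
an exon or lies within 5 kbp of one (inclusive at exactly 5,000 bp; SNP
positions 1-based, exons 0-based half-open, converted once at this
boundary). The sliding profile reports mean |F_deme − F_L| per 4-kbp
window at 1-kbp steps; the absolute difference is used (configurable
consumers can re-sign it), since the quantity of interest is the magnitude
of the cline relative to the lowest deme.

### Enrichment

Units are gene-linked SNPs (SNP-based mode; a SNP carries a term if any
linked gene does, counted once regardless of how many linked genes carry
it) or SNP-tagged genes (gene-based mode; a gene is screened if ≥1
screened SNP links to it). The 2×2 table is screened vs not-screened
against term vs no-term — disjoint categories, so counts partition the
unit set; the "expected" ratio under the null is then the background term
fraction, and fold enrichment is (screened term fraction)/(overall term
fraction). The one-tailed Fisher p is the upper hypergeometric tail.
Multiple testing uses Benjamini–Hochberg across the requested terms
(typically a curated list of ~30 flat labels; no GO-graph propagation),
significance at q < 0.05. Storey-type π₀ estimation is deliberately not
used: with ~30 tests it is unstable.

### Resampling tests

Both empirical p-values draw two gene lists (sizes n1, n2) uniformly
without replacement from the N SNP-tagged genes, one million trials. The
shared-gene statistic of one trial — |list1 ∩ list2| — depends only on
sizes, and conditioning on list1 and relabeling genes shows it is exactly
Hypergeometric(N, n1, n2); likewise the number of tagged genes in a list
is Hypergeometric(N, m, n). Each trial therefore draws from numpy's
hypergeometric generator directly (one draw for the shared test, two
independent draws for the GO-count test) — the same process the
list-sampling procedure defines, vectorized. The events are "at least"
tails: P(overlap ≥ k) and P(T1 ≥ k1 and T2 ≥ k2). Exact tail probabilities
(scipy hypergeometric survival functions, and their product for the
independent joint event) are always computed alongside as a cross-check;
the Monte-Carlo standard error sqrt(p(1−p)/trials) is reported. With the
default universe of 22,395 SNP-tagged genes and list sizes 38 and 32, the
exact tails are 0.001 (overlap ≥ 2) and 0.007 (≥4 and ≥3 of 863 tagged
genes) at three decimals; a 23,395-gene universe yields 0.006 for the
GO-count test, so the universe size materially affects the third decimal.

## Synthetic data

The generator emulates: SNP positions with exponential spacing (mean
484 bp, matching genome-wide inter-SNP spacing of a medium-coverage
resequencing panel); neutral frequencies from a Balding–Nichols chain —
ancestral p0 ~ Uniform(0.05, 0.95), deme L ~ Beta around p0 with
divergence F (default 0.05, placing neutral pairwise G′ST in the few-percent
range typical of adjacent transect demes), each subsequent deme drawn
around its neighbor with divergence F(1 − ρ) so that ρ (default 0.8)
controls neighbor correlation; reference demes drawn independently around
p0 with divergence F, mimicking spatially separate low-altitude
populations. A selected locus imposes the exact linear cline F_L*..F_H*
across the four demes and F_L* in the references; every other locus on the
scaffold is pulled toward the cline with weight w = exp(−d/λ)
(λ default 2 kbp), the distance-decay proxy for hitchhiking. Genotypes are
two binomial draws per individual from the deme frequency vector; read
depths are negative binomial (mean 20, dispersion 10). A configurable
fraction (default 1.6%, the observed tri-allelic share of a ~527k-SNP
panel) of neutral loci carries a third allele splitting the background
share. Genes are tiled every 5 kbp with two exons; two GO terms are
planted at high probability (0.9 vs background 0.1) on genes within 10 kbp
of a selected locus, giving the enrichment stage a known positive set.

What the generator does **not** emulate: linkage disequilibrium from real
recombination (hitchhiking is imposed on expected frequencies, not
haplotypes), missing genotypes, sequencing error, allele-specific depth
biases, and spatially autocorrelated sampling within demes. Passing tests
therefore demonstrate that the statistics and screening recover the
planted structure under the assumed frequency model — not that the scan is
robust to artifacts of real short-read data.

Default desk scale is 4 scaffolds × 250 kbp (~2,000 loci); the parameter-
recovery study uses one 1-Mbp scaffold (~2,100 loci) carrying one selected
locus, 20 replicate seeds — sizes chosen so the full study runs in seconds
while every stage still has enough loci for stable genome-wide fences.

## Numerical and design choices

* Quantiles: numpy linear interpolation (type 7), documented because
  quartile conventions move fences.
* Ties: focal-allele selection and minor-allele identification break to the
  lowest allele index; island area ties order by (scaffold, start).
* Frequencies are stored in a NaN-padded (groups × loci × 4) array; all
  reductions use NaN-aware sums over the allele axis.
* The locus filters run in fixed order (per-individual depth, total depth,
  second-allele fraction) and record only the first failing reason. The
  read-level "antagonistic allele > 20%" calling rule is re-expressed at
  the genotype level as: frequency of the second-most-frequent allele among
  called chromosomes strictly > 0.20; a zero threshold disables the rule so
  the null config is an identity filter.
* Monte-Carlo seeds feed numpy `default_rng`; the acceptance script derives
  independent child seeds (< 2³¹) from the user seed via `SeedSequence`.
* End-to-end determinism: identical config + inputs give byte-identical
  output tables; output tables carry a provenance header (version, config
  hash excluding the output directory, seed).

## Known limitations

* The screen assumes exactly four altitude demes; designs with more levels
  would need a generalized U.
* Windowed means weight all SNPs equally; dense local clusters dominate a
  window.
* The multilocus pairwise G′ST aggregates H_S/H_T across loci before
  standardizing — an interpretation, since mean-of-loci is also seen in the
  literature.
* Empirical p-values below ~1/trials are reported as 0 at three decimals;
  the exact tails should be quoted alongside in that regime.
* The enrichment background is the disjoint not-screened set. With screened
  fractions around 1% this is numerically indistinguishable from using the
  full dataset as background; both constructions are noted here because the
  choice matters when the screened fraction is large.
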