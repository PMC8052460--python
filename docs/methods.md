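# Methods

This note documents the statistical models, numerical choices and known
limitations behind `tetrasnp`. Everything stated here is computed by the
package itself; the test suite and `scripts/acceptance.py` exercise each
claim.

## Dosage model and orientation

A tetraploid SNP call is the count of the array's B (alternate) allele,
0–4; after diploidization the codes are 0/1/2 with all three heterozygous
tetraploid classes collapsing to 1. The B orientation is a convention, not
a statement about ancestral state: every statistic in the package is either
invariant to a global allele flip (He, PIC, MAF, Nei distance, Fst, the G
matrix) or documents its polarity caveat (iHS treats B as the "derived"
proxy on array data; on simulated panels polarity is known by
construction).

Partially missing VCF genotypes (e.g. `0/0/./1`) are treated as fully
missing — dosage is never imputed from a subset of the four alleles.

## Marker filtering

Filtering is two-stage and order matters for the bookkeeping: markers with
MAF < 0.05 (monomorphic included) are removed first; among survivors,
markers with ≥ 10% missing calls are removed. The ≥ boundary is enforced by
integer-count comparison (`n_missing < threshold · n_clones` keeps a
marker), so a marker at exactly the threshold is removed without
floating-point surprises. Both thresholds are arguments.

## Ploidy screening

Simplex (AAAB) and triplex (ABBB) genotypes are impossible in a diploid, so
the combined frequency *s* of those classes over a clone's non-missing
markers separates ploidies: *s* < 0.05 → diploid, *s* > 0.20 → tetraploid,
otherwise ambiguous. For a genuine tetraploid with allele frequencies in
[0.05, 0.5] the expected *s* is far above 0.20 (≈ 0.60 at p = 0.3), so the
ambiguous band is rarely hit in practice; both cutoffs are configurable
because "close to zero" is a judgment about assay noise, not biology.

## Diversity statistics

Marker statistics use pooled allele frequencies (Σ dosage / 4n). He = 2pq
and the biallelic PIC = 1 − (p²+q²) − 2p²q² satisfy PIC ≤ He ≤ 2·MAF with
equality only at the frequency boundaries; these inequalities are property
tests. The clone-level inbreeding coefficient is defined as
F = 1 − Ho/He̅ against the panel mean expected heterozygosity, which makes
the identity mean(F) = 1 − mean(Ho)/He̅ exact.

Sequence diversity treats each clone's diploidized genotype as one
sequence. At a site with m non-missing clones (2m alleles) and frequency
p̂, the site diversity is 2p̂(1−p̂)·2m/(2m−1); the small-sample factor is
switchable (`small_sample_correction`) because genotype-table tools differ
on it. π averages over all assayed sites, including sites fixed after
filtering; S counts segregating sites among them. Watterson's θ_W =
S/(a₁L) evaluates the harmonic number a₁ at the *harmonic-mean* per-site
sample size (via the digamma continuation for non-integer n), which under
complete data is exactly the textbook a₁ at n sequences: with every site
segregating and no missing data, θ_W = 1/H₍ₙ₋₁₎ (= 0.1683 at n = 214).
Tajima's D uses the standard a/b/c/e variance terms at the same effective
n, is reported as missing when S < 3, and is centred near zero on panels
generated from the neutral 1/i site-frequency spectrum
(`simulate_neutral_sites`), which is the generator's definition of
"π forced equal to θ".

Note that heterozygous diploid calls contribute within-genotype allele
differences: two clones with identical genotype rows containing
heterozygotes have π > 0 by construction. Only identical homozygous-coded
sequences give π = 0.

## Distance, trees and curation

Nei's (1972) standard distance is computed per pair on x = dosage/4 with
pairwise deletion of missing loci; tiny negative values from rounding are
clamped to 0, and a pair sharing no loci is reported missing.

R's hclust distinguishes `ward.D` (Lance–Williams update on the distances
as given) from `ward.D2` (on squared distances). SciPy's `ward` on a
precomputed distance matrix implements the D2 dialect, so the classical
ward.D tree is obtained by running SciPy on √d and squaring the merge
heights; both variants are exposed and ward.D is the default. Dendrograms
are serialized as newick with branch lengths derived from merge heights.

Duplicates are pairs below a Nei distance of 0.001 ("almost zero"; the
later-listed clone is the flagged one). Mislabel candidates are clones
whose declared market class is *rare* (< 15%) within their 3-cluster tree
group while *common* (≥ 25%) in another group. A plain
majority-disagreement rule was rejected: genetic clusters legitimately mix
market classes (a chip-and-russet cluster is roughly half of each), and
majority voting would flag half the collection. The rare-but-common-
elsewhere pattern is exactly what a recording error between classes
produces.

## Cluster number, DAPC and Fst

The cluster scan runs K-means (25 seeded k-means++ restarts) on the
retained PC scores of the centered, mean-imputed, diploidized matrix for
K = 1..k_max and scores BIC(K) = n·ln(WSS_K/n) + K·ln(n); the minimum BIC
wins with ties broken toward smaller K. On low-differentiation panels the
BIC curve is nearly flat around the optimum, so neighboring K values can
trade places within noise; at pairwise Fst ≥ 0.1 and realistic sample
sizes the simulated K is recovered with ≥ 95% assignment accuracy (an
acceptance test).

DAPC fits LDA on the retained PCs with an overfit guard
(n_pca < n − groups); memberships are the discriminant-space Gaussian
posteriors (rows sum to 1 within 1e−9) and marker loadings are the PC
rotation times the LDA scalings. Cross-validation chooses n_pca by
stratified holdout (default 10%) minimizing the RMSE of the holdout error
rate, ties toward fewer PCs; single-member groups are pinned to training.
The discriminating-marker step splits the absolute loadings of one axis
into two Ward groups and returns the high-loading group, warning and
returning nothing when the loadings are flat.

Pairwise Fst is the Weir–Cockerham-type estimator on allele counts (4 per
tetraploid clone): per marker MSP and MSG from group frequencies and
sample sizes, combined across markers as a ratio of sums. No
polysomic-specific correction is applied. Recovery within ±0.03 of the
Balding–Nichols truth at F ∈ {0.02, 0.10, 0.15} is an acceptance test.

## Selection scans

The PCA-outlier scan standardizes markers, regresses each on K orthonormal
PC axes, takes the Mahalanobis distance of the z-score vectors
(pseudo-inverse covariance), rescales by λ_GC = median(D²)/median(χ²_K)
and converts to χ²_K p-values. On null panels λ_GC is calibrated to
[0.8, 1.2] (checked over 20 replicates at 200 × 2,000). Optional greedy LD
clumping (r² threshold within a marker window) thins the set used for PC
estimation.

EHH at a focal marker is the probability that two random carrier
haplotypes are identical over the closed interval from the focal marker to
x; with the whole sample as carriers (the XP-EHH mode) the focal value is
therefore the focal-site homozygosity, not 1. Curves extend until EHH
< 0.05 or the chromosome end, and iES is the trapezoid integral over
physical distance. iHS = ln(iES_ancestral/iES_derived) is standardized
within 20 equal-width derived-frequency bins (bins under 10 markers merged
with neighbors); XP-EHH is standardized genome-wide. Two-sided normal
p-values feed Storey–Tibshirani q-values (π0 from a cubic-smoother λ-grid,
forced to 1 below 100 tests). Consensus sweep regions are top SNP
± 250 kb for markers significant in ≥ 2 statistics (iHS/XP-EHH at FDR
0.01, PCA-outlier at q < 0.05); overlapping regions from distinct top SNPs
are deliberately not merged. Gene lookup intersects the further ± 250 kb
padded interval, closed on both ends, against GFF3 `gene` features.

Sweep detection power is assessed at the *region* level: a sweep is
detected when some marker within the decay window of the planted locus
reaches the chromosome-wide top 1% of |z|. The planted locus itself is
frequently out-scored by its own flanking markers, whose haplotype
structure is genuinely distorted by the copying construction — EHH
statistics localize regions, not single SNPs, which is why consensus
output is region-shaped. Measured power over 20 replicates at the default
sweep settings: 1.0 (iHS) and 0.85 (XP-EHH).

## Core selection

The objective is the mean entry-to-nearest-entry distance of the selected
subset. Search is first-improvement single-swap local search from 10
seeded random starts; each accepted swap strictly increases the objective,
so the ascent property holds by construction, and on 10-clone instances
the search attains the exhaustively enumerated optimum. Core size is
round-half-up of fraction × n (0.20 × 214 → 43). Duplicate pairs are never
jointly kept when avoidable because their mutual distance of zero is
maximally penalized. Pipeline ordering: duplicates and mislabel candidates
are removed before core selection.

## Pedigree verification

The A matrix uses the tabular method in topological order (cycle-checked);
unknown parents contribute zero, so founders are non-inbred. It matches
Monte-Carlo gene-dropping estimates within ±0.01 at 10⁵ drops.

G normalizes centered dosages by Σ4p̂q̂ with panel allele frequencies and
pairwise missing-data exclusion (both sums restricted to shared markers).
Under this normalization G_ii ≈ 1 under HWE and parent–offspring pairs sit
near 0.5 — but conditionally on a specific parent, E[G_po] = G_pp/2, so
single-pair values inherit the parent's own sampling fluctuation (SD
≈ 0.05 at 2,000 markers), and panel-frequency estimation shrinks related
pairs by O(1/n). Tests therefore average over parent pairs and use panels
of ≥ 150 clones. The A-vs-G regression slope over a simulated
three-generation pedigree is 1 ± 0.1.

The trio conflict metric counts markers where both recorded parents are
monomorphic (dosage 0 or 4) and all three calls are present; the forced
offspring dosage is the sum of obligate gamete dosages (0×0→0, 0×4→2,
4×4→4), and a 0×4 duplex offspring is *not* a conflict. "Different" means
different from the forced value. An error-free offspring of its true
parents scores exactly 0% by Mendelian arithmetic; trios under 1% are
labeled accurate (configurable allowance for genotyping error). Markers
with any missing call in the trio are excluded, not imputed. Single-parent
verdicts require the putative parent's G within the parent band
(≥ 0.5 − 0.15) and above every A-unrelated clone's G, and report the
opposing-homozygote rate (parent 0 with offspring 4 or vice versa),
which is 0 under true parentage without genotyping error.

## Synthetic data

The structured-population generator is Balding–Nichols: ancestral
frequencies uniform on the configured MAF range (default [0.05, 0.5]),
subpopulation k frequencies Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) (exactly
ancestral at F_k = 0), clone dosages Binomial(4, p_k), uniform random
missingness, markers placed uniformly on 12 chromosomes of 73 Mb (which
reproduces a ~71 kb mean marker spacing at 10⁴ markers). Defaults emulate
a mid-size breeding collection: subpopulation sizes (94, 18, 102), 10⁴
markers, per-subpopulation drift (0.03, 0.22, 0.05) — a small, strongly
drifted strain group against two weakly differentiated large groups,
spanning roughly 0.04–0.14 pairwise Fst — 5% missing calls, and injected
anomalies at the scale a real collection shows: 2 duplicates, 5 market-
class mislabels, 1 diploid clone.

Crosses draw each gamete's dosage as Hypergeometric(4, d, 2) — two of the
four chromatids without replacement — independently per marker. Double
reduction is excluded (rates in potato are low; the simplification makes
the trio-conflict zero guarantee exact).

Sweep panels place neutral haplotypes as marker-wise independent draws at
derived frequencies uniform on [0.05, 0.95] — array alleles carry no true
polarity, so a full-range derived spectrum is the realistic condition and
gives every standardization bin neutral members. All carriers of the
planted derived allele copy one founder haplotype outward from the locus,
switching out permanently per step with probability 1 − exp(−gap/decay)
(decay default 2 Mb) and copying each marker with fidelity `homogeneity`
(default 0.9). In the infinite-decay, fidelity-1 limit carriers are
identical chromosome-wide.

What the generator does **not** emulate: background LD between neutral
markers (each is independent), realistic recombination maps or coalescent
genealogies, genotyping error outside the duplicate-copy option, and
ascertainment bias of array marker selection. Passing tests therefore
demonstrate correctness of the estimators under their stated models, not
robustness to array ascertainment or LD structure in real panels.

## Problem sizes

Statistical checks run at sizes chosen to make their tolerances
meaningful on one CPU: Fst and λ_GC at 200 clones × 2,000 markers,
K-recovery at 200 × 2,000, sweep power at 120 haplotypes × 400 markers
over 20 replicates, oracle equivalences at enumerable sizes (≤ 8
sequences, ≤ 16 haplotypes, all C(10,4) subsets).
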