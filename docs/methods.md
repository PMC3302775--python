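# Methods

This note documents the models, estimators, numerical choices and
limitations behind `dartpop`, and what the synthetic-data generator
does and does not emulate.

## Data model

Accessions are inbred lines treated as homozygous, so a dominant marker
call (band presence/absence) is a single haploid allele and allele
frequency equals presence frequency among non-missing calls. Missing
data are first-class: `NA`, `N`, `-` and empty cells parse as missing
and are never coerced to absence. Multi-allelic (SSR/RFLP-like) data
are haploid-coded as one allele label per cell; heterozygotes are
assumed to have been resolved upstream by randomly sampling one allele.

Marker filtering is applied per analysis: structure-type analyses keep
markers with missing fraction strictly below 0.10, LD analyses strictly
below 0.20 plus MAF ≥ 0.05 (rare alleles inflate the variance of r²).
The missing-data rule is deliberately strict ("less than" the
threshold) while the MAF rule is inclusive ("at least"); `filter_markers`
is idempotent.

Native STRUCTURE report (`_f`) files are not parsed. To convert one,
extract the ancestry block into a plain CSV, e.g.:

```bash
awk '/Inferred ancestry/,/^$/' run_f | tail -n +3 | \
  awk '{printf "%s", $2; for(i=6;i<=NF;i++) printf ",%s", $i; print ""}' > q.csv
```

then prepend a header line (`accession,Q1,...,QK`).

## Diversity

Gene diversity He = 1 − Σₐ pₐ² uses the plain estimator (PowerMarker's
gene-diversity default); an unbiased n/(n−1) correction is available
behind a flag but off by default. The reported statistic is the mean
over loci; its SD comes from 1000 bootstrap resamples **of loci** (the
statistic is a mean over loci, so that is the resampling unit).

Rarefied allelic richness is the exact hypergeometric expectation
Σₐ [1 − C(N−Nₐ, g)/C(N, g)]; private allelic richness multiplies the
probability an allele appears in the focal group's g-gene subsample by
the probability it is missed by every other group. The rarefaction size
g defaults to the smallest group's gene count so groups are compared at
an equal standardized sample size. Both quantities are verified in the
test suite against exhaustive enumeration (N ≤ 12) and Monte-Carlo
subsampling (10⁵ draws) oracles.

Dissimilarities: simple matching (Sokal & Michener)
d = 1 − matches/comparable on band data or allele labels, and Dice
d = 1 − 2a/(2a+b+c) on band data. Missing calls are deleted pairwise;
the degenerate no-discordance case (b = c = 0, including all-absent
profiles) is defined as d = 0 so the two indices agree there. A pair
with no comparable marker yields a missing entry plus a warning.

## Ancestry concordance

Group assignment takes argmaxₖ q_ik iff that membership is **strictly**
greater than the threshold (default 0.6); otherwise the accession is
unassigned. The dissimilarity of ancestry between two runs is
D_i = ½ Σₖ |q_ik − q′_ik|, identical to 1 − Σₖ min(q_ik, q′_ik) for
probability rows — the ½-L1 normalization keeps D_i ≤ 1. In thresholded
mode rows are first one-hot encoded over K+1 categories (K groups +
unassigned), so assigned-vs-unassigned disagreement scores 1 and the
panel average equals the misassignment fraction.

Cluster labels are always aligned before comparing (and the permutation
is reported): the objective Σᵢ Σₖ min(q_ref,ik, q_i,σ(k)) is a sum of
per-column scores, so the assignment problem
(`scipy.optimize.linear_sum_assignment`) yields the exact optimal
permutation for any K — an exhaustive search over permutations would
return the same σ, so none is needed.

The data-resolution statistic samples m markers without replacement,
splits them into two disjoint halves, builds one dissimilarity matrix
per half and correlates the two over unordered accession pairs
(optionally only intra- or inter-group pairs at the membership
threshold); plain Pearson on the vectorized off-diagonals, no Mantel
permutation, since only the coefficient is of interest. Defaults:
1000 replicates per m, marker-number step 50 for large dominant panels
(2 for small multi-allelic sets).

## Trees and MLST core sampling

Neighbour-Joining uses the Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion. Numerical conventions: negative branch
lengths at a join are clamped to zero with the deficit transferred to
the sister branch (path length between the joined nodes is preserved);
Q-criterion ties break by lexicographic order of the sorted label pair,
so topologies are deterministic. The implementation is cross-checked in
the tests against scikit-bio's NJ on additive matrices, where NJ is
exact.

MLST (Maximum Length SubTree) redundancy removal: until the requested
core size is reached, rebuild the NJ tree on the current subset, find
the pair with the smallest **input-matrix** dissimilarity (the matrix is
the primary data; the tree only supplies terminal edge lengths), and
remove whichever member has the shorter terminal branch. Distance ties
break by lexicographic pair, edge-length ties remove the
lexicographically smaller id. The tree is recomputed after every
removal rather than pruned — at panel sizes of a few hundred this is
sub-second per step and avoids any dependence on pruning order. Because
removals are nested, one run down to the smallest size yields the core
of every intermediate size. Reference implementations of this
procedure may break ties differently; results can differ from them on
tied inputs.

## Linkage disequilibrium

Haploid complete-case counting (accessions non-missing at both markers)
gives two-locus haplotype frequencies directly; no EM phase estimation
is needed. D = p_AB − p_A p_B, r² = D²/(p_A q_A p_B q_B), D′ = |D|/D_max
with D_max = min(p_A q_B, q_A p_B) for D > 0 and min(p_A p_B, q_A q_B)
otherwise. Pairs monomorphic in their complete-case subset are skipped
and counted.

Distance classes are left-open right-closed — (0,10 kb], (10,50 kb],
(50,100 kb], (100 kb,1 Mb], (1,10 Mb], (10,100 Mb] — so every linked
pair lands in exactly one class; inter-chromosomal pairs form their own
class. The P95 background threshold is the 95th percentile (linear
interpolation between order statistics; no convention is canonical, so
the numpy default is used) of r² over inter-chromosomal pairs only, and
"significant LD" means r² strictly greater than P95.

The decay fit regresses r² on E(r²) = 1/(1 + 4·a·d) over linked pairs
(nonlinear least squares; a initialized by a log-spaced grid over
1e-8…1e-2 and refined by Levenberg–Marquardt in log10 a, which keeps
a > 0). The fit is declared failed — with the best grid value attached —
when the fitted curve cannot beat the best constant fit, which covers
distance-free r² exactly and avoids reporting a meaningless boundary
value. Note the model forces r² → 1 as d → 0 and r² → 0 at long range;
on panels whose short-range LD is capped well below 1 and whose
long-range LD plateaus at a structural background (including the
default synthetic panels here), the hyperbola can be genuinely
unsupported and the failure is the correct answer. Marker requirements
invert the fitted curve: d* = (1/r² − 1)/(4a), n = G/d*, reported
unrounded and as a ceiling; n grows with both a and the r² threshold
(the decay *distance* is what shrinks).

Sampling experiments draw accession subsets per size either at random
(independent replicates, mean ± SD of each statistic) or as the
deterministic MLST core, then recompute the full LD table, P95,
distance-class summary and the Pearson correlation between subset and
full-panel r² over shared pairs.

## Differentiation and outlier scan

Weir–Cockerham θ for haploid samples, per locus: with r groups, sizes
nᵢ and frequencies pᵢ,

    p̄   = Σ nᵢ pᵢ / Σ nᵢ
    MSP = Σ nᵢ (pᵢ − p̄)² / (r − 1)
    MSG = Σ nᵢ pᵢ (1 − pᵢ) / Σ (nᵢ − 1)
    n_c = (Σ nᵢ − Σ nᵢ²/Σ nᵢ) / (r − 1)
    θ   = (MSP − MSG) / (MSP + (n_c − 1) MSG)

Multi-locus and pairwise-group values are ratios of numerator and
denominator components summed over loci (and over allele indicators for
multi-allelic input). Loci monomorphic across the included accessions
are excluded from the sums; unassigned accessions are excluded
throughout. Significance uses label permutations over accessions with
p = (1 + #{θ_perm ≥ θ_obs})/(1 + n_perm), default 1000 permutations.

The neutral envelope replaces a coalescent island simulation with its
moment-matched desk-scale equivalent: per locus, an ancestral frequency
p0 ~ U(0.01, 0.99), deme frequencies from the Balding–Nichols beta
Beta(p0(1−F)/F, (1−p0)(1−F)/F) — first two moments identical to the
island model at differentiation F — and binomial sampling of 50 haploid
genomes per deme ("50 individuals" read as 50 haploids, since the data
are haploid-coded), then the same θ estimator as for the observed data.
The divergence F is calibrated by bisection until the mean simulated θ
is within ±0.005 of the target; the target is the 5%-trimmed mean of
the observed per-locus θ, a robustification standing in for iterative
outlier exclusion (all loci, including true outliers, otherwise enter
the neutral yardstick — a known weakness of this family of methods).
Each bisection evaluation re-simulates the full cloud from the same
seed, so the envelope is deterministic given (seed, config). Simulated
loci are split into 20 equal-count He bins; a locus is called
diversifying above its bin's 1−tail quantile and balancing below the
tail quantile (tail 0.01 ≈ a 99% interval, configurable), and the
reported quantile position is the fraction of simulated loci in the bin
with θ below the observed value. Out-of-range He clamps to the nearest
bin. The number of demes defaults to the number of observed groups and
is exposed because finite- vs infinite-island readings differ only
through it.

## Synthetic-data generator

Defaults are the study conditions the package is exercised under: 6
groups of unequal sizes (38, 28, 22, 10, 15, 24 — 137 accessions),
1100 markers uniformly placed on 10 chromosomes of 73.6 Mb (736 Mb
genome), target Fst 0.4, H = 10 founder haplotypes per group, founder
switch rate c = 2e-6 per bp, ancestral MAF floor 0.05, 10% missing
calls.

Mechanics: per locus, p0 ~ U(maf_floor, 1−maf_floor) and group
frequencies from the Balding–Nichols beta at the target F. Founder
haplotype f of group k carries allele 1 at marker j iff u_fj < p_kj,
with the uniforms u_fj **shared across groups**: marginally each
founder allele is Bernoulli(p_k), jointly the founders act as ancestral
lineages common to all groups whose fixation probabilities drifted
apart. This coupling matters: with independent per-group founder draws
the within-group drift LD has random sign per group and cancels when
pooled over a strongly structured panel, leaving no distance-decaying
signal at all — whereas real germplasm shares haplotypes by descent, so
short-range LD survives pooling. Each accession chromosome is then a
mosaic of its group's founders with Poisson(c per bp) switch points
(each switch redraws a founder uniformly), giving LD that decays on the
scale 1/c ≈ 0.5 Mb towards the structure-driven background, and missing
calls are injected completely at random.

Parameter choices, made once while designing the generator: H = 10
keeps the realized mean per-locus θ at 0.41–0.44 across seeds for
target 0.4 (the founder bottleneck adds a little drift on top of
Balding–Nichols; the lineage coupling damps most of it) while leaving
the short-range r² visibly above the background (≈0.05 vs ≈0.04 at
default marker density). c = 2e-6 puts the decay scale near 0.5 Mb so
the statistic stabilizes beyond ~1 Mb, matching the qualitative picture
in worldwide cereal panels.

What the generator does **not** emulate: migration and admixture
(groups are discrete; truth Q-matrices are one-hot), demographic growth,
selection acting along extended haplotypes (spiked outliers regenerate
single loci), genotyping error structure beyond MCAR missingness, and a
realistic site-frequency spectrum (the ancestral frequency is uniform
above the MAF floor). Short-range r² is capped near 1/H rather than
approaching 1, so the hyperbolic decay fit is only well-supported on
configs with small founder pools; passing tests therefore demonstrate
correct estimator behaviour and qualitative reproduction of
sample-composition effects, not calibration of the generator to any
particular empirical decay constant.

Replicate Q-matrices draw row i from Dirichlet(conc·q_i + 1e-6) (the
epsilon keeps concentrations positive) with an optional whole-run label
permutation to mimic label switching. Spiked loci overwrite group
frequencies — alternating 0.99/0.01 for diversifying (locus-level
divergence ≈ 0.96), all 0.5 for balancing — while preserving the
locus's missingness pattern.

## Problem sizes used in the tests

The test-bench panels are scaled down from the defaults so the suite
runs in minutes: the sample-composition experiments use 137 accessions
with 400 markers on 10 × 2 Mb chromosomes (denser spacing populates
every distance class); the outlier operating-characteristics runs use
6 × 50 accessions with H = 50 founders — the founder pool matched to
the envelope's 50-haploid deme sampling — and 1000 loci with a
20,000-locus envelope; decay-fit recovery uses 1000–2000 synthetic
pairs. On default panels with H = 10, locus-level θ is overdispersed
relative to the binomial envelope (the founder bottleneck is not part
of the neutral model), so the scan's empirical false-positive rate is
nominal only when deme sampling and founder drift are matched, as in
the matched configuration above; on mismatched panels the envelope is
conservative in the mean but not in the tails. This mirrors the
behaviour of island-model scans on real data whose demography departs
from the island assumptions.

## Pipeline

`run_pipeline` derives one seed per stage from the master seed (SHA-1 of
`"{seed}:{stage}"`, reduced mod 2³¹), stamps every output with a hash of
the analysis-relevant configuration, records per-stage counts in
`run_report.json`, aborts with a stage-named error on failure (partial
outputs are kept), and is byte-identical across repeat runs of the same
configuration.
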