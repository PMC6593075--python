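# Methods

This note documents the models, estimators and numerical choices behind
`sibriver`, and what the synthetic data generator does and does not
emulate.

## The problem setting

Founders of aquaculture breeding programs are often obtained as fertilized
spawn from rivers. Because highly fecund fish spawn in aggregations, a
spawn collection taken at one place and time can over-represent the
progeny of very few parents, so a nominally wild founder set hides full-
and half-sib structure. That structure biases allele-frequency-based
inference (heterozygosity, FST, clustering), deflates apparent diversity,
and — if ignored in a closed breeding population — accelerates inbreeding.
The pipeline estimates the hidden sibship from SNP genotypes, rebuilds a
dummy-parent pedigree, extracts a pairwise-unrelated founder subset for
population-genetic summaries, and projects the inbreeding consequences.

## Genotype coding

Calls are reference-allele counts, 0/1/2 with −1 for missing, project-wide.
The −1/0/1 coding of the genomic relationship matrix is an internal
transform. All frequency computations use observed calls only.

## SNP quality control

Fixed cascade, in order:

1. **MAF / call rate.** Loci with observed MAF ≤ 0.05 or missingness
   ≥ 0.05 are excluded (boundaries excluded; an all-missing locus is
   removed by the missingness rule). Boundary comparisons carry a 1e-9
   float guard so count-exact boundaries (e.g. MAF 1/20) behave as
   written.
2. **Fragment de-duplication.** Genotyping-by-sequencing fragments can
   carry several SNPs that are near-perfect proxies; one SNP per fragment
   is retained uniformly at random (seeded).
3. **LD pruning.** Pairwise squared Pearson correlation of call values,
   pairwise-complete over missing data; iteratively, the current maximum
   pair is found and one member removed at random (ties on the maximum
   broken by lexicographic locus-ID pair), until all r² ≤ 0.2. Removing a
   locus cannot change other pairs' r², so the matrix is computed once.
   A zero-variance locus has r² defined as 0 with every partner.
4. **Hardy–Weinberg.** Per locus and population, the classical χ² with
   df = 1 against expected counts n·(q², 2pq, p²) from the observed
   frequency; no continuity correction. Monomorphic locus–population
   combinations are skipped and logged. The family-wise threshold is
   Dunn–Šidák, α′ = 1 − (1−α)^(1/m); by default m counts all tests
   actually performed (loci × populations, skipped tests excluded) —
   `hwe_m_mode="per_pop"` corrects within population instead. A locus
   significant in any population is removed. The pipeline computes the
   test statistics on a relative-reduced subset (one member of each
   full-sib pair flagged by a preliminary sibship pass is set aside),
   because sib-inflated genotype counts mimic HWE departure; removals
   apply to the full table.

## Genomic relationship matrix

VanRaden's first method: `G = ZZ′ / (2 Σᵢ pᵢ(1−pᵢ))`, `Z = M − P`, where
M holds −1/0/1 (alternate homozygote / heterozygote / reference
homozygote), `P = 2(pᵢ − 0.5)` and pᵢ is the reference-allele frequency.
Missing entries of M are imputed to the locus mean of observed entries —
with observed frequencies this equals 2pᵢ−1, so imputed entries vanish
after centering and contribute nothing to G. G is invariant to a globally
consistent allele flip (tested). With every locus monomorphic the
denominator is zero and the computation refuses to proceed.

Pairs of individuals carrying G ≥ 0.35 across *different* population
labels are flagged as labelling/management anomalies (the value sits just
below the "strong relationship" display band of 0.370); the pipeline omits
implicated individuals from subsequent stages. Relationship categories for
display use < 0.156 / 0.156–0.370 (closed) / > 0.370.

## Sibship reconstruction

**Pairwise likelihood.** For a pair with IBD coefficients (k₀,k₁,k₂) —
full sibs (¼,½,¼), half sibs (½,½,0), unrelated (1,0,0) — the per-locus
joint genotype probability is `k₂P₂ + k₁P₁ + k₀P₀`, with P₀ the product of
HWE genotype probabilities, P₂ the HWE probability on the diagonal, and P₁
the one-allele-IBD table (e.g. both-heterozygous = pq). Each class's
per-locus table sums to one over the nine ordered genotype pairs (tested
analytically on a grid). Genotyping error enters as a mixture — an
observed genotype is the truth with probability 1−e, otherwise an
independent HWE draw — which collapses to
`(1−e)²·J_class + (2e−e²)·J_unrelated` because every class has HWE
marginals; at e = 1 all classes coincide and every log-LR is zero. Loci
with a missing member are skipped; a used locus must have frequency
strictly inside (0,1).

**Allele frequencies.** This is the step that decides whether half-sib
structure is recoverable at all. A plain sample frequency fails in
sib-laden samples: the pair's own alleles (and its sibs') dominate the
estimate, so genuinely shared alleles look common and the HS-vs-U log-LR
collapses toward zero — in our simulations HS accuracy fell to 0.4–0.6
while true frequencies gave ~1.0, and *independent* noise on the true
frequencies (sd up to 0.09) was harmless, isolating the correlated
contamination as the mechanism. `classify_pairs` therefore uses a
deterministic leave-family-out scheme: detected full-sib families are
weighted as single observations and the frequency used for a pair excludes
both members' families entirely. The family partition itself is found by
fixed-point iteration (at most 4 passes), seeded by the frequency-free
KING-robust kinship estimator
`2φ = (2·N_het,het − 4·N_opposite-hom) / (N_het(1) + N_het(2))`
with full-sib edges above 2^(−1.5) — KING is insensitive to the frequency
distortions that break a likelihood-based seed when one family holds half
the sample. When fewer than four families are detected the scheme degrades
to leave-pair-out; with only one or two families in a population the
frequencies are fundamentally unidentifiable from that sample, and
accuracy degrades (a known limitation). The plain one-pass behaviour
remains available as `freq_mode="sample"`.

**Classification.** Each pair gets the argmax class; a best-vs-unrelated
log-LR below `lr_min` (default 3 natural-log units) is forced to
unrelated, controlling false family formation.

**Family assembly.** Full-sib families are connected components of the FS
graph. A component containing a pair whose unrelated log-likelihood beats
full-sib by more than `lr_min` is split by deleting its weakest FS edge,
iterated to consistency. Half-sib evidence is then aggregated at the
family level: the link statistic for two families is the *summed*
log-LR(HS vs U) over all their cross pairs — if they truly share a parent
every cross pair is a half-sib pair, so the sum is large, while a lone
misclassified pair between two big families is swamped by the negative
remainder. Links above `lr_min` are processed in descending order and
realised as "parent groups" (sets of families sharing one parent) under
two constraints: a family holds at most two parents, and families sharing
a parent must be pairwise linked (cliques in the link graph) without any
two families sharing both parents. Inconsistent links are dropped and
logged. Remaining parent slots get fresh private dummy parents; dummy
parent IDs are unique within population. Two founders share both dummy
parents iff they are in the same full-sib family, exactly one iff they are
half-sib linked.

The sibship marker panel is the within-population MAF > 0.2 subset
(strict), balancing information content against computation.

**Pedigree export.** Dummy parents enter the founder pedigree with unknown
parents, hence mutually unrelated in A; full sibs then get a = 0.5 and
half sibs a = 0.25 by construction.

## Pedigree A matrix and founder selection

A is built by the tabular method — a_ii = 1 + a(sire,dam)/2,
a_ij = (a(j,sire) + a(j,dam))/2, unknown parents contributing zero — over
a topological order; cycles are detected and reported. Monte-Carlo gene
dropping reproduces A within 3 SE in tests.

The unrelated-founder selection is the greedy recipe: (i) start from A;
(ii) move every individual whose off-diagonal entries are all zero to the
selected list; (iii) append the remaining individual with the lowest mean
off-diagonal relationship to the remainder (ties by lexicographic ID),
deleting it and all its relatives (a_ij > 0); (iv) repeat until empty.
The mean excludes the diagonal. The output always satisfies pairwise
a_ij = 0 (oracle-checked), and its size is bounded by the maximum
independent set of the nonzero-relationship graph (checked exhaustively on
small matrices); the greedy answer is not guaranteed to attain the
maximum.

From the mean relationship ā of the founder A matrix, ΔF = ā/2 and
Ne = 1/(2ΔF) (unbounded at ā = 0; a rounded Ne is reported alongside the
exact value). Both the full-matrix mean (diagonal included) and the
off-diagonal mean are computed; the pipeline reports ΔF from the full mean
by default with the mode exposed in config.

## Population-genetic summaries

Computed on the unrelated-founder subset.

- **Heterozygosity.** Per locus and population, Hexp = 2p(1−p) from
  observed frequencies (no small-sample correction) and Hobs = fraction of
  heterozygotes among observed calls; population means are unweighted
  across loci. The Hobs−Hexp contrast uses a two-sided paired t-test with
  explicit degenerate handling (identical vectors → t = 0, p = 1; a
  constant non-zero difference → signed infinity, p = 0).
- **FST.** Weir & Cockerham (1984) variance components a (among
  populations), b (among individuals) and c (within individuals) from
  genotype counts per locus, with the multi-locus estimate Σa/Σ(a+b+c)
  over usable loci; each pairwise estimate uses only the two populations'
  data, and an all-population overall estimate is also emitted. Negative
  estimates are reported as computed. Confidence intervals resample loci
  with replacement (percentile method; 2000 iterations by default). Loci
  where the components are undefined (an unobserved population, mean
  sample size ≤ 1, or non-positive n_c) are excluded from the sums.
- **Rarefaction allelic richness.** Exact combinatorial expectation
  `E[A_g] = Σⱼ (1 − C(N−Nⱼ, g)/C(N, g))` per locus, averaged over loci;
  computed with log-gamma for stability; g may not exceed any locus's
  observed gene-copy count; monotone non-decreasing in g.
- **PCA.** Mean-imputed, column-centred call matrix, thin SVD; variance
  explained in percent; deterministic up to axis sign.
- **Cluster number.** For K = 1..K_max the best of n_start K-means
  solutions by within-cluster sum of squares, scored as
  BIC(K) = n·ln(WSS/n) + K·ln(n); the reported optimum is the argmin, and
  the full curve is returned because "flat or rising from K = 1" is itself
  the scientifically meaningful outcome. K is capped at n−1 and a
  saturated (zero-WSS) solution scores +inf, since the formula degenerates
  there. This BIC convention rewards splitting more readily in
  low-dimensional score spaces; it behaves as intended on
  high-dimensional PCA scores, which is its use here.

## The synthetic study generator

`simulate_population` emulates the founder-collection design end to end:

- **Divergence.** Ancestral reference-allele frequencies ~
  Uniform(maf_floor, 1−maf_floor); per-population frequencies follow the
  Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with one parameter F
  interpretable as the expected FST (F = 0 branches to identical
  frequencies; the Beta parameterization is never evaluated there).
- **Family structure.** Each population has a sire pool and a dam pool
  drawn in HWE; a Dirichlet(α) weight vector over the sire×dam mating
  table assigns each sampled offspring a mating cell, so one knob spans
  "a single pair spawned everything" (α → 0) to "all matings equal"
  (α large). Offspring genotypes are Mendelian.
- **Noise.** Symmetric per-call miscall (heterozygote → random homozygote,
  homozygote → heterozygote) with probability err_rate, then missingness.
- **Marker redundancy.** A fraction of loci receives an exact duplicate on
  the same fragment (exercising fragment de-duplication) and a fraction a
  high-r² partner on a different fragment, made by copying calls and
  re-drawing 5 % from HWE (exercising LD pruning without simulating
  recombination).

Defaults are the package's reference study: 3 populations at F = 0.005,
75 offspring per population from 25×25 parents at α = 0.04 (a broad
mixture of singleton matings and sizable families), 2000 base loci + 10 %
fragment duplicates + 5 % LD partners, 1 % miscall, 2 % missing. Recovery
tests use a deliberately more sib-heavy condition (15×15 parents,
α = 0.027, mean full-sib family size ≈ 5, ≥1000 post-subset loci).

What the generator does *not* emulate: linkage and recombination (loci are
exchangeable), read-depth-dependent call quality, allelic dropout or other
asymmetric error, population substructure within rivers, overlapping
generations, or relatedness among the parental pools themselves. Passing
tests therefore demonstrate correct recovery under exchangeable-locus,
symmetric-error conditions, not robustness to genuine GBS artefacts.

## Numerical and interface conventions

- Every stochastic step takes an explicit seed; the pipeline derives all
  stage seeds from one config seed, and reports are byte-identical across
  reruns.
- File formats are plain delimited text (genotype matrix with locus and
  fragment IDs; 4-column pedigree with "0" for unknown parents; symmetric
  matrices written at 17 significant digits so round trips are exact to
  1e-12); a minimal GT-only VCF can be written and read.
- Readers validate rectangularity (naming the offending line), ID
  uniqueness (naming duplicates), and matrix symmetry; unknown call
  tokens become missing with a logged count.

## Known limitations

- Sibship classes are limited to FS/HS/U: parent–offspring, avuncular and
  inbred configurations are folded into whichever of the three fits best.
  Distant relationships (first cousins and beyond) are indistinguishable
  from unrelated at realistic panel sizes.
- Allele-frequency estimation inside sibship reconstruction needs at
  least a handful of distinct families per population; a population that
  is essentially one or two families yields unreliable half-sib calls.
- The `lr_min` threshold is calibrated in absolute nat units and does not
  scale automatically with panel size; at a few hundred loci, half-sib
  evidence may not clear it.
- The greedy unrelated-founder selection is the published recipe, not an
  optimal independent-set solver; it can select fewer founders than the
  maximum attainable.
- Pairwise FST bootstrap resamples loci only, treating individuals as
  fixed; with very few genotyped individuals the intervals understate
  uncertainty.
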