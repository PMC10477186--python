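# Methods

This note documents the statistical models behind each `dartpop` stage, the
defaults that matter, what the synthetic generator does and does not
emulate, and the numerical conventions a user should know before trusting a
number.

## Data representation

Genotypes are held as a dense samples × markers integer matrix.  SNP calls
count copies of the marker's alternate allele (0/1/2); SilicoDArT calls are
fragment presence (0/1).  A single reserved sentinel (−9) marks missing
calls; both `-` and the empty string map to it on input because DArT
exports vary.  Positions are 1-based throughout, and the strand of the
marker metadata is taken as given (no allele flipping).  Napier grass is an
allotetraploid (2n = 4x = 28), but the markers are scored as diploid
dosages, and every statistic here operates on that representation — a
statement about the data, not the cytology.

The two-row DArT dialect pairs consecutive rows sharing the clone-id prefix
of the marker id (the token before `|`); presence pairs (1,0)/(0,1)/(1,1)
map to dosages 0/2/1 and (0,0) to missing.  The exact column layouts
accepted are conventions documented in `io_formats` rather than a published
standard.

## Marker statistics and filtering

For alternate-allele frequency p and q = 1 − p:

* He = 2pq (expected heterozygosity; maximum 0.5 at p = ½).  The 0–0.5
  range of this statistic is what identifies it as *expected* rather than
  observed heterozygosity.
* PIC = 1 − p² − q² − 2p²q² (Botstein; maximum 0.375 at p = ½).

For dominant SilicoDArT markers only the band frequency f is observable.
The default converts it to an allele-frequency estimate q̂ = √(1 − f)
(absence treated as the recessive homozygote under Hardy–Weinberg), which
reproduces a 0–0.375 PIC range; the alternative convention
PIC = He = 2f(1 − f) is available via `silico_mode="band"`.  Neither is
fully satisfactory for dominant data; the choice is surfaced as an option
rather than hidden.

The robust-marker filter applies, in order: mapped → missing/call-rate →
MAF → LD pruning.  Cheap filters run first so the quadratic LD step sees
the smallest possible set; the criteria themselves (missing ≤ 10%,
MAF ≥ 5%, r² ≤ 0.5, mapped only; call rate ≥ 0.90 in GWAS mode) are the
standard DArTseq germplasm thresholds.  LD is the squared Pearson
correlation of dosage vectors over pairwise-complete samples (genotypic,
unphased r²).  Pruning is greedy within a 50-marker window advanced in
steps of 5 along genome order; when a pair exceeds the cutoff, the member
with the lower call rate is dropped (ties: lower MAF, then the
lexicographically greater id).  Window and step are configurable since only
the 0.5 cutoff is a fixed criterion.  Filtering is idempotent and the audit
table satisfies input = output + Σ removed.

## Diversity

**Nei distance.**  D = −ln I with I = J_xy / √(J_x J_y), where J are means
over loci of Σ p₁ᵢp₂ᵢ, Σ p₁ᵢ², Σ p₂ᵢ² (ratio of averages; each biallelic
locus contributes p and 1 − p).  The 1972 estimator is the default; the
1978 small-sample correction is switchable (`unbiased=True`).  Individuals
are treated as two-allele samples with frequencies 0/½/1 read off the
dosage, over pairwise-complete loci; the 0.025 duplicate threshold is
calibrated against this default in the tests.  An identity of exactly zero
(opposite fixation at every shared locus) is clipped to 1e−300 before the
logarithm rather than returned as infinity.

**F_ST.**  Weir–Cockerham θ from per-locus variance components a (among
populations), b (among individuals within), c (within individuals);
the multi-locus estimate is Σa / Σ(a+b+c) with monomorphic loci excluded.
Negative pairwise estimates are clamped to zero for reporting (raw values
are kept on the result object).  Differentiation bands: [0, 0.05) low,
[0.05, 0.15) moderate, [0.15, 0.25] high, > 0.25 very high, with boundary
values assigned upward.

**AMOVA.**  One-level analysis of molecular variance in Excoffier's
sum-of-squares form.  When given a genotype matrix, each diploid call is
expanded into two allele copies (missing calls mean-imputed), which puts
Φ_ST on the same scale as θ — the two agree within ±0.02 on
Balding–Nichols panels, and this agreement is a tested invariant.  When
given a precomputed distance matrix, the classic squared-distance SSD
partition over individuals is used instead (note the scale then depends on
the supplied metric).  Significance comes from permuting individuals among
groups: p = (#{Φ_perm ≥ Φ_obs} + 1)/(n_perm + 1), default 199
permutations.  Groups of size 1 are excluded with a warning.  Two-level
summaries (clusters, then sub-clusters) are produced by running the
one-level procedure at each level.

## Population structure

The admixture model assumes individual i draws each allele copy from
cluster k with probability Q_ik, and cluster k has allele frequency P_kl.
The Gibbs sampler cycles Z | P,Q (copy origins), P | Z ~ Dirichlet(λ +
counts) and Q | Z ~ Dirichlet(α + counts) with λ = 1 and α fixed at 1.0.
This is the independent-allele-frequency prior; the correlated-frequency
hierarchy (an F-model prior on P) is not implemented in v1 — with strongly
differentiated clusters the difference is immaterial for assignment, but
weakly differentiated clusters are harder to separate under this prior.

ln P(X|K) is estimated as mean(lnL) − var(lnL)/2 over the post-burn-in
trace (the harmonic-style estimator STRUCTURE reports), so replicate runs
feed directly into the Evanno table: L′(K) = L(K) − L(K−1),
L″(K) = |L(K+1) − 2L(K) + L(K−1)|, ΔK = L″(K)/sd(L(K)), defined only for
interior K with positive replicate sd.  ΔK is sensitive to the replicate
standard deviation; with very few replicates the sd estimate itself is
noisy, which is why the production default is 10 replicates per K and the
desk-scale test preset (3 replicates, burn-in and chain length 2000) is
validated on a strongly differentiated fixture.  Samples whose maximum
posterior-mean membership falls below 0.60 are labelled admixed; a maximum
exactly at the threshold is assigned (inclusive boundary).

UPGMA is average-linkage agglomeration with a deterministic tie-break
(among equally close pairs, the pair containing the lexicographically
smallest member merges first); the output tree is ultrametric and is
written as newick with branch lengths.  PCA mean-imputes missing dosages
per marker, centers (scaling optional) and eigendecomposes via SVD;
variance-explained is eigenvalue over trace.

## Redundancy

A pair is a duplicate when Nei distance ≤ 0.025 **or** ML kinship ≥ 0.45
(the two thresholds are alternative calibrations of the same "self"
criterion; an AND mode exists).  Kinship is evaluated only for pairs whose
Nei distance is within reach of the thresholds (d ≤ max(4 × 0.025, 0.1));
more distant pairs cannot satisfy either criterion and are reported with
kinship NaN.  Clonal groups are connected components of the duplicate
graph; the representative of each group is the member with the highest
call rate (ties: lexicographically smallest id) — a selection rule this
package defines, since any one member of a clonal group is genetically
interchangeable.  The distinct set size always equals
n_samples − Σ(group_size − 1).

## Parentage

**ML IBD.**  For a non-inbred diploid pair, (k0, k1, k2) are the
probabilities of sharing 0/1/2 alleles identical by descent;
φ = k2/2 + k1/4.  The estimator maximizes Σ_loci ln Σ_m k_m P(g1,g2 | m, p)
by EM on the simplex, using the standard genotype-pair probability table
under HWE frequencies (no k1² ≥ 4k0k2 constraint enforced).  Convergence:
lnL improvement < 1e−6 or 500 iterations; the lnL sequence is monotone
non-decreasing (asserted in tests).  Expected anchors: self/clones φ = 0.5
(k2 → 1), parent–offspring φ = 0.25 (k1 → 1), unrelated φ = 0.  A warning
is raised below 100 informative loci; loci with fixed or undefined
frequencies carry no information and are excluded.

**Seed-parent confirmation.**  The recorded parent is confirmed when
φ ≥ 0.15 — a floor chosen midway between the unrelated (0) and
parent–offspring (0.25) expectations, since no exact discrepancy rule is
standard; otherwise the candidate with maximal φ above the floor replaces
it (flagged "corrected"), and with none qualifying the progeny is
"unconfirmed".

**Mendelian-inconsistency counts.**  The pair (PC) test counts loci where
parent and child are opposite homozygotes — the only impossible
single-parent configuration; heterozygous parents are never inconsistent.
The trio (PPC) test counts loci where the child cannot take one allele from
each hypothesized parent (0×0→{0}, 0×2→{1}, 2×2→{2}, 0×1→{0,1}, 1×2→{1,2},
1×1→{0,1,2}).  Loci with any missing call are skipped; counts are reported
raw, with genotyping error absorbed by the thresholds.  PC1 is the progeny
versus its confirmed seed parent, PC2 versus every other candidate (the
minimal count marks the putative pollen donor), PPC the seed parent plus
each candidate as a trio.

**Evidence thresholds.**  Sorted counts typically show a gap between true
relatives (error-driven low counts) and unrelated candidates.  The rule
formalizing the by-eye reading: take the largest consecutive gap whose
midpoint lies in the lower half of the count range; it is "distinct" when
it exceeds twice the median consecutive spacing, and the threshold is its
midpoint.  Counts strictly below the threshold are strong evidence.

## GWAS

GLM: per marker, least squares of y on intercept + PCs (default 3) +
dosage, F-test for the dosage term; effect is the dosage coefficient in
trait units per allele copy; r² is the partial R² of the marker term × 100.
SilicoDArT markers enter as 0/1 dosages.  Monomorphic markers are skipped
with a log entry.

MLM: y = Xβ + u + e with u ~ N(0, σ_g² K), K the VanRaden genomic
relationship (centered dosage cross-product scaled by 2Σp(1−p),
mean-imputed).  After one spectral decomposition of K, the variance ratio
δ = σ_e²/σ_g² is profiled by bounded 1-D REML on ln δ ∈ [−10, 10]
(restricted likelihood computed in the rotated basis), then every marker is
tested by generalized least squares at that δ with an F reference — the
"population parameters previously determined" shortcut.  With K = I the
procedure collapses exactly to the GLM.  Bonferroni (α/m) is the default
significance rule; the p-value floor is 1e−300 to keep p in (0, 1].

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Structured populations** follow Balding–Nichols: ancestral frequency
  p ~ Uniform(0.05, 0.95) per locus, population frequency
  p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F), genotypes Binomial(2, p_k).  The
  model's expected F_ST equals F, which gives every differentiation
  estimator an analytic truth.  F = 0 degenerates to shared frequencies
  (handled, not an error).
* **Admixed individuals** draw each allele copy's source population from
  their ancestry vector Q.
* **Clones** copy a source sample with independent per-call error at rate ε
  (resampled uniformly from the other valid codes) and dropout at rate m.
* **Progeny** receive one allele from each parent per locus (heterozygotes
  transmit either allele with probability ½); selfing only when the two
  parent ids are explicitly equal; a missing parent call yields a missing
  offspring call.
* **Phenotypes** are baseline + Σ a_j·dosage_j + optional polygenic term
  (covariance proportional to the realized VanRaden kinship) + Gaussian
  noise scaled so the realized heritability matches the requested h².

Markers are simulated unlinked — LD-pruning tests plant correlated
duplicates explicitly — and there is no coalescent machinery, no linkage
map, no genotyping-batch structure, no null-allele or dominance-scoring
artifacts.  Passing tests therefore demonstrate correctness of the
estimators under their own model assumptions, not robustness to every
artifact of real DArTseq data.  All generators are seed-deterministic and
emit truth objects (labels, frequencies, Q rows, clone map, pedigree, QTL
effects) alongside every fixture.

The `simulate_germplasm_study` convenience fixture bundles the pieces into
a study-like panel: three collections of 24 genotypes at F = 0.2, nine
admixed individuals, four cross-collection clone pairs (ε = 0.005), six
seed parents with six open-pollinated progeny each, 1% missingness, and a
biomass phenotype with one QTL at 20% of variance plus a 30% polygenic
share — sizes chosen so the full pipeline runs in seconds while every
recovery check still has power.

## Problem sizes used in the checks

The automated checks run at desk scale: differentiation recovery on
2 × 100 samples × 2000 markers (F = 0.10); AMOVA null calibration on 50
replicates of 60 samples × 300 markers with 199 permutations; admixture
recovery on 3 × 20 samples × 120 markers at F = 0.3 with three replicate
chains of 2000 + 2000 iterations over K = 1..5; the duplicate rule on 100
clone replicates at ε = 0.01 and 2000 markers; parentage on 13 parents ×
4 progeny at ε = 0.005 and 2000 markers; GWAS calibration on 100 null
replicates (200 × 500) and 100 power replicates (300 × 1000, QTL at 20%
variance).  The production defaults (10 structure replicates, K up to 20,
burn-in/iterations 100,000) remain available through configuration.

## Known limitations

* The admixture sampler implements the independent-frequency prior only;
  α is fixed by default (no adaptive α update in v1), and replicate
  alignment is greedy best-match rather than CLUMPP-style.
* Dominant-marker He/PIC requires an assumption (recessive-homozygote
  absence) that real dominant data may violate.
* The IBD model assumes non-inbred individuals and unlinked loci; close
  inbreeding inflates φ between relatives.
* AMOVA supports one grouping level per run; nested designs are handled by
  running each level separately.
* No spatial/field-design adjustment of phenotypes (simple per-genotype
  means) and no multi-locus association models; GLM and MLM only.
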