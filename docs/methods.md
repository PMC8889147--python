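# Methods

This note documents the models and procedures implemented in `sigrepo`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Gene-level statistics (`sigrepo.diffexpr`)

Expression values are analysed on the log2 scale. For a contrast
(test, control) with group sizes (n₁, n₂), each gene gets an ordinary
two-sample linear model: effect log₂FC = mean(test) − mean(control), pooled
residual variance s²_g on d_g = n₁ + n₂ − 2 df, and unit contrast variance
v = 1/n₁ + 1/n₂. The empirical-Bayes hierarchy assumes the true residual
variances follow a scaled inverse chi-square prior with hyperparameters
(d₀, s₀²). These are estimated by moment matching on z_g = log s²_g:
after removing the sampling contribution digamma(d_g/2) − log(d_g/2), the
residual spread of z identifies trigamma(d₀/2), which is inverted by a
Newton iteration (tolerance 1e-8, ≤ 100 steps). Degenerate regimes:

* excess spread ≤ 0 → d₀ = ∞; the posterior variance is s₀² for every gene;
* exactly zero spread of log variances → s₀² is the common variance itself
  (no sampling correction applies to a constant);
* zero-variance genes participate in the posterior formula (legal: the
  blend is finite) but are excluded from hyperparameter estimation, where
  their log variance is undefined;
* the t reference uses min(d₀ + d_g, 10⁶) df — a capped Student t rather
  than a Normal, so p-values vary smoothly as d₀ → ∞.

The volcano rule consumes the **raw** p-value (strict |log₂FC| > 1,
inclusive p ≤ 0.05); the BH-adjusted column is carried for downstream use.
The log-posterior-odds column (`include_b=True`) uses a fixed prior
differential-expression proportion of 0.01 and an effect-variance prior
taken from the upper tail of t²; it is a diagnostic only and drives no
decision.

## Directional gene-set analysis (`sigrepo.gsa`)

Nine functional-class-scoring statistics in three families (signed-t:
mean, median, sum, maxmean; p-value: Fisher −2Σlog p, Stouffer Σz/√k,
reporter = universe-standardised mean z, tail strength; rank: standardised
Wilcoxon rank-sum). The exact method set used by any particular published
screen varies; these nine are the canonical family representatives, and the
list is configurable.

The null model is **gene sampling** (random gene sets of matched size), not
sample permutation: the clinical cohorts this pipeline targets are too
small for sample permutation to have resolution. Directionality classes:

* *distinct up/down* — right/left tails of the signed-statistic null
  (one-sided gene p-values for the p-family, so both directions are
  well-defined there too);
* *mixed up/down* — the statistic restricted to same-sign member genes,
  against nulls drawn from the same-sign portion of the universe with
  matched subset size (empty subset → p = 1);
* *non-directional* — the statistic on |t| (two-sided p), right tail.

Empirical p-values use the add-one estimator (1 + hits)/(B + 1), flooring
at 1/(B+1); an exhaustive mode enumerates all subsets on tiny universes and
reports the exact tail fraction. Null index draws are keyed by
(seed, set, universe size, subset size) and never by direction, which makes
the up/down p-values swap *exactly* under a global sign flip of t.

Consensus: within each class, sets are ranked per method by p (average
ranks on ties); the consensus rank is the median rank and the consensus p
the median p across methods. Class assignment is the argmin of consensus p
with **directional-dominance tie resolution**: permutation p-values floor,
so a strongly direction-pure set ties its distinct class with the
non-directional class and a naive "tie → non-directional" rule would label
every strong pathway directionless. Instead, ties at the minimum resolve to
the most specific class of the only side carrying evidence (distinct before
mixed); if both sides tie, or only the non-directional class attains the
minimum, the set is non-directional. Significance applies BH within each
class across sets and selects sets whose assigned-class adjusted p ≤ α
(default 0.05). Sets smaller than `min_size` (5) or larger than
`max_fraction` (0.5) of the universe are skipped with a warning.

## Connectivity scoring (`sigrepo.connectivity`)

The K-S enrichment score of a tag at sorted ranks V(1..t) in a universe of
n genes is ES = a if a ≥ b else −b with a = max_j(j/t − V(j)/n),
b = max_j(V(j)/n − (j−1)/t); ties resolve to the positive branch. The
combined score of an (up, down) query is 0 when ES_up and ES_down share a
sign, otherwise (ES_up − ES_down)/2 — bounded by [−1, 1] and antisymmetric
under tag swap. This is the classic build-1 connectivity construction
(unweighted; no GSEA-style exponent). Profiles are permutations by
construction; real-world profiles with tied expression values must be
pre-ranked (average rank, then stable order) before use.

Significance is a two-sided tag permutation: B random disjoint tag pairs of
the same sizes rescored on the same profile, p = (1 + #{|null| ≥ |obs|})/(B+1);
B < 99 is refused as unstable. Query tags default to the top/bottom
`tag_size` = 50 genes by moderated t.

## Repositioning (`sigrepo.repositioning`)

A pathway is "affected by" a compound when it contains ≥ 1 of the
compound's pooled target genes — membership, not enrichment, mirroring a
target-database → pathway-database lookup. P_clin aggregates significant
pathways across datasets/contrasts by union (configurable to
intersection — no combination rule is canonical); P_target = P_clin ∩
P_stea depends only on clinical and steatogen inputs, so growing the
compound library never changes it. Candidates must be screen-selected
(p < α, score ≠ 0, either sign) *and* overlap P_target; ranking is |score|
desc, overlap size desc, identifier asc (determinism). The hit rate is
100·positives/screened **floored** to one decimal (6/21 → 28.5, not 28.6).

## Phenotype quantification (`sigrepo.imaging`, `sigrepo.assays`)

Segmentation chain (all radii/areas configurable, defaults in px):
median 3×3 → white top-hat (disk r = 25 nuclei / 5 droplets) → Otsu →
hole filling → size filter (nuclei ≥ 100 px; droplets 2–500 px) →
distance-transform watershed for nuclei, seeded at distance peaks separated
by at least half the minimum nucleus diameter. A constant channel yields an
empty mask (Otsu needs contrast). Integrated droplet intensity sums the
*original* pixel values under the droplet mask. "Lipid intensity per cell"
is integrated droplet intensity / nuclei count; normalisation by nuclear
intensity and a per-nucleus circular association mask are provided as
options but off by default. Fold change = mean(treated per-cell metric) /
mean(control); images without nuclei are excluded with a warning.

Viability curves are fitted with a bounded-least-squares 4PL
y = d + (a − d)/(1 + (x/c)^b), a ∈ [50, 150] %, d ∈ [−20, 80] %, b ∈
(0, 50], c within the tested dose range × [0.01, 100]. IC₁₀ is the dose
where the fitted curve crosses 90% **absolute** viability (not 90% of the
fitted top), solved in closed form x = c·((a − 90)/(90 − d))^(1/b); a flag
marks crossings outside the tested range. A curve not beating a constant
fit in an F-test (α = 0.05) has an undefined IC₁₀. Group comparisons use
one-way ANOVA plus Tukey HSD via the studentized-range distribution.

## Mode-of-action clustering (`sigrepo.moa`)

Analyte fold changes over matched controls are fraction-normalised per
column to [0, 1] (constant columns → 0, deterministic, warned), embedded
with centred PCA (component signs fixed by the largest-|loading| entry),
and clustered with best-of-50 k-means, k = 4 by default — the number of
signalling modes the assay design distinguishes (negative control,
steatosis induction, steatosis reduction, compound alone). Cluster
assignment runs on the first two PCs, matching the visual analysis the
design emulates; the silhouette scan behind `chosen_k_` runs on the **full
normalised matrix**, because a 2-D projection can merge centroids that are
well separated in feature space. Concordance with reference labels is the
adjusted Rand index.

## The synthetic universe (`sigrepo.simulate`)

What it emulates: a three-group (Healthy/NAFL/NASH) log-scale expression
cohort whose residual variances actually follow the scaled inverse
chi-square prior (so the shrinkage estimator is testable against truth);
direction-pure planted pathways (contiguous core blocks, sign alternating
across pathways) among decoy sets drawn from non-planted genes; a ranked
compound library where reversers/mimickers inversely/directly rank the
planted signature (rank jitter configurable) among uniform-permutation
decoys; a compound knowledgebase whose active compounds jointly anchor
every planted pathway (dealt round-robin) with hepatotoxicity flags;
two-channel fluorescence fields (sigmoid-edged disks, minimum separations
so planted counts are recoverable, optional touching pair for the
watershed path); 4PL viability plates; and proteomic panels drawn from k
centroids with isotropic noise.

Default conditions: 2000 genes, 8+8+8 samples, 60 gene sets of 10–40 genes
with 11 planted pathways, effect 1.5 log₂ units, variance prior d₀ = 4,
s₀² = 0.05 (residual sd ≈ 0.22, typical for log-intensity microarrays),
110 compounds (5 reversers, 5 mimickers), tag size 50, tox fraction 0.3;
512×512 px fields with 12 nuclei (r = 12 px) and 40 droplets (r = 3 px).
The cohort size is on the scale of small clinical biopsy series; the gene
count keeps permutation analysis desk-fast while leaving ~90% of the
universe null.

What it does **not** emulate: microarray platform artifacts, batch or
probe-level effects, correlated gene-gene structure, real perturbational
signature structure (dose, cell line, replicate), uneven illumination or
3-D imaging, and bead-assay preprocessing. Passing recovery tests on this
universe therefore demonstrates correctness of the statistical machinery
under its stated assumptions — not robustness to the violations real data
bring.

## Known limitations

* Gene-sampling nulls treat genes as exchangeable; correlated genes
  inflate significance in real data (as for all FCS methods with gene
  nulls).
* The consensus across nine methods uses medians; no method weighting.
* The screen's tag-permutation null conditions on tag sizes only, not on
  tag composition.
* Segmentation assumes roughly disk-like objects; heavily clumped nuclei
  beyond pairwise touching are out of scope.
* Problem sizes in the validation suite (cohort 8+8+8, B = 999, 200 null
  replicates at 2000 genes) were chosen to keep the full suite fast on a
  single CPU while leaving each statistical check well-powered.
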