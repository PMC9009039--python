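# Methods

## The model

Expression is analysed on the log2 scale at the probe-set level. For gene
(probe set) g and treatment t ∈ {AL, CR, F2, SK} the model is a one-way
layout

    y_gta = μ_gt + ε_gta,   ε_gta ~ N(0, σ²_g),

fit by within-group means with pooled residual variance s²_g on
d = N − 4 degrees of freedom (N = arrays surviving QC; 22 − 4 = 18 under the
default design of 6/6/4/6). Gene variances are treated as exchangeable with
a scaled inverse-chi-square prior, σ²_g ~ d₀s₀²/χ²_{d₀}, the standard
empirical-Bayes setting for microarray moderation. The prior is estimated by
method of moments on z_g = log s²_g using the exact identities

    var(z) = ψ′(d/2) + ψ′(d₀/2)
    E[z]  = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2),

with ψ, ψ′ the digamma/trigamma functions: d₀ solves
ψ′(d₀/2) = var(z) − ψ′(d/2) by monotone bisection (tolerance 1e-8); a
non-positive excess gives d₀ = ∞ (all genes share s₀²). The posterior
variance s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d) replaces s²_g in the pairwise
statistics

    t_g(X,Y) = (μ̂_gX − μ̂_gY) / sqrt(s̃²_g (1/n_X + 1/n_Y)),

two-sided p from t with d + d₀ df (normal when d₀ = ∞). Setting d₀ = 0
("ordinary" mode) reduces exactly to the pooled-variance t. All six
unordered pairs are tested; direction is always reported for the
first-named group.

Benjamini–Hochberg adjustment is applied per pair across genes (step-up,
stable-sorted, clipped at 1). The **inclusion filter** keeps a gene when
some pair satisfies adjusted p < α (α = 0.01) *and* fold change ≥ 1.4 in
that same pair — the joint, per-contrast reading; mixing the p-criterion
from one pair with the fold change of another is deliberately not allowed.
Whether the α applies to raw or adjusted p is switchable
(`use_adjusted_p`); adjusted is the default because multiplicity adjustment
precedes the significance call.

## Pattern taxonomy

With sig(X,Y) the same joint criterion as the filter (switchable to p-only)
and dir(X,Y) the sign of the difference:

* switching (broad): sig(F2,SK) ∧ (sig(F2,AL) ∨ sig(SK,AL));
* switching (strict): sig(F2,AL) ∧ sig(SK,AL) with opposite directions —
  the fed/fasted metabolic-switch profile. The strict definition does not
  additionally require sig(F2,SK): opposite-direction AL offsets of at
  least twice the fold-change threshold make the F2–SK contrast significant
  in practice, and the summary reports the strict ∧ sig(F2,SK) overlap
  separately so either count is recoverable;
* chronic: sig(F2,AL) ∧ sig(SK,AL) with equal directions, split into
  chronic-pure (¬sig(F2,SK)) and chronic-and-switching (sig(F2,SK));
* robust chronic: chronic ∧ sig(F2,CR) ∧ sig(SK,CR) with the CR contrasts
  in the chronic direction (an "any one CR contrast" mode is provided).

Strict switching and chronic are mutually exclusive by construction. A
probe-set→symbol map collapses duplicate transcripts; probe sets of one
symbol that disagree on chronic direction are flagged discordant and
excluded from direction counts.

## Clustering and downstream

The filtered genes are row-standardized (mean 0, sd 1; zero-variance rows
become zero with a warning) and clustered agglomeratively — Euclidean
distance, complete linkage by default, mirroring the conventional `hclust`
defaults; 1 − Pearson distance and average/ward linkage are exposed. The
gene tree is cut at k = 4 (the design's cluster count, not selected from
data) with cluster ids assigned in dendrogram leaf order for reproducible
labels; the array tree cut at k = 2 tests the fed ({AL, F2}) vs underfed
({CR, SK}) separation. Cluster means over standardized values feed the
trait correlations.

Over-representation of a cluster against a pathway collection is the
hypergeometric upper tail P(X ≥ k) for k overlap genes, pathway size K and
selection n inside a universe N of annotation-carrying genes (optionally
intersected with the array content); an EASE-style variant scoring k − 1 is
available for closer emulation of DAVID's modified Fisher test. p-values
are BH-adjusted across pathways within a cluster; overlap genes of
significant pathways are partitioned into shared (≥ 2 significant pathways)
and unique.

Trait correlation is Pearson (Spearman by flag) with pairwise deletion of
missing values, p from t = r√((n−2)/(1−r²)) on n − 2 df, and a Bonferroni
flag at α_family/m where m is the number of traits tested per unit — with
the ten standard traits, 0.05/10 = 0.005. Arrays map one-to-one to
individuals (each bird is one biological replicate).

## The synthetic-data generator

The generator emulates the study conditions end to end: 6/6/4/6 arrays over
AL/CR/F2/SK, 2,000 probe sets by default (a desk-scale stand-in for the
20,771-probe-set array; full scale by config), 2–3 probes per set with a
per-probe constant bias (sd 0.3) so summarization is non-trivial but
unbiased under the median, gene baselines N(8, 1.5²) log2 units, and gene
variances from the scaled inverse-chi-square prior with d₀ = 4,
s₀² = 0.05 (mean variance 0.1). Noise is drawn at the gene × array level
and shared by a gene's probes, matching the one-σ²-per-gene model the
moderation assumes. An optional global per-array shift (default off)
exercises the optional normalization/QC stages.

Planted classes, with per-gene effect magnitudes drawn uniformly from
[e, e + 0.4] where e = 0.8 log2 units is the configured minimum (comfortably
above the log2 1.4 ≈ 0.485 filter threshold):

| class | AL | CR | F2 | SK |
|---|---|---|---|---|
| null | 0 | 0 | 0 | 0 |
| switching_up_in_fast | 0 | 0 | −m | +m |
| switching_down_in_fast | 0 | 0 | +m | −m |
| chronic_up / down | 0 | 0 | ±m | ±m |
| chronic_and_switching_up | 0 | 0 | +m | +m+m′ |
| cr_responsive | 0 | ±m | 0 | ±m |

Default proportions (null 0.54, cr_responsive 0.30, chronic 0.04 + 0.04,
switching 0.03 + 0.03, chronic-and-switching 0.02) mirror the composition
of a filtered liver IF gene set, where the fed-vs-underfed
(lipid/carbohydrate metabolism) axis dominates and the switching/chronic
classes are small. This geometry was chosen so the planted structure is
actually recoverable at the design's resolution: the restriction-responsive
archetype correlates 0.67 with the switching archetypes and 0.10 with the
chronic ones, so it attaches to existing clusters rather than bridging
them, and the four switching/chronic archetypes stay mutually separated
(pairwise |r| ≤ 0.15). Chronic classes keep CR at the AL level, so all
planted chronic genes are also "robust" chronic — a simplification relative
to real livers, where many chronic genes sit at the IF level under CR as
well.

Synthetic traits are built from a per-individual archetype score z:
trait = r·z + √(1−r²)·ε with ε standard normal, so the sample correlation
converges to the planted r; all ten traits are then mapped to plausible
units for a five-week-old bird, and relative liver mass is kept exactly
equal to 100·liver mass/body mass by deriving whichever of the two liver
variables was not the planted target.

**What passing recovery tests do and do not show.** The generator matches
the variance model of the moderation machinery exactly and plants clean
mean shifts; real arrays add intensity-dependent variance trends, probe
cross-hybridization, batch structure and non-Gaussian tails that it does
not emulate. Recovery results therefore validate the implementation and
calibration of the pipeline, not its field performance on arbitrary data.

## Numerical and design choices

* Probe-set summarization: median by default (robust to a single biased
  probe), mean by flag. Excluding failed arrays before or after
  summarization commutes; exclusion is done before.
* QC: an array fails when its median inter-array correlation drops below
  0.8 or its PC1 score (gene-centered data) deviates more than 5 MADs from
  the median, with an epsilon floor on the MAD so identical arrays never
  self-flag; a run refusing guard trips when more than 25% of arrays would
  fail.
* BH ties are broken by stable sort; adjusted values are clipped at 1.
* Zero moderated variance yields t = 0 for a zero difference and ±∞
  otherwise.
* Hypergeometric p for zero overlap is 1 (the k = 0 upper tail is total
  mass).
* Cluster labels follow dendrogram leaf order; partitions (as set
  partitions) are invariant to gene and array input order.
* Problem sizes used by the verification scripts: 20 simulated datasets of
  2,000 probe sets for filter/pattern recovery, 5 for cluster recovery
  (reported as the median adjusted Rand index — complete linkage's
  max-distance statistic is sensitive to heavy-tailed noise and to null
  false positives, so single-dataset ARI is occasionally degraded by an
  outlier-absorbed cluster), 5,000 genes for variance-prior recovery, and
  50 replicates of 22 individuals for trait-correlation power.

## Known limitations

* No covariates (sex, batch) — the design is treatment-only, as in the
  emulated study.
* No background correction, within-array spatial normalization, or
  between-array normalization by default (optional shift term and QC catch
  gross array effects); no parsing of scanner-native file formats.
* The pattern calls inherit the power of the joint filter: genes near the
  minimum detectable effect with above-average variances can satisfy one AL
  contrast but not both, so both-day pattern recall is a few percent below
  single-contrast recall by construction.
* k = 4 is a design constant; no optimal-k selection is attempted.
* Pathway results depend entirely on the supplied GMT; no annotation
  database ships with the package.
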