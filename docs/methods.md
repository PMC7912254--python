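# Methods

This note documents the models, numerical choices and limitations behind
`gutdiet`, in the spirit of a statistical-software methods appendix.

## Analysis model

The pipeline treats a cohort as four aligned tables: OTU counts with
lineages, a rooted phylogeny over the OTUs, food-group intakes (g/day) with
total energy and alcohol, and covariates (sex, age, BMI, supplement use,
physical activity, smoking status, sample batch). Samples present in all
tables are intersected (order taken from the feature table); dropped rows
are logged, mirroring the usual handling of collection failures.

Order of operations on the microbiome side: counts are rarefied **once**
(a single recorded draw, not an average over draws) to the minimum library
size, then aggregated to the rank of interest; α- and β-diversity are
computed on the rarefied table; correlation screens use rarefied,
aggregated, zero-replaced, clr-transformed proportions. Rationale: a single
standardized table keeps every downstream statistic mutually consistent,
at the cost of one extra source of seeded randomness.

### Compositional treatment

Zeros are replaced by the geometric Bayesian-multiplicative rule with a
uniform Jeffreys prior s_j = 0.5 per part (configurable `prior_strength`):
for sample i with original count total N_i, each zero part becomes
δ_ij = s_j/(N_i + S) with S = Σ_j s_j, and non-zero parts shrink by
(1 − Σ_zeros δ_ij). This is the simplest closed-form member of the
Bayesian-multiplicative family; it preserves ratios between non-zero parts
exactly, which the clr transform then relies on. clr output rows sum to 0
by construction; the Firmicutes/Bacteroidetes contrast is computed as
clr_F − clr_B, identically ln(p_F/p_B).

### Diversity

Chao1 uses the bias-corrected form throughout so samples without
doubletons are defined. Shannon uses the natural log by default (a `base`
flag is provided; older 16S pipelines sometimes used base 2). Faith PD and
both UniFrac variants are computed from an explicit branch-incidence
decomposition of the rooted tree (root itself carries no branch): Faith PD
sums branches on root-to-leaf paths of observed taxa; unweighted UniFrac is
(branch length unique to one sample's leaf set)/(branch length in either);
weighted UniFrac is Σ_b l_b|P_A(b) − P_B(b)| and is **unnormalized by
default** (a `normalized` flag divides by Σ_b l_b(P_A + P_B)). Negative
PCoA eigenvalues (possible for non-Euclidean dissimilarities) are excluded
and their absolute mass reported — no Cailliez/Lingoes correction, so the
decision stays auditable.

### Diet adjustment

Intakes are log-transformed (zeros offset by half the smallest positive
value in that column — a choice the data cannot dictate, exposed in code)
and energy-adjusted by the residual method **on the log scale**: residuals
of log intake on log total energy plus the fitted value at the sample-mean
log energy, so adjusted columns keep their location and are exactly
uncorrelated with log energy.

### Reduced rank regression

With a single response the first RRR factor is exact: weights are the OLS
coefficients of the response on column-standardized foods, the score is the
standardized fitted value, loadings are food–score Pearson correlations
(the convention of the dietary-pattern literature; raw weights are also
reported so the choice is transparent), and explained response variance is
the squared score–response correlation. The score is oriented so its
correlation with the response is non-negative ("high-diversity" pattern).
Multi-response RRR is out of scope.

### Enterotypes

Clustering operates on exactly the first two principal coordinates
(configurable), k-means++ with 50 restarts, seeded. Diagnostics cover
k = 1..k_max: within-cluster sum of squares (elbow: maximal second
difference), mean silhouette width (argmax), and the gap statistic with a
uniform reference over the 2-D bounding box (B = 50 references by default;
suggested k is the smallest with gap(k) ≥ gap(k+1) − se(k+1)). The final k
is a user decision (default 3, the canonical enterotype count); the
diagnostics are reported, not enforced. Clusters are named by the genus
maximizing (mean proportion inside − mean outside), with ties broken by
inside mean then lexicographically and an injective cluster→genus map; a
raw-dominance rule would let one globally dominant genus name every
cluster.

### Association statistics

Partial Spearman = rank-transform (midranks) x, y and indicator-expanded
covariates, residualize ranked x and y on ranked covariates + intercept,
Pearson-correlate residuals; two-sided p from t on n − 2 − c df. BH-FDR is
the step-up procedure; correction scope is explicit config (default: within
each left-variable family, i.e. per taxon family in screens). PERMANOVA is
the single-factor pseudo-F with label permutations; p has floor
1/(n_perm+1). Mann-Whitney switches to exact enumeration when the pooled
sample is ≤ 12 and tie-free, otherwise the tie- and continuity-corrected
normal approximation. The GLM group test is a partial F comparing
covariates+group against covariates only, with adjusted means evaluated at
covariate sample means; among the equivalent-looking conventions (type-III
decomposition vs adjusted-mean contrasts) the partial-F definition used
here is stated explicitly in output metadata.

## Synthetic-study generator

The generator emulates the *shape* of a 222-subject cohort, not its
estimates:

- **Phylogeny.** Leaves carry a deterministic taxonomy over four phyla
  (Bacteroidetes, Firmicutes, Proteobacteria, Actinobacteria; leaf budget
  30/50/12/8%) and 21 named genera including the enterotype markers.
  Topology is random-join within genus, then within phylum, then across
  phyla; branch lengths are exponential (tips mean 0.05, genus stems mean
  0.2, joins 0.35/0.3) so genera form well-separated clades, as in real 16S
  trees where between-genus distance dominates within-genus distance.
- **Counts.** Per sample: an enterotype label from proportions
  (0.288, 0.365, 0.347); a Dirichlet draw around that enterotype's mean
  composition (base phylum masses follow the 54/38/4/0.4% dominance
  ranking, log-normal weights within phylum; the dominant genus clade mass
  is multiplied by 6); multinomial counts at a uniform depth in
  (8000, 45000). The Dirichlet precision is 250·exp(0.8·u_i) for a
  standard-normal latent u_i, so **the planted diet effect acts on true
  community evenness**, not on the Shannon statistic directly — recovering
  it is a genuine end-to-end test. Realized corr(Shannon, u) ≈ 0.7–0.8.
- **Diet.** log intake = log mean + slope·(log energy − mean) +
  diet_effect·w_g·u_i + N(0, 0.4), with energy log-normal
  (median 2000 kcal/day, σ = 0.2), slopes U(0.5, 1), group means set to
  plausible Korean-cohort g/day values, and planted weights w on eight
  foods (fermented legumes 0.8, vegetables 0.7, potatoes 0.6, seaweeds 0.6,
  nuts/seeds 0.5, tea 0.4; non-alcoholic beverages −0.7, other cereal
  products −0.4). Default diet_effect = 0.5 gives food–latent correlations
  around 0.4–0.6 — a strong but not degenerate planted signal.
- **Covariates** are independent draws matching the cohort's marginal rates
  (49% male, 35% supplement use, 41% active, 24% ever-smokers, 8 batches),
  except a planted sex→alcohol effect (+0.9 on the log scale for males),
  which serves as the confounding fixture for partial-correlation tests.
- All draws flow from one root seed through named sub-streams (CRC-derived
  child seeds), so adding a component never perturbs another's stream and
  identical configs serialize byte-identically.

What the generator does **not** emulate: genus-level abundance
distributions of any real cohort (only the phylum dominance ranking),
sequencing error/chimeras, item-level (106-item) FFQ structure,
enterotype–diet coupling (enterotype labels are independent of the latent
diversity variable), and covariate–microbiome confounding beyond the
sex→alcohol fixture. Passing recovery tests therefore demonstrates that
the estimators work at cohort-scale signal strengths, not that any real
cohort's effect sizes are reproduced.

## Numerical choices and degenerate inputs

Rarefaction uses multivariate-hypergeometric sampling (without
replacement); samples below depth are dropped and logged. All-zero samples,
constant energy, rank-deficient designs and constant inputs raise typed
errors naming the offender. PCoA symmetrizes its input and truncates to
the positive-eigenvalue subspace with a warning. k-means determinism comes
from a seeded scikit-learn run with 50 restarts; the WSS elbow tolerance
for monotonicity is 1e-9. Permutation p-values never return 0.

## Problem sizes used in tests

Unit and property tests run on trees of 2–12 leaves with brute-force
per-branch oracles; calibration tests use 200-replicate nulls; recovery
tests use the full 222-sample generator defaults over 10–50 seeds; the
pipeline smoke and determinism tests use a 30-sample, 60-taxon study with
reduced gap-statistic replicates. These sizes were chosen so the whole
suite exercises cohort-scale behaviour while remaining quick to run.

## Known limitations

Single-response RRR only; single-factor PERMANOVA (no strata or marginal
multi-factor tests); no alternative normalizations (CSS/TMM/rCLR); no
rarefaction-averaged ("multiple draw") diversity; unweighted-UniFrac
enterotyping shares the same code path but, being presence/absence only,
often supports a different cluster count than the abundance-weighted
metrics; the gap statistic uses the simple
uniform bounding-box reference, which is conservative for elongated score
clouds.
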