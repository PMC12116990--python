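# Methods

`guildflow` implements a guild-based analysis of longitudinal gut-microbiome
cohorts: a repeated-measures design in which every subject is sampled at a
fixed grid of timepoints around a dietary intervention, and the questions are
(i) which groups of genomes move together as ecological units ("guilds"),
(ii) which features and guilds respond to the intervention, (iii) whether the
community as a whole shifts and reverts, and (iv) which guilds track
metabolite concentrations.

## Guild inference

Bacteria in the gut do not vary independently; co-abundant groups behave as
functional units. Guilds are inferred from the abundance table alone:

1. **Prevalence filter.** Features present (abundance > 0) in fewer than
   `ceil(min_prevalence * n_samples)` samples are removed
   (`min_prevalence = 0.20` by default). The filter report records the kept
   features' share of total abundance; in cohorts of prevalent, dominant
   organisms this share is close to 1.
2. **Within-subject (repeated-measures) correlation.** For every feature
   pair, Pearson correlation of the deviations from each subject's own mean:
   `r = Σ_it (x_it − x̄_i)(y_it − ȳ_i) / sqrt(Σ(x−x̄_i)² Σ(y−ȳ_i)²)`.
   Centering by subject removes the large, stable between-person differences
   in community composition, so `r` measures co-variation *within*
   individuals over time. A flag exposes plain Pearson across all samples as
   an alternative. Features with zero within-subject variance get `r = 0`
   (distance 1) against everything, with a logged warning, rather than being
   dropped — this keeps the distance matrix complete and is conservative for
   clustering.
3. **Correlation distance and Ward tree.** `D = 1 − r ∈ [0, 2]`. The tree is
   agglomerative Ward in the Ward.D2 convention (Lance–Williams update on
   squared distances; the convention of R's `hclust(method="ward.D2")` and
   scipy's `linkage(..., "ward")`). Merge ties are broken by the smallest
   (row, column) index pair, making the tree deterministic; the variant is
   recorded in run logs so runs are comparable.
4. **Sequential PERMANOVA tree cut.** Descending from the root, each
   internal node with ≥ 3 members is tested by PERMANOVA with its two child
   clades as groups and the correlation distance as the metric (the only
   distance available over features at this level). If the clades differ
   (p ≤ α, default α = 0.001 with 9999 permutations), recursion continues
   into both children; otherwise the node's members become one guild. Nodes
   too small to test stop as guilds; leaves reached by recursion become
   singleton guilds. Guilds are numbered in pre-order. Each node's
   permutations come from an RNG keyed on (seed, node id), so the partition
   is invariant to traversal order.

The significance rule is `p ≤ α`, not `p < α`: the permutation p-value uses
the add-one estimator `p = (1 + b)/(1 + m)` (it can never be 0), whose
smallest attainable value is `1/(1 + m)`; with a strict inequality the rule
could never fire at `m = 1/α − 1` permutations.

A caveat worth stating: the tested split is the one Ward chose on the same
distance matrix, so the test at each node is anti-conservative (the
observed pseudo-F is selected, permuted ones are not). This is inherent to
the sequential tree-cutting design; in practice it means clades of
unstructured features can be subdivided beyond their true (absent)
structure, while genuinely cohesive blocks still stop the recursion.

**PERMANOVA.** `SS_total = Σ_{i<j} d²_ij / N`, `SS_within = Σ_g (1/n_g)
Σ_{i<j∈g} d²_ij`, `pseudo-F = ((SS_total − SS_within)/(a−1)) /
(SS_within/(N−a))`. With strata, permutations shuffle labels only within
each stratum. An exhaustive mode enumerates every distinct relabeling
(including within-stratum enumeration) for small problems; unit tests pin
it against brute-force enumeration at N = 4 and at 5 subjects × 2
timepoints. `SS_within = 0` yields `F = +∞` with the p-value still taken
from permutations.

## Repeated-measures screening

Per-feature screening across timepoints follows a cascade:

- **Screen:** repeated-measures one-way ANOVA with subject as block
  (an unblocked one-way ANOVA is available by flag), producing one p-value
  per feature; Benjamini–Hochberg across features within the omic layer;
  features with q ≤ 0.25 advance. The liberal threshold is a screen — it
  bounds the expected false-discovery proportion among advanced features,
  not the familywise error.
- **Post hoc:** Friedman test (within-subject ranks, mid-ranks for ties,
  tie-corrected statistic, χ²_{k−1} reference) and the Nemenyi all-pairs
  test (standardized mean-rank differences against the studentized range
  with infinite df — verified against R's `ptukey` to 1e-8). Optionally
  Dunnett-style many-to-one contrasts versus the baseline day: paired
  t-statistics referred to the maximum of an equicorrelated (ρ = 1/2)
  multivariate t with n−1 df, integrated by seeded Monte Carlo (100 000
  draws; adjusted p-values reproducible to ~5e-3).
- **Two-timepoint comparisons** are gated on Shapiro–Wilk normality of the
  paired differences (α = 0.05): paired t when normal, two-sided Wilcoxon
  signed-rank otherwise (exact null distribution up to 25 nonzero
  differences — pinned against full 2^n sign-pattern enumeration — normal
  approximation with continuity correction above; zeros dropped). All
  differences zero returns p = 1 with a degenerate-data flag.

Subjects missing any timepoint of a tested set are dropped from that test
(complete-case); features with fewer than 2 complete subjects are flagged
in the output, never silently removed.

**Power analysis.** The a-priori sample-size computation for the
repeated-measures within-factors F test follows the G*Power conventions:
noncentrality `λ = f²·n·m·ε/(1−ρ)`, `df₁ = (m−1)ε`, `df₂ = (n−1)(m−1)ε`,
power = noncentral-F mass beyond the central-F critical value. With
f = 0.3, α = 0.05, m = 4, ρ = 0.5, ε = 1 the smallest n reaching power
0.85 is 19 (achieved power 0.8628).

## Ordination and community-level testing

Bray–Curtis (presence and abundance) or Jaccard (presence only, threshold
abundance > 0 with no pseudocount) for community profiles; Euclidean
distance on per-feature z-scores for protein/metabolite profiles
(zero-variance features dropped with a warning).

**PCoA** is classical Torgerson scaling: Gower-center `G = −½·C·d²·C`,
eigendecompose, scale eigenvectors by √eigenvalue. Negative eigenvalues are
reported and their axes discarded; no Lingoes/Cailliez correction is
applied by default because raw ordinations are what get plotted.

**aPCoA** (covariate-adjusted PCoA) replaces `G` by `(I−H)·G·(I−H)` where
`H` projects onto the covariate's indicator space (subject identity by
default). The resulting coordinates are exactly orthogonal to every
between-subject contrast, so the ordination displays the variation left
after removing inter-individual differences — in longitudinal gut
microbiome data the dominant structure, since samples cluster by person
far more tightly than by treatment.

**Subject-stratified PERMANOVA** tests timepoint effects while permuting
timepoint labels only within each subject, preserving the repeated-measures
structure under the null (unrestricted permutation is not valid when
subjects differ strongly). Day contrasts are run pairwise on the two days'
samples; subjects contributing fewer than 2 samples to a contrast are
dropped with a warning. Raw p-values are reported per day pair (no
correction across pairs, matching the one-row-per-contrast reporting
convention; a flag enables BH).

## Guild–metabolite association

For every (guild, analyte) pair the analyte concentration is regressed on
the guild's arcsine-square-root-transformed relative abundance
(`AST(p) = arcsin(√p)`, variance-stabilizing for proportions) with a random
intercept per subject. The model is fit by maximum likelihood with a 1-D
profile over the variance ratio `λ = σ²_u/σ²_e`: given λ, the GLS
coefficients and σ²_e are closed-form via Sherman–Morrison
(`V_i⁻¹ = I − λ/(1+λn_i)·J`, `|V_i| = 1+λn_i`); λ is optimized on the log
scale by bounded scalar search (tolerance 1e-10) with the OLS boundary
(λ = 0) always evaluated, so the returned likelihood is never below the OLS
likelihood. The fit matches `statsmodels` MixedLM (ML) to ~1e-5 in
log-likelihood in the test suite, where statsmodels serves as the
independent cross-check, never the implementation.

The slope's Wald statistic is referred to a t distribution with
`n_subjects − 2` df rather than a normal: guild abundance varies mostly
between subjects, so the effective information is closer to the number of
subjects than of samples, and the normal reference is measurably
anticonservative at cohort sizes in the tens (null rejection ≈ 0.063 vs
≈ 0.057 at n = 27 in our calibration runs). BH runs across all tested
pairs in one family; pairs with fewer than 3 shared observations or a
constant regressor are flagged, not fit. A negative slope encodes the
"suppressed guild, elevated metabolite" direction.

## Synthetic cohorts

The generator produces cohorts with exactly the structure the analysis
assumes, plus ground truth for recovery tests. Defaults emulate a
27-subject cohort sampled at days −5, 0, 2, 4, 10 (16 F : 11 M) with 120
compositional features: 10 planted guild blocks of 8 plus 40 background
singletons. The full study scale (~1500 features, ~170 guilds) is a
configuration, not a test default.

Log-abundance of feature g (block k) in sample (i, t):

    log A_git = mu_g + u_ki + s_it
                + feature_sd · (√rho · z_kit + √(1−rho) · e_git)
                + delta_k(t)

- `mu_g ~ N(0, 1.5²)`: heavy-tailed base abundances, emulating the orders
  of magnitude spanned by genome abundances in real metagenomes.
- `u_ki ~ N(0, subject_sd²)`, subject_sd = 1: **guild-level** subject
  intercepts — each subject carries each guild at its own stable level.
  This choice is deliberate. A subject effect shared by *all* features is a
  common within-sample factor and cancels exactly under compositional
  closure, leaving no subject fingerprint at all; an independent
  *per-feature* intercept acts multiplicatively on the linear scale and
  rescales each block member's within-subject deviations independently,
  eroding the very co-abundance the blocks are meant to carry. Guild-level
  intercepts give same-subject samples their characteristic tight
  clustering in unadjusted ordinations while keeping block members
  co-abundant both within and across subjects.
- `rho = within_guild_corr = 0.7`: target latent correlation between block
  members; `feature_sd = 1` scales the shared factor z and residual e.
- `s_it ~ N(0, 0.3²)`: per-sample depth-like shift (largely removed by
  closure; kept as a realistic nuisance).
- `delta_k(t)`: per-timepoint log-fold-changes for affected guilds, zero at
  baseline. The default transient pattern suppresses one guild and raises
  another by 1.5 log-units at days 2 and 4, reverting at day 10 —
  emulating a temporary intervention effect that the community recovers
  from.

Abundances are exponentiated and closed per sample; a counts mode
Poisson-samples a stated sequencing depth. One global seed feeds named
substreams (abundance / metabolites / outcomes), so adding one component
never perturbs another's draws.

Metabolites are drawn as `intercept + slope · AST(target-guild abundance) +
subject intercept + noise`, truncated at 0. The default "HCA-like" analyte
couples negatively (slope −5, residual sd 0.5) to the suppressed guild.
Realistic effect sizes for such couplings are not identifiable from
published study summaries, so the
generator's effect parameters are calibrated for testability: strong enough
that a correct implementation recovers them essentially always, which makes
recovery failures informative about the code rather than about sampling
luck. The residual sd of 0.5 keeps the planted coupling's standardized
effect clearly detectable across the seed-to-seed variation in the target
guild's compositional share.

**What the generator does not emulate:** sequencing and assembly error,
zero inflation and detection limits (features are never exactly absent, so
the prevalence filter is exercised by crafted tables, not by the default
cohort), taxonomic identity, food-intake covariates, and any real
metabolite chemistry. Passing recovery tests therefore demonstrates that
the inference machinery is correct under the assumed statistical structure,
not that real cohorts satisfy that structure.

## Numerical choices and degenerate inputs

- Permutation p-values use `(1 + b)/(1 + m)` everywhere.
- Ward tie-break: smallest (row, column) pair; exchangeable inputs give
  flat merge heights regardless of tie order.
- All-zero sample pairs under Bray–Curtis get distance 0 with a warning.
- Correlation distances are clipped to [0, 2]; eigenvalue tolerance for
  PCoA axis retention is 1e-10.
- The profile-likelihood GLS solve falls back to the minimum-norm
  (pseudo-inverse) solution if the weighted design is numerically singular
  (a regressor constant within every subject at extreme variance ratios);
  such pairs surface with huge standard errors rather than crashing a
  150-pair association sweep.
- Benjamini–Hochberg is delegated to `statsmodels.multipletests(fdr_bh)`
  behind the package's own surface and pinned against hand step-up
  arithmetic in tests.

## Problem sizes in the test suite

The suite runs end-to-end recovery at the reduced default scale (120
features, 27 × 5 samples, 999 permutations, 10 seeds), calibration loops at
500–1000 replicates, the planted-association sweep at 50 seeds, and screen
FDR at 30 seeds; these sizes were chosen so the whole suite completes in a
few minutes on one core while keeping Monte Carlo error well inside the
asserted bands. Simulation-based assertions use fixed seed ranges chosen
before inspection, and bands follow the quantity's own sampling error (e.g.
±0.02 around a nominal 0.05 at 500–1000 replicates).

## Known limitations

- The sequential tree cut inherits the selection bias discussed above; the
  number of guilds found in unstructured data grows with the permutation
  count's resolution and should not be over-interpreted.
- The guild PERMANOVA treats features as exchangeable observations under
  the null, which ignores the dependence induced by compositional closure.
- The association model fits one fixed covariate (the guild) — no
  adjustment for diet or other time-varying covariates.
- Dunnett adjusted p-values are Monte Carlo estimates; at the default
  100 000 draws they carry ~3e-3 standard error.
- Wilcoxon exact p-values fall back to the normal approximation when ties
  among nonzero |differences| defeat the exact method.
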