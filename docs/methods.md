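# Methods

`famnet` implements a family-based strategy for weighted gene coexpression
network analysis of quantitative traits in a small set of large pedigrees,
together with the two whole-sample ("naïve") network analyses and the
single-probe mixed-model scan it is meant to be compared against. This
note documents the models, the algorithmic choices made where the design
was genuinely open, the synthetic data the package is validated on, and
the known limitations.

## Models

### Variance-components mixed model

All association testing and decorrelation rests on one model family. For
individual *j* in family *i*,

    Y_ij = mu + beta * Z_ij + u_ij + v_i + e_ij

where `Z` is the tested covariate (a probe's expression, or a module
eigengene), `u ~ N(0, sigma_g^2 * 2K)` is the additive polygenic effect
with `K` the pedigree kinship matrix, `v ~ N(0, sigma_v^2 * B)` a shared
family-environment effect (`B` is 1 within a family, 0 across), and
`e ~ N(0, sigma_e^2 * I)`. Three configurations are used:

* **single-probe scan** — `Z` = probe expression, all three kernels;
* **within-family module test** — `Z` = family-module eigengene, fitted
  on that family's samples only, *without* the `v` kernel: within a
  single family a family-constant effect is confounded with the
  intercept;
* **joint eigengene test** — `Z` = a cross-family eigengene (family
  approach E_F, or a whole-sample network eigengene), all three kernels.

Estimation is REML with the fixed effects and the residual scale
profiled out: with variance ratios `theta_q = sigma_q^2 / sigma_e^2`, the
restricted likelihood is maximized over `theta >= 0` by a Nelder–Mead
search in log-ratio space started at equal components, plus bounded
scalar searches on every boundary sub-model (each subset of ratios pinned
to 0). The best evaluated point wins, so boundary estimates are exactly
zero rather than clamped, and the returned solution never has a worse
objective than any iterate. Objective tolerance is 1e-8. Wald tests of
`beta` use a standard normal reference; with 5 families and a few
hundred samples this is mildly liberal in principle, but the null
calibration checks (500 replicates per model) show the empirical size
within the binomial band around 0.05, so no degrees-of-freedom
correction is applied.

**Conditional residuals.** Decorrelated expression `X*` is defined as the
conditional residual `y − X beta − BLUP(u) − BLUP(v)`, computed as
`sigma_e^2 V^{-1} (y − X beta)`. Marginal residuals (fixed part only)
are available behind a flag; they retain the family covariance the
decorrelation step is meant to remove, which is why conditional is the
default.

**Batch fitting.** Decorrelation and heritability filtering fit the same
intercept-only model to thousands of probes. These paths share one
profile-likelihood evaluation per point of a fixed 14×14 grid of
variance ratios (0 plus a geometric ladder from 0.02 to 24), reusing
each grid point's Cholesky factor across all probes. The grid resolves
heritability to roughly ±0.03, which is ample for ranking probes and for
residualization; the exact per-probe optimizer remains the reference
implementation and the single-probe scan always uses it.

**Heritability** is `h2 = sigma_g^2 / (sigma_g^2 + sigma_v^2 +
sigma_e^2)` from the intercept-only fit. The top-fraction filter keeps
`ceil(f * P)` probes, breaking ties at the cutoff by probe id so the
subset is reproducible.

### Kinship

Pedigree-based kinship is computed by the standard tabular recursion in
topological order (founders: phi_ii = 1/2, unrelated across founders and
families; non-founders: phi_ii = (1 + phi_fm)/2, phi_ij = (phi_fj +
phi_mj)/2). Inbred pedigrees are handled by the recursion as written.
The genetic kernel is `2K`. Correctness is checked against a
gene-dropping Monte Carlo (200,000 allele drops per pedigree, tolerance
±0.01 per entry).

### Signed coexpression networks

* **Correlation**: biweight midcorrelation — each probe is centered on
  its median and scaled by 9×MAD; Tukey biweight weights
  `(1 − u^2)^2 · 1{|u| < 1}` zero out points at or beyond 9 MADs. A
  probe with zero MAD falls back to the Pearson form for its pairs
  (logged); constant probes correlate 0 with everything.
* **Adjacency**: `a_lk = |0.5 + 0.5 · cor|^gamma`, diagonal 1. The
  default `gamma = 6` follows common practice for signed-type networks;
  `pick_soft_threshold` instead selects the smallest even exponent in
  {2,…,20} whose signed scale-free fit index (log-log regression of the
  binned connectivity histogram) reaches 0.8, falling back to the best
  fit when none qualifies.
* **Topological overlap**: `TOM_lk = (sum_m a_lm a_mk + a_lk) /
  (min(k_l,k_k) + 1 − a_lk)` with zeroed diagonal in the sums; the
  clustering dissimilarity is `1 − TOM` by default (`1 − adjacency`
  by configuration).

### Module detection

Average-linkage hierarchical clustering of the dissimilarity, cut by a
dynamic-hybrid-style procedure designed to behave identically on
strongly and weakly correlated data:

1. **Core height.** Let `h_low` be the 5th percentile of all merge
   heights (the tightest structure this tree contains) and `h_cut =
   0.98 ×` tree height. Module cores are the maximal branches that
   finish merging below `h_low + c · (h_cut − h_low)` with cohesion
   `c = 0.5`, and hold at least `min_module_size / 8` (at least 4)
   probes. Anchoring at `h_low` makes the threshold scale-free in the
   dissimilarity.
2. **Nucleus merging.** Two cores fuse when the mean dissimilarity
   between them lies inside either core's assignment radius (below),
   repairing modules whose tight nucleus fragments.
3. **PAM-like assignment.** Each remaining probe joins the core with
   the smallest mean dissimilarity, provided that mean is below the
   core's radius — 60 % of the way from the core's internal mean
   dissimilarity to the overall background mean. This recovers members
   that average linkage chains on one at a time, while rejecting
   background probes whose distance to any core is indistinguishable
   from the overall mean.
4. Modules below `min_module_size` (default 30) dissolve into the
   reserved `grey` label; labels are `module1, module2, …` by
   decreasing size.

The `cohesion` knob plays the role of a split sensitivity: larger values
admit weaker, less separated modules. The defaults were calibrated on
planted-module simulations spanning three regimes — noiseless blocks
(exact recovery required), moderately correlated planted modules among
noise probes (adjusted Rand index > 0.8), and pure noise (everything
grey) — and on family-sized data (45–65 samples) where within-module
correlations of ~0.2–0.35 must still seed a detectable core.

### Eigengenes

A module eigengene is the first principal component of the
samples-by-genes block of standardized expression (probe mean 0, sd 1),
rescaled to unit variance. `variance_explained` is the leading
eigenvalue's share. The sign is fixed so the scores correlate
positively with the module's mean standardized expression. Zero-variance
genes are dropped with a warning; a set collapsing below two genes is an
error.

### The family meta-analysis

1. Build one signed network per family on the covariate-adjusted
   expression of that family's samples (within a family the shared
   environmental term is constant, so decorrelation is not applied
   here).
2. Test every non-grey module eigengene against the trait with the
   within-family model; per family keep the smallest p, across families
   select the overall smallest-p (family, module) pair. Exact p ties go
   to the larger |beta|/se, then lexicographic module id, making the
   selection order-independent.
3. Match the selected module into every family's network by the module
   with the largest raw gene overlap (the reference family naturally
   matches itself); ties break by higher Jaccard, then smaller module,
   then id. Raw count rather than Jaccard is the primary metric because
   the method's combination step wants shared genes, not similarity of
   module extents.
4. Intersect and union the matched modules. For each candidate set,
   compute a per-family eigengene and summarize the candidate by its
   *minimum* variance explained across families — a worst-family
   criterion; the better candidate defines E_F (intersection wins
   ties). Per-family scores are concatenated, not pooled into one PCA:
   each family's component may weight the common genes differently, and
   per-family variance explained is the quantity the selection rule is
   defined on. Pooled PCA across all samples is available via
   `netbuild.module_eigengene` on the concatenated matrix if wanted.
5. Test E_F jointly with the full three-kernel model; Bonferroni-adjust
   the within-family module tests over the total number of such tests
   performed, and whole-sample network tests over the number of modules
   in that network.

The naïve baselines build a single whole-sample network on the raw
(`naive`) or decorrelated (`naive-decor`) expression with identical
network settings and test each module eigengene with the joint model.

## Synthetic data

The generator emulates the target study design: five pedigrees of sizes
65/55/45/62/49 (276 individuals, 3+ generations, founders marrying in),
probe expression

    X = lambda * F + g + v + beta_age * age + beta_sex * sex + e

with per-module, per-family latent factors `F ~ N(0,1)` (a module is
either shared by all families or private to one), polygenic `g`
generated by gene dropping (founder ~ N(0, sigma_g^2), offspring =
midparent + N(0, sigma_g^2/2); the non-inbred Mendelian-sampling form —
the generator never produces inbreeding), family-constant `v`, and iid
noise. The default per-probe variance components are `sigma_g^2 = 0.4,
sigma_v^2 = 0.2, sigma_e^2 = 1.0`, i.e. h2 ≈ 0.25 for a background
probe — mid-range for expression traits. The causal trait adds
`0.3 × X` over 15 causal probes placed one per planted module and the
rest in the background (the generating genes of the emulated trait sit
in distinct pathways), plus an independent gene-dropped polygenic term
(variance 1), covariate effects (age 0.2/year, sex 2.0) and unit noise.
The null trait has the same architecture minus the causal term and is
independent of every probe given pedigree and covariates. Age is
uniform on [20, 80]; sex follows the pedigree. The packaged
`gaw19-like.json` scenario uses 2,000 probes and six modules (four
shared, two family-private).

What the generator does **not** emulate: probe-level measurement
artifacts and batch structure, non-Gaussian expression distributions,
linkage disequilibrium or genotype-level inheritance, correlated module
factors, ascertainment, and longitudinal structure. Passing tests
therefore demonstrate correctness of the statistical machinery under a
well-specified polygenic factor model, not robustness to everything
real expression data can do.

## Numerical choices and degenerate inputs

* All randomness flows from `numpy.random.Generator` seeded via
  `SeedSequence`; identical seeds give byte-identical outputs, which the
  test suite asserts end-to-end through the CLI.
* REML: objective tolerance 1e-8; ratio searches bounded to
  `log theta ∈ [−12, 6]`; ratios below 2e−12 snapped to the boundary.
  A response numerically fully explained by the fixed design (constant
  probe) short-circuits to a zero-variance fit with a warning.
* Probes with > 10 % missing values are dropped before correlation;
  the rest are mean-imputed per probe.
* Empty intersections fall through to the union set with a warning;
  a family whose best overlap is zero maps to the empty set.
* Bonferroni uses `p ≤ alpha / n_tests` with `p_adj = min(1, p·n)`.
* Simulation sizes in the test suite are scaled to what the statistical
  property needs: 200-sample data sets for the 500-replicate
  calibration checks, 400-probe five-family scenarios for module
  recovery, a 250-probe scenario for the end-to-end determinism check.

## Known limitations

* Module detection parameters are calibrated for the tens-of-samples,
  hundreds-to-thousands-of-probes regime; block-wise handling of very
  large (>50k probe) matrices is out of scope.
* The Wald reference is N(0,1); with very few families a
  Satterthwaite-style correction would be more conservative.
* Whether decorrelation should use conditional or marginal residuals is
  ambiguous in the method being implemented; conditional is the
  default, marginal is behind a flag.
* The union-combination path and LASSO-style selection from the union
  set are not implemented beyond eigengene construction; intersection
  is the primary combination rule.
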