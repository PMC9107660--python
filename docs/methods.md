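# Methods

`crosstrait` implements a summary-statistics pipeline connecting an
early-life exposure (birthweight, decomposed into fetal- and
maternal-specific genetic components) to an adult disease outcome (breast
cancer) through three layers of evidence: genome-wide genetic correlation,
gene-level pleiotropy, and a Mendelian-randomization (MR) mediation chain
through age at menarche and age at menopause.  Every stage consumes only
GWAS summary statistics plus a block LD reference; no individual-level
data are touched anywhere.

## Summary statistics and harmonization

The per-SNP record is (rsID, chromosome, position, effect/other allele,
beta, SE, p, N, optionally Z and effect-allele frequency), with Z derived
as beta/SE when absent and p recomputed from |Z| under the two-sided
normal when absent.  Coordinates are 1-based closed intervals.

QC drops SNPs without an `rs`-style identifier and removes *every* copy of
a duplicated rsID — duplicates cannot be adjudicated from summary data, so
the conservative choice is to discard them all.  Cross-trait harmonization
intersects on rsID, aligns swapped or strand-complemented allele codings by
flipping the sign of beta and Z, and removes strand-ambiguous palindromic
SNPs (A/T, C/G) by default; a flag retains them with frequency-based
alignment when both traits carry an allele frequency at least 0.08 away
from 0.5.  The MHC region (chr6:25–34 Mb, the standard convention) is
excluded before LD score regression because its extreme LD violates the
regression model.

## Cross-trait LD score regression

Univariate and bivariate moment models:

    E[z_j^2]     = n h2 l_j / M + 1 + a
    E[z1_j z2_j] = sqrt(n1 n2) rho_g l_j / M + c

with `l_j` the LD score (sum of squared correlations over the SNP's LD
block, self included), `M` the number of regression SNPs, and free
intercepts absorbing confounding and sample overlap.  The genetic
correlation is `rg = rho_g / sqrt(h2_1 h2_2)`.

Estimation is two-step weighted least squares.  The first pass uses
weights `1/l_j` (correcting over-counting of correlated SNPs); the second
divides additionally by the fitted conditional variance of the response —
`2 (n h2 l/M + 1 + a)^2` for chi-square responses, and
`v1 v2 + (fitted cross moment)^2` for the product response.  The variance
term is essential, not cosmetic: high-LD SNPs carry both most of the
leverage and most of the residual variance, and a single 1/l pass leaves
the slope dominated by a handful of high-LD blocks (replicate SD of r̂g
roughly 4× larger, with a visible ratio bias, under the simulation sizes
below).

Standard errors come from a delete-one-block jackknife over contiguous SNP
blocks; for rg the jackknife re-solves all three regressions and the full
ratio per deletion.  The jackknife t-statistic is referred to a
t-distribution with (blocks − 1) df: with ~50 blocks the normal reference
is measurably anti-conservative (type-I 0.058 instead of 0.050 at
alpha = 0.05 in the null calibration simulation), while for the default
200 blocks t and normal are indistinguishable.  The jackknife block count
defaults to min(200, M/50); analyses of the 50-block simulated reference
align the jackknife blocks with the 50 independent LD blocks, since
jackknife chunks that split an LD block violate the independence the
jackknife assumes.  rg is clipped to [−1, 1] only for reporting; raw
values are retained.  Per-chromosome rg simply applies the same fit within
each chromosome, with degenerate chromosomes skipped.

## Gene-based SNP-set test

The gene statistic is `T = sum z_j^2` over the gene's SNPs (explicit
SNP-to-gene map, or interval membership with a configurable window,
default 0 kb).  Under the null, `z ~ N(0, R)` with R the gene's LD
submatrix, so T is a weighted chi-square sum with weights the eigenvalues
of R (floored at 1e-10 to repair indefinite submatrices).  P-values use
Imhof's exact numerical inversion of the characteristic function; the
integral is split at ~8π/T and the oscillatory tail is handed to
QUADPACK's Fourier integrator, which keeps the method exact and
warning-free out to p ≈ 1e-12 (beyond that a Satterthwaite tail keeps
extreme genes ordered).  Two-moment Satterthwaite matching (scale
`Σλ²/Σλ`, df `(Σλ)²/Σλ²`) is retained as a fast approximation; it is
accurate to a few percent in the moderate tail but, measured against the
exact inversion on a 5-SNP AR(1) ρ=0.9 gene, its relative error crosses
10% below p ≈ 0.012 and reaches ~25% at p ≈ 0.002 — which is why the
exact method is the default for discovery.

Genomic control maps each gene p-value to a 1-df chi-square equivalent
(well defined across genes with different effective df), computes
`lambda = median / 0.4549`, and deflates only when lambda exceeds 1.05.

## Composite-null pleiotropy test

A gene is pleiotropic when associated with both traits (H11).  The
composite null is the union of H00 (both null), H01 (trait 1 null only)
and H10 (trait 2 null only).  With `t = max(p1, p2)`, the null CDF under
the three-component mixture gives the p-value

    p = [ (pi01 + pi10) t + pi00 t^2 ] / (pi00 + pi01 + pi10),

exact when null p-values are uniform within each component.  Mixture
weights come from the two marginal Storey null proportions (grid
λ = 0.05…0.95, cubic smoother read off at λ = 0.5 — the conventional
endpoint extrapolation is far noisier at a few thousand genes) under a
product (independence) decomposition; the four weights are clipped and
renormalized.  Discoveries use Benjamini–Hochberg at FDR 0.05.

Two design points deserve emphasis.  First, the naive `t^2` calibration
(valid only under pure H00) is anti-conservative under the mixture: in the
calibration simulation its BH FDR inflates to ~0.30 at a nominal 0.05.
Second, because both the mixture p-value and `t^2` are monotone in t, any
comparison "at exactly matched realized FDR" forces identical rejection
sets; the meaningful comparison is against the *valid* distribution-free
max-P calibration `p = t` (the worst-case composite-null bound), which the
mixture test strictly dominates in power at the same controlled FDR —
roughly 0.70 vs 0.37 under the planted mixture
(π = 0.85/0.07/0.07/0.01, 5000 genes, signal mean 4 on the z scale).

Per-gene effect-size correlation is the Pearson correlation of the two
traits' harmonized raw betas over the gene's local SNPs (≥ 3 SNPs
required; LD-induced correlation between neighbouring SNPs is deliberately
not adjusted for — the quantity is descriptive).  Set comparison reports
the shared genes, the correlation between the two sets' per-gene effect
correlations, and each set's fraction of positive correlations.

## Mendelian randomization

Instrument selection is greedy LD clumping: candidates below the p
threshold in ascending p order, accepted when r² with every accepted SNP
within the window is below the r² threshold (defaults 5e-8 / 0.001 /
1 Mb; the birthweight exposure uses its dedicated thresholds 6.6e-9 /
0.10).  Birthweight instruments are classified by which genetic component
drives them — fetal-specific, maternal-specific, shared same/opposite
direction (both significant, by sign agreement), or unclassified (excluded
from both sets).  The significance rule is a configurable p threshold
(default 5e-8); the classification rule is an assumption of this package.
A Bonferroni screen removes candidate instruments associated with the
competing upstream trait at p < 0.05/m (m = candidate count).

Estimators (all invariant to instrument order and to joint per-SNP sign
flips):

* **IVW** — weighted regression of outcome on exposure betas through the
  origin, weights 1/se_y²; multiplicative random-effects SE inflation
  sqrt(Q/(J−1)) when Cochran's Q exceeds its df (default), fixed-effects
  variant available.
* **MR-Egger** — adds a free intercept after re-orienting exposure betas
  non-negative; the intercept estimates directional pleiotropy; inference
  by t with J−2 df and residual variance floored at 1.
* **Weighted median** — weighted empirical median of Wald ratios
  (first-order inverse-variance weights se_y²/beta_x²), linear CDF
  interpolation at 0.5; SE by seeded parametric bootstrap (default 1000
  draws).  Consistent while valid instruments hold > 50% of the weight;
  under one-sided contamination its limit shifts by about one ratio-noise
  SD, so scenarios exercising it keep ratio noise small.
* **Maximum likelihood** — joint normal likelihood of (beta_x, beta_y)
  around (xi_j, beta xi_j), profiled over the nuisance xi_j, BFGS from the
  IVW start, SE from the numerical observed information of the profile.
* **MR-PRESSO** — residual sum of squares with leave-one-out IVW slopes;
  the global p compares the observed RSS with parametric simulations of
  the no-pleiotropy model; per-SNP outlier p-values from each SNP's
  simulated residual distribution, Bonferroni-adjusted at 0.05; the
  corrected estimate is IVW after outlier removal (identical to the
  uncorrected fit when nothing is flagged).
* **Multivariable IVW** — weighted multiple regression of outcome betas on
  all exposure beta columns without intercept; collapses exactly to IVW
  for one exposure.

Binary-outcome power uses
`Phi( sqrt(n r2 K (1−K)) |log OR| − z_{1−alpha/2} )` with K the case
fraction and r² the instrument-explained exposure variance.  The case
fraction and instrument r² behind the reference power figures are not
determinable from summary statistics alone; the values shipped
(K = 0.5, r² = 0.0088 and 0.0125) are admissible calibrations solving the
power equation at n = 266,081, OR = 0.90, and are reported as such.

## Mediation

The causal ordering is fixed: X (birthweight) → M1 (menarche) → M2
(menopause) → Y (breast cancer).  Edges: X→M1 univariable IVW; X→M2 and
M1→M2 from the two-exposure MVMR; M1→Y and M2→Y from the three-exposure
MVMR; X→Y reported as the univariable total effect.  A path mediates iff
every constituent edge is significant at alpha = 0.05 — the
joint-significance rule, with no multiple-testing correction across edges
and deliberately no formal indirect-effect estimator (no product method,
no Sobel test).  Under the global null the three-edge verdict fires at
about alpha³.  The effect graph is serialized to DOT (solid = significant,
dashed = not) and rendered with matplotlib.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of a config and an explicit
`numpy.random.Generator`; identical seeds give identical bytes.

* **LD reference** — AR(1) blocks, zero correlation across blocks, 22
  pseudo-chromosomes round-robin.  `block_rho` may be a single value or a
  (low, high) range giving an equally spaced per-block grid; the default
  range (0.0, 0.95) emulates regional LD variability and spreads the LD
  scores over ~1–19.  This heterogeneity is statistically load-bearing:
  with one common AR(1) parameter the LD scores span a narrow band and the
  LDSC slope is barely identified.
* **Paired traits** — standardized per-SNP effects drawn jointly with
  covariance `[[h2_1, c],[c, h2_2]]/M`, `c = rg sqrt(h2_1 h2_2)`; observed
  `z = sqrt(n) R beta + e` with block-correlated noise and an optional
  cross-trait noise correlation `rho n_overlap / sqrt(n1 n2)` emulating
  sample overlap.  Betas are emitted per-allele using simulated allele
  frequencies so harmonization is exercised.  Defaults: M = 5000, 50
  blocks, h² = 0.3, n = 50,000 — sizes chosen for test power and
  desk-scale runtimes, not to mimic any real trait.
* **Fetal/maternal pair** — per-SNP true effects bivariate with
  correlation `fm_corr` (default −0.6; the two components pull in opposite
  directions), emitted as if already decomposed into the two components
  (the decomposition of own/offspring GWAS into fetal and maternal effects
  is upstream of this package and out of scope).
* **Planted genes** — genes labeled H00/H01/H10/H11; H11 genes get local
  SNP effects with controlled correlation (default magnitude 0.8) of a
  requested sign; truth labels are returned for calibration tests.
* **Causal chain** — instrument-level only: three instrument groups (for
  X, M1, M2), path coefficients defaulting to 0.09 / 0.11 / 0.10 with no
  direct X→Y effect, GWAS sizes defaulting to the source studies'
  (264,498 / 329,345 / 69,360 / 266,081), standardized observation noise
  1/sqrt(n), optional horizontal pleiotropy on X's instruments and planted
  outlier instruments with inflated outcome effects.  Y lives directly on
  the log-odds summary-statistic scale; no individual-level liability is
  simulated because the pipeline never consumes one.
* **Instrument panel** — a fetal/maternal birthweight panel with planted
  class composition 63/31/26/15 (+71 unclassifiable), used to verify the
  classification bookkeeping end to end.

What passing tests therefore show: estimator correctness, calibration and
power under the generative models above.  What they do not show: behaviour
under real LD (long-range, admixture), allele-frequency-dependent
architectures, binary-trait liability effects, sample-overlap beyond the
intercept term, or misspecified gene boundaries.

## Numerical choices

Eigenvalue floor 1e-10; Imhof truncation error below 1e-12 with fallback
ordering below p = 1e-12; LDSC second-step variance floor 0.5; weighted
median bootstrap seeds explicit everywhere; mixture weights clipped to
[0, 1] and renormalized; BH q-values via statsmodels.  Simulation sizes in
tests (150–500 replicates per operating characteristic) were chosen so
Monte-Carlo error is several times smaller than each tolerance being
asserted.

## Known limitations

No liftover, INDELs, or imputation; no annotation-stratified LDSC or
constrained-intercept mode; no competitive gene-set enrichment; no
colocalization; no CAUSE/contamination-mixture MR or nonlinear MR; no
formal mediation effect decomposition.  The pleiotropy mixture estimator
assumes independence of the two traits' null indicators when factorizing
the joint composition; correlated gene-level nulls (e.g. from shared
sample overlap) would bias the weights.
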