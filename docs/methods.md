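# Methods

## Model

The association model is ordinary least squares throughout.  For marker
`j` the scan fits

    y_i = μ + Σ_c x_ic a_c + Σ_l S*_il b_l + S_ij d_j + e_i,
    e_i ~ N(0, σ²_e)

with `x_ic` the common covariates (principal components, etc.), `S*_il`
the current pseudo-QTN dosages and `S_ij` the tested marker's dosage
(0/1/2 counts of the alternate allele, mean-imputed where missing).  The
reported P value is the two-sided t test on `d_j` with
`df = n − (fitted columns) − 1`.  An intercept is always included and
never penalised; the phenotype is not centred by contract, so the model
must carry its own location term.

The covariates-only model (the scan model without the tested-marker term)
supplies the deviance used for model-size selection,

    −2LL = n·(ln(2π·RSS/n) + 1),

i.e. the Gaussian likelihood with the residual variance profiled out at
its maximum-likelihood value RSS/n.  ML rather than REML is deliberate:
the whole point of the construction is that fixed-effect likelihoods are
cheap and directly comparable across nested model sizes.

Pseudo-QTN selection minimises, over k = 0..t nested models,

    BIC(k)  = −2LL(k) + f·k·ln(n)        (default f = 2)
    AIC(k)  = −2LL(k) + 2k
    eBIC(k) = BIC(k) + 2γ·ln C(M, k)     (default γ = 0.5)

`k` counts pseudo QTNs only.  The default penalty coefficient of 2 per
parameter (twice the textbook BIC) is the method's published form and is
kept as the default; `bic_penalty_factor=1` restores the standard BIC.
The eBIC combinatorial term uses the total scanned marker count M as the
predictor-space size.

## The iteration

Iteration 1 scans with an empty pseudo-QTN set (a plain covariates-only
GLM scan).  Each iteration then applies: Bonferroni candidate filter
(`P ≤ α/M`, α = 0.01), greedy LD pruning at |r| > 0.7, criterion search
over nested k.  The loop stops when two consecutive pseudo-QTN sets are
identical (converged), when any previously seen set is revisited (cycle —
the best-criterion set seen is kept), or at `max_iterations` (default 10).
Neither termination nor acyclicity is guaranteed in principle, hence the
two guards.  The final report re-runs the scan under the accepted set so
reported P values always correspond to the final model.

A marker that *is* a pseudo QTN would be exactly collinear with its own
covariate; for its own test (and for any marker exactly collinear with a
pseudo QTN) the offending pseudo QTN is dropped from the covariate block.
Markers merely in high-but-imperfect LD with a pseudo QTN are tested
against the full covariate set.  Constant or covariate-collinear markers
get an undefined (NaN) P value, printed as NA.

## Numerical strategy

The covariate block is orthonormalised once per iteration (Gram–Schmidt
with reorthogonalisation on the full design); each marker test is then a
simple regression of residualised phenotype on residualised marker
(Frisch–Waugh–Lovell), vectorised over all M markers.  This is required
to agree with a full per-marker OLS refit to 1e−10, and the test suite
enforces that bound against an independent normal-equations oracle.

The nested k-search reuses the same idea incrementally: each accepted
candidate column is orthogonalised against the current basis and reduces
RSS by exactly (qᵀy)², so the −2LL trace is non-increasing in k by
construction, an exact property the tests assert on every trace.  A
candidate column numerically in the span of the design (relative residual
norm ≤ 1e−9) is flagged and dropped — first occurrence kept — never
silently fitted.  RSS is floored at 1e−12·max(yᵀy, 1) before logs;
fits at the floor are flagged as perfect.  Criterion ties go to the
smaller k.  The candidate list is capped at n − c − 2 so every fit keeps
at least one residual degree of freedom.

## Data handling

Genotypes are markers × individuals, int8, with −9 as the missing
sentinel; text dialects accept NA, N, −9 and "." (any unknown token also
reads as missing).  Positions are 1-based base pairs, and all distance
arithmetic is in base pairs.  MAF filtering removes markers whose minor
allele frequency is *at or below* the threshold (default 5%).  Mean
imputation is the default inside all numerics (it preserves Pearson
correlations and keeps OLS well conditioned); modal ("major allele")
imputation is available where integer codes must be preserved.  Sample
alignment takes the sorted intersection of individual ids and drops
missing phenotypes, so run order never depends on input order.

## Simulation

`simulate_genotypes` draws each marker's alternate-allele frequency
uniformly (default 0.05–0.5) and individual codes as Binomial(2, freq):
independent biallelic SNPs in Hardy–Weinberg proportions, placed uniformly
on a uniform marker map (default 10 chromosomes × 50 Mb, chosen so a
10,000-marker genome has ~50 kb marker spacing and 300-kb clustering is
comfortably feasible).  Optional population structure uses the
Balding–Nichols construction (per-subpopulation Beta-distributed
frequencies around the global frequency).

`simulate_phenotype` gives each causal marker a Normal(0, 1) effect
(`effect_sd` tunable; only the variance ratio matters), sums dosages to a
genetic value, and adds Normal residuals with variance
`var(g)·(1−h²)/h²`, where var(g) is the *realised* genetic variance
across individuals.  The assigned additive-variance proportion therefore
equals h² exactly, while the realised ratio var(g)/var(y) scatters around
it through the finite residual draw — over 200 replicates at n = 1000 its
mean sits within one percentage point of the 75% target, which is what
the acceptance script measures.  Clustered causal sampling draws anchor
markers and pairs each with a marker within 300 kb (default) on the same
chromosome; an anchor with no eligible partner is redrawn, and the
operation fails loudly if the map cannot support the requested distance.

What the simulator does *not* emulate: linkage disequilibrium between
non-causal markers (each marker is independent), realistic allele-
frequency spectra, dominance/epistasis, and case–control liability.
Passing tests on these data therefore demonstrate the mechanics and the
calibration of the method under an idealised architecture, not its
behaviour on real LD structure.

## Evaluation

Markers are grouped into fixed-width bins keyed by
(chromosome, ⌊(position−1)/width⌋); a bin is a QTN bin if it contains a
causal marker, and its P value is the minimum over members.  Sweeping the
distinct bin P values as thresholds yields power (true-positive bins /
QTN bins) against FDR (false-positive bins / declared bins; 0 when
nothing is declared) or type I error (false-positive bins / non-QTN
bins).  Curves are closed at (0, 0), take the running-max power envelope
over cost, extend horizontally to cost 1, and are integrated by the
trapezoid rule — interpolation is not defined by the counting procedure
itself, so the trapezoid is a package choice.  Default report bin width
is 10 kb, with 1 bp / 1 kb / 100 kb also emitted.

The enrichment null is Binomial(n_loci, region_fraction) in closed form
(default), or a Monte-Carlo resampling of locus sets against a
genome-sized mask of the same coverage; the two agree within Monte-Carlo
error and the tests check this.  Overlap counting is inclusive at the
window boundary (a locus exactly `window_bp` from a gene counts).

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `maf_threshold` | 0.05 | markers with MAF ≤ this are dropped |
| `alpha` | 0.01 | Bonferroni level, candidate filter and final call |
| `ld_threshold` | 0.7 | \|r\| above which candidates are merged |
| `criterion` | `bic` | model-size criterion (`aic`, `ebic` available) |
| `bic_penalty_factor` | 2 | per-parameter penalty coefficient |
| `max_iterations` | 10 | outer-loop cap |
| cluster distance | 300 kb | QTN pairing distance in clustered simulation |
| report bin | 10 kb | evaluation bin width (1 bp/1 kb/100 kb also used) |

All thresholds live in `BlinkConfig`; no module hard-codes its own.

## Problem sizes

The test suite and the acceptance script run at desk scale: the
heritability check uses 200 replicates of n = 1000 × 10,000 markers; the
clustered-architecture power comparison uses 50 replicates of
n = 500 × 5,000 markers with 20 causal markers; null calibration uses 100
replicates of 10,000-marker scans at n = 100.  These sizes preserve the
statistical structure of the design while keeping a full run to a few
minutes on one core.

## Known limitations

* Binary traits are treated as numeric 0/1 in the linear FEM; no logistic
  scan.
* No mixed-model (kinship) option, by design.
* LD is computed as plain Pearson correlation on dosages over the full
  analysed sample; no subsampling shortcut is implemented.
* The PLINK reader handles variant-major `.bed` only (the modern layout);
  sample-major files are rejected.
* One trait per run; loop in the shell for multi-trait studies.
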