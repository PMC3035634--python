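# Methods

## The model

`mmgsa` screens predefined gene sets for joint differential expression
between two groups (cases vs controls) in a normalized log2 expression
matrix. For one gene set with genes g = 1..G and samples s = 1..n, the
outcome is the long vector of member-gene expression values and the model is

    y_gs = mu + beta * 1[group(s) = case] + b_batch(s) + u_subject(s)
           + sum_{k=1..K} a_{s,k} E_{g,k} + eps_gs

with mutually independent random terms

    b_batch  ~ N(0, sigma_b^2)   one intercept per hybridization batch
    u_subj   ~ N(0, sigma_u^2)   one intercept per subject
    a_{s,k}  ~ N(0, sigma_k^2)   one coefficient per sample and component
    eps_gs   ~ N(0, sigma^2)     residual

`E` holds eigenvectors of the within-set gene–gene correlation matrix, so
the induced covariance among a sample's genes is

    sigma_u^2 * J  +  sum_k sigma_k^2 * E_k E_k'  +  sigma^2 * I ,

i.e. an equicorrelated component (subject), a low-rank co-expression
component, and independent noise. The group effect `beta` is a single
log2-scale shift shared by all member genes — the "self-contained" gene set
hypothesis that weak, concordant signals across a set add up. Control is
the reference level, so beta > 0 means higher expression in cases ("up").

The correlation matrix is estimated on *group-mean-centered* residuals so a
real group shift is not mistaken for gene–gene correlation. Eigenvectors
are retained up to `K_max` (default 5) or until they cumulatively explain
`explain_frac` (default 80%) of the trace, whichever is smaller.

### Restriction of the loadings to the mean-orthogonal subspace

The eigenvectors are estimated from the same data the model is then fitted
to. Their overlap with the constant gene direction 1_G is exactly the
direction that carries the group contrast (the set-average expression per
sample), and treating overfitted data-driven loadings as known lets the
factor terms absorb set-average variance that belongs to the subject
component, deflating the standard error of beta. In simulation this
inflated the null rejection rate at alpha = 0.05 from the nominal 0.05 to
about 0.10 (n = 20 per group), while fits with the *true* loadings or with
no factor terms were exactly calibrated. `mmgsa` therefore projects 1_G out
of the estimated loadings (dropping components nearly parallel to it, which
merely duplicate the subject intercept) before building the factor design.
The subject component then carries all set-average variance; the factor
terms model the co-expression structure orthogonal to the contrast. This
restores the nominal level at a small cost in efficiency relative to an
(unavailable) fit with known loadings.

## Estimation and testing

Variance components are estimated by REML. The likelihood is evaluated
after projecting each sample's G-vector onto an orthonormal basis of
span{1_G, E}: the orthogonal complement contributes only a residual sum of
squares with n(G - rank) degrees of freedom, the residual variance is
profiled out analytically, and the remaining parameters are variance ratios
optimized on the log scale (bounded below at `variance_floor`, default
1e-8; boundary fits mean the component is effectively absent). The
projected covariance factorizes into an (r-1)x(r-1) within-sample block and
an n x n coordinate-1 Schur complement, so one evaluation costs
O(n^3 + n r^2) regardless of set size. Optimization uses L-BFGS-B with the
analytic gradient of the profiled objective (verified against finite
differences); two fixed starts guard against local optima, and convergence
failures are reported per set (`converged = False`) without aborting a
screen.

Three group tests are available (`ModelSpec.test`):

* `"t"` (default): Wald t statistic beta_hat / se(beta_hat) at the REML
  fit with between-subject denominator degrees of freedom
  (n_subjects - 2). Group is a between-subject effect in this design, and
  with one gene, one batch and no factor terms this reduces *exactly* to
  the pooled two-sample t-test — the profiled-likelihood construction makes
  the reduction an identity rather than an approximation. This also mirrors
  how the classical mixed-model software used for such screens tests fixed
  effects (REML fits with denominator-df t/F statistics) rather than
  asymptotic chi-square references, which are anticonservative at a dozen
  arrays.
* `"lrt"`: both nested models refit by full ML, deviance referred to
  chi2(1).
* `"wald"`: the squared Wald statistic referred to chi2(1).

Raw p-values across all screened sets (never a displayed subset) are
adjusted with the Benjamini–Hochberg step-up procedure; the screen table is
sorted by ascending raw p with ties broken by set name. Gene-level
follow-up uses the single-gene reduction of the same model, with direction
called from the sign of the raw case-minus-control mean difference, and an
unadjusted reporting threshold alpha (default 0.05) — a reporting choice,
not a family-wise inferential claim.

## qPCR quantification

The confirmation stage implements the comparative-Ct method with
amplification efficiency fixed at 2 (no standard-curve calibration):
replicates are averaged on the Ct scale, delta-Ct = mean Ct(target) - mean
Ct(reference), relative expression = 2^(-dCt), and fold changes between
conditions are 2^(-ddCt). Group comparisons use Welch's t-test, by default
on the log scale (delta-Ct), since 2^(-dCt) is log-normal-like; a raw-scale
option is retained.

## The synthetic-data generator

`simulate_dataset` runs the fitted model forward: per set it draws a random
orthonormal G x K_true loading matrix (so the factor structure the
eigendecomposition should discover is present by construction), adds batch
and subject intercepts shared across sets (array-wide effects), and shifts
every gene of a designated non-null set by `delta` log2 units in cases.
Sets are disjoint; batches are assigned round-robin within each group so
group and batch stay balanced unless deliberately confounded.

Defaults (chosen once as realistic two-batch log2-microarray conditions):
8 cases vs 4 controls; 2 batches; batch SD 0.2, subject SD 0.3, residual
SD 0.5 (log2 units); K_true = 2 with factor SDs 0.5 and 0.3; 20 sets of 20
genes; 10% non-null with delta = 1.0; baseline 7.0. `simulate_qpcr` draws
reference Ct ~ N(20, 0.2), per-sample delta-Ct ~ N(5, sd) with a case
shift, and triplicate jitter N(0, 0.1).

What the generator does *not* emulate: probe-level array artifacts,
normalization residue, overlapping sets, gene-specific effect sizes within
a set, heavy-tailed noise, or real GO set-size distributions. Passing
operating-characteristic tests on these simulations demonstrates internal
consistency of model, fitter and tests under the assumed covariance
structure — not robustness to real-data violations of it.

Because subject and batch draws are shared across the sets of one simulated
dataset (as they are across the genes of one array), set-level rejections
within a single dataset are conditional on that draw. Level/power checks
therefore use independent single-set replicate datasets; FDR checks use
whole screens, averaged over independently seeded screens.

## Numerical and design choices

* One subject per sample is the cross-sectional default, but the subject
  random intercept is kept distinct from the residual so repeated-measures
  designs work unchanged; with one sample per subject, sigma_u^2 and
  sigma^2 are separately unidentified while their sum — all the test needs
  — is identified, and the profiled objective is exactly flat along the
  ridge.
* Genes with zero within-group variance are dropped from a set with a
  warning (they break the correlation estimate); an all-constant outcome is
  a degenerate-input error.
* Minimum measured set size defaults to 5 — small enough not to exclude
  anything a screen would report, large enough to avoid degenerate
  correlation estimates.
* Monte-Carlo problem sizes in the test-suite and acceptance script
  (replicate counts, screens of 200 sets, n = 12–100 samples) were chosen
  so each check resolves its target quantity at the Monte-Carlo rate.
* P-values are printed with 4 significant digits in human tables; full
  precision is preserved in `screen_full.tsv` and the JSON manifest.

## Known limitations

* Estimated (rather than known) loadings cost some power after the
  mean-orthogonal restriction; competitive (GSEA-style) alternatives and
  permutation reference distributions are out of scope.
* The between-subject df choice is exact for balanced single-batch designs
  and an approximation otherwise (no Satterthwaite/Kenward-Roger
  correction).
* Overlapping gene sets are screened independently; no cross-set
  dependence adjustment beyond BH.
* Gene identifiers are matched case-sensitively with no alias resolution.
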