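# Methods

## Model and procedure

For each molecular phenotype *P* quantified in *N* samples, the mapper
considers the *L* variant dosages within ±W bp of the phenotype's anchor
(default W = 1,000,000; the anchor is the BED start interpreted as a
1-based TSS-style coordinate, and signed distances are variant POS −
anchor). The nominal pass computes Pearson correlations r_j between *P*
and every variant, keeps the argmax of |r| (exact ties go to the lowest
genomic position, making runs deterministic), and converts it to a
two-sided P-value via t = r·√(df/(1−r²)). This is algebraically the
t test of the slope in the single-variant least-squares regression
*P = βg + ε*; the reported slope is r·sd(P)/sd(g) on the analysis scale
(i.e. after any normalization/residualization). 1−r² is floored at
1e-16 so |r| → 1 yields the smallest positive double rather than 0.

Degrees of freedom default to N − 2 − C when C covariate dimensions have
been residualized out; under-counting the lost dimensions inflates
significance. A `legacy_df` option keeps N − 2 for compatibility with
tools that ignore the correction.

## Preprocessing

* **Quantile normalization** (optional, `--normal`): rank-based inverse
  normal transform with offset rank/(n+1), average ranks for ties (a
  seeded random tie-break is available), rescaled to mean 0 and sample
  sd 1. Constant vectors are rejected: ranks are undefined.
* **Residualization**: genotypes and phenotypes are both projected onto
  the orthogonal complement of the covariates plus an intercept, so the
  correlation of residuals is the partial correlation. Collinear
  covariate columns are detected by rank-revealing QR and dropped with a
  warning rather than failing the run.

## Permutation schemes

Permutations shuffle the phenotype only, leaving the genotype matrix
intact so the LD structure of the null is exactly that of the data.
Because the genotype rows are standardized once, each permutation scan
is a single matrix–vector product; permutations are processed in
batches as one matrix–matrix product.

* **Direct**: p_d = (r+1)/(R+1) with r the number of null best P-values
  ≤ the nominal one (ties count as exceedances — conservative). The
  estimate cannot fall below 1/(R+1).
* **Adaptive**: batches of permutations (default 100 per batch) until B
  exceedances (default 100) or M permutations (default 100,000);
  p_a = (min(r,B)+1)/(min(R,M)+1). When the B-th exceedance falls inside
  a batch, counting is truncated at that permutation so the scheme is
  exactly equivalent to one-at-a-time stopping; applying the formula to
  a full overshooting batch would bias the estimate downward.
* **Beta**: the best P-value from n independent uniform tests is
  Beta(1, n); with LD the effective n is below L, so both shapes are
  fitted by maximum likelihood to the R null minima (R defaults to
  1000; 100 is permitted). The log-likelihood
  (k−1)Σln p + (n−1)Σln(1−p) − R·ln B(k,n) is maximized by L-BFGS-B on
  (log k, log n) — positivity for free, analytic gradients via the
  digamma function — started from method-of-moments estimates, with
  convergence tolerance 1e-8 and up to three deterministically jittered
  restarts. P-values are clamped to [1e-300, 1−1e-16] before logs. The
  adjusted P is the regularized incomplete beta I_{p_n}(k̂, n̂); when
  the direct CDF underflows, the leading-order term
  exp(k·ln x − ln k − ln B(k,n)) keeps values down to ~1e-200 nonzero.
  The fitted k̂ is interpretable as the rank of the best variant
  (centering on 1), n̂ as the effective number of independent tests.

Every phenotype draws permutations from its own RNG substream seeded by
(run seed, SHA-256 of the phenotype id), so results are independent of
phenotype order and chunk boundaries: concatenated per-chunk outputs are
byte-identical to a whole run.

## FDR across phenotypes

π0(λ) = #{p > λ}/(m(1−λ)) is evaluated on λ = 0.05…0.95 (step 0.05) and
smoothed by a least-squares cubic smoothing spline evaluated at the
largest λ, then clamped to (0, 1]; an interpolating spline would simply
return the noisiest raw estimate, so the smoothing fit is the point of
the convention. A fixed-λ fallback (λ = 0.5) is provided for small
panels where spline fitting is unstable. q-values are the π0-scaled
step-up minima q_(i) = min_{j≥i} π0·m·p_(j)/j; with π0 = 1 this is
exactly Benjamini–Hochberg, and with π0 < 1 the calls are a superset of
BH at the same level. The significance threshold reported is the
largest adjusted P among called phenotypes.

## Synthetic data

The generator emulates the three input files with known truth. Dosages
come from a Gaussian-copula model: two latent AR(1) chains per sample
(correlation `ld_rho` between adjacent variants), thresholded at the
quantile of each variant's MAF (sampled uniformly, default 0.05–0.5) and
summed — Hardy–Weinberg genotypes whose adjacent-dosage correlation
rises with `ld_rho`. Phenotypes are slope·dosage + optional covariate
contributions + Gaussian noise (default sd 1); defaults use 300 samples,
50 variants and 20 phenotypes, a scale typical of a single cis-window in
population eQTL panels. Anchors sit on the planted variant so it is
always inside the window.

What this does **not** emulate: realistic recombination-driven LD decay
(AR(1) is geometric by construction), allele-frequency spectra from
demography, phenotype heteroskedasticity, outliers, or shared latent
confounders across many phenotypes. Passing calibration tests on these
fixtures therefore demonstrates the statistical machinery under a clean
additive model, not robustness to every artifact of real assays — the
quantile-normalization and covariate options exist precisely for those.

## Numerical and design choices

* Dosage source: the VCF DS field when present, else the GT
  alternate-allele count; missing calls are mean-imputed by default
  (preserving N), with a drop-sample policy available.
* Monomorphic (zero-variance) variants are always removed and counted;
  the MAF filter defaults to 0 (no filtering beyond zero variance).
* Region semantics: a query returns exactly the variants a full scan
  plus in-memory filter would; compressed files need a Tabix/CSI index
  for region queries, plain files are scanned.
* Chunking partitions coordinate-sorted phenotypes into contiguous,
  near-equal groups (larger groups first); phenotypes sharing an anchor
  are never split across chunks.
* The exceedance comparison is on the P-value scale (null p ≤ nominal
  p), equivalent to the |r| scale at fixed df but unambiguous.

## Test and verification scale

The statistical suites run at desk scale chosen by the package: null
calibration uses 200 phenotypes at R = 300 (direct/beta) and B = 100,
M = 2000 (adaptive); the beta-vs-direct concordance check compares
R = 1000 beta fits against R = 10,000 direct runs over 60 mixed
phenotypes, using the 95% binomial envelope expected of a
1000-permutation estimate around the long-run value; the k̂-centering
check fits 200 batteries of 1000 minima of 100 independent uniforms.
FDR control is verified over 200 mixture replicates against the target
level plus three Monte-Carlo standard errors.

## Known limitations

* Single-chromosome whole-file VCF reads; genome-wide analyses go
  through per-chromosome region queries (as the chunked CLI does).
* No BCF, phased-haplotype, or multi-allelic handling; multi-allelic
  records contribute their first ALT only.
* The beta tail extrapolation is only as good as the Beta(k, n) fit;
  goodness-of-fit on held-out permutations is part of the test suite,
  but pathological windows (e.g. a single near-monomorphic variant) can
  defeat it.
* π0 estimation needs a few hundred phenotypes to be stable; below 100
  a warning suggests the fixed-λ estimate.
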