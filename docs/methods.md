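# Methods

## Model and hypotheses

The input is gene expression measured at two timepoints for the same
individuals and genes, with individuals split into two groups A and B and
with each individual's age known. The first step reduces the two-endpoint
problem to one scalar per individual and gene: the *contrast*

    Y[k, j] = R[k, j] - S[k, j],

the timepoint-2 minus timepoint-1 expression difference, computed per group
after aligning rows and columns by sample id and gene name (never by
position: differently sorted files would otherwise silently corrupt every
contrast). For each gene j and group i the contrast is regressed on age with
intercept,

    Y[:, j] = slope_ij * age + intercept_ij + noise,

by ordinary least squares with centered sums of squares. The intercept —
the expected contrast at age zero — is the parameter of interest: a nonzero
value indicates a departure from baseline not explained by age.

Two hypotheses are tested per gene:

* **Null family (group A).** H_j: intercept_1j = 0 against a two-sided
  complement. With t = intercept / SE(intercept) and
  SE = s * sqrt(1/n + abar^2 / S_aa), s^2 = RSS/(n-2), the p-value is
  p_j = 2 * F_{n1-2}(-|t|), F the t CDF.
* **Alternative family (group B).** A one-sided upper-tail test at a
  gene-specific level lambda_j: since "intercept > lambda" is equivalent to
  "intercept - lambda > 0", the statistic is the standard shifted t,
  t_shift = (intercept - lambda_j) / SE(intercept), and
  p~_j = 1 - F_{n2-2}(t_shift).

Genes rejected in *both* families — baseline departure detected in group A
and the calibrated alternative-level test significant in group B — are the
reported findings.

## Calibration of the alternative level

lambda_j is defined by degrading the group-B fit: holding the slope at its
least-squares value, the intercept is moved away from its estimate b_hat
until the R² of the modified fit drops to a fraction pi of the original.
Because least-squares residuals sum to zero,

    R²(b) = 1 - (RSS + n (b - b_hat)²) / TSS,

a downward-opening quadratic in b, so the target R²-fraction pi has exactly
two roots,

    lambda = b_hat -/+ sqrt((1 - pi) R² TSS / n).

The closed form is the default (exact, O(1)); a geometric-bracketing
bisection over the same quadratic (tolerance |ΔR²| ≤ 1e-10, bracket width
≤ 1e-12) is retained as an independently coded verification path. Which
root becomes the level is genuinely open — nothing in the construction
prefers one side — so it is a configuration option; the default is the root
*below* the fitted intercept, which makes t_shift = sqrt((1-pi) R² TSS/n)/SE
positive for every calibrated gene and so places every alternative p-value
below one half. Genes whose fit is degenerate or has R² ≤ 0 cannot be
calibrated; they keep lambda = b_hat and are marked non-converged, so the
downstream test sees a zero shift (degenerate fits additionally force
p~ = 1, see the edge cases below).

## Multiple testing

The 2m p-values are corrected as two separate families of m at level
alpha/2 each, which keeps the overall type-I budget at alpha. Either
Bonferroni (FWER control) or Benjamini–Hochberg (FDR control) is applied
within each family — the findings table records which, since the two modes
carry different guarantees. BH ties share fate: every p equal to the
critical sorted value is rejected. The BH step-up itself is delegated to
statsmodels' `multipletests`; tests check it against an exhaustive step-up
enumeration.

## Tunable parameters

| parameter    | default       | units     | why |
|--------------|---------------|-----------|-----|
| `alpha`      | 0.05          | —         | conventional overall type-I budget; each family is tested at `alpha/2` |
| `pi`         | 0.35          | fraction of R² | the retained explanatory fraction defining the level; an application-motivated but essentially arbitrary choice, exposed as config |
| `correction` | `bh`          | —         | FDR is the usual disclosure mode for gene panels; `bonferroni` available |
| `direction`  | `below`       | —         | which calibration root becomes the level (see above) |
| `method`     | `closed_form` | —         | exact root; `binary_search` kept as the verification path |
| `tail`       | `upper`       | —         | tail of the one-sided alternative-family test; `lower` flips it |

## Degenerate and edge cases

* A constant response column (TSS = 0) or constant age vector yields a
  flagged degenerate fit (slope 0, intercept = mean, R² = 0) rather than an
  error: one flat gene must not abort a full-panel analysis. Degenerate
  fits propagate p = 1 in both families and a non-converged calibration.
* A perfect fit (RSS = 0, SE = 0) gives p-values of exactly 0 or 1 by the
  sign of the shifted intercept, 1/2 at equality.
* Each group needs at least 3 samples (df = n - 2 ≥ 1); fewer is a
  validation error at contrast construction.
* Missing or non-numeric cells are rejected at parse time; the method has
  no missing-data model.
* Output tables serialize floats with 17 significant digits, so identical
  configurations reproduce byte-identical files.

## Synthetic data generator

`simulate.generate_parametric` emulates the motivating study design: group
sizes 22 and 23, a 469-gene panel, ages uniform on the open interval
(0, 16) years, and contrasts drawn as
`intercept + slope * age + Normal(0, noise_sd²)` with i.i.d. noise
(`noise_sd = 1` by default). Genes outside the configured signal set have a
group-A intercept of exactly zero, giving an exact null for type-I
calibration. Default parameter distributions — slopes Normal(0, 0.5), null
intercepts point-mass 0, signal intercepts Normal(2, 0.5) — are artifact
choices, configurable per run. One root seed spawns independent substreams
for ages, per-group noise, and the synthetic baseline matrix S (the data
model needs paired timepoint matrices; only the difference R - S is
scientifically meaningful, so S is Normal(8, 2) filler and R = S + contrast
by construction). Replicate seeds in the validation harness are derived
arithmetically from the root seed so replicates are independent but
reproducible.

`simulate.bootstrap_dataset` reproduces the pooled resampling scheme used to
build showcase datasets: within each group all n_i × m contrast values are
flattened into one pool and n_i × m values are redrawn i.i.d. with
replacement, deliberately destroying per-gene structure; ages are resampled
with replacement from the group's own original ages; group sizes and the
gene panel stay fixed. The result is null-like by construction.

What the generator does **not** model: sequencing-count noise (negative
binomial), library-size or batch effects, and gene–gene correlation. Tests
passing on this generator therefore demonstrate the statistical machinery
(validity of the p-value formulas, error control, bookkeeping), not
robustness to count-data artifacts — real data should be quantified and
normalized upstream.

## Known limitations and divergences

* **Step-shaped alternative p-values.** On pooled-bootstrap (null-like)
  data the sorted alternative-family p-values produced here concentrate in
  the mid-range below 0.5 rather than splitting into near-0 and near-1
  plateaus. This is a direct consequence of using the dimensionally
  consistent shifted statistic: t_shift reduces to
  sqrt((1-pi) R² (n-2) / (1 + n abar²/S_aa)), which is scale-invariant and
  cannot saturate when per-gene R² is small, as it is under a pooled
  bootstrap. A formulation that subtracts the contrast-unit level directly
  from the t statistic would saturate at 0/1 whenever |lambda| is large on
  the expression scale, but mixes units; this package deliberately does not
  do that. The mid-range fraction is reported by the acceptance script as
  an observation.
* **Directionality of the alternative.** The hypothesis placed in the null
  position for group B is the statement "intercept > lambda"; with the
  upper-tail formula, small p~ favors a large fitted intercept relative to
  the level. Users wanting the opposite reading can flip `tail`.
* The intersection report controls each family's error separately at
  alpha/2; it is not a joint test of the conjunction.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on small designs (tens of genes, n ≤ 50).
Operating-characteristic checks use the full study scale — 22 + 23
individuals by 469 genes — with 20 generator replicates for the
null-uniformity and raw type-I checks, 200 randomized fits for
calibration-root agreement, 100 random datasets for reference-OLS
agreement, and 500 random p-vectors for the multiplicity oracles. These
sizes give the checks sampling tolerances of about three standard errors
while keeping the whole suite desk-scale.
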