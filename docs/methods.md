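# Methods

## The model

`inflanet` estimates and compares *regularized partial-correlation
networks* over cytokine concentrations, individual symptom items, and
covariates. Nodes are variables; an edge weight is the regularized partial
correlation

    w_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj)

obtained from an L1-penalized precision estimate Theta. Because cytokine
concentrations are strongly right-skewed and symptom items are ordinal
Likert scores, the input to estimation is the Spearman rank correlation
matrix (average ranks on ties), repaired to positive semi-definiteness by
one pass of eigenvalue clipping with diagonal renormalization when a
pairwise-complete matrix turns out indefinite.

The precision matrix maximizes

    log det(Theta) - tr(S Theta) - lambda * sum_{i != j} |Theta_ij|

over a log-spaced path of 100 penalties from `lambda_max` (the largest
absolute off-diagonal correlation, above which the graph is empty) down to
`lambda_max / 100`. The solver is a block coordinate descent of the
Friedman type, numba-compiled and warm-started along the path; convergence
is declared when no working-covariance entry moves more than 1e-7 in a full
sweep, and entries below 1e-10 are treated as exact zeros. The compiled
path costs about a millisecond at p ~ 10, which is what makes faithful
re-estimation inside the bootstrap and permutation loops feasible.

The penalty is selected by the Extended Bayesian Information Criterion

    EBIC = -2 l + E ln(n) + 4 E gamma ln(p),
    l    = (n/2) (log det Theta - tr(S Theta)),

with E the number of nonzero upper-triangle entries. The likelihood is
evaluated on the (possibly repaired) Spearman matrix with n equal to the
subject count — a pseudo-likelihood convention, stated as such. Ties in
EBIC resolve toward the sparser (larger-penalty) model.

**The gamma default.** `gamma = 0` is the package default: it is the
discovery-oriented setting and is the replication-mode choice for this
analysis design; `gamma = 0.5` is the cautious alternative exposed
everywhere. A property worth knowing: with gamma = 0 and n large relative
to p, the EBIC curve decreases monotonically along the path, so selection
lands near the path floor and tiny spurious edges (|w| around 0.02 at
n = 2000) are admitted alongside the true structure. Exact support
recovery is therefore *not* a property of this selector; what holds, and
what the tests assert, is that true edges are always recovered and are an
order of magnitude stronger than the spurious ones, that hub nodes top the
strength-centrality ranking, and that independent data yield near-empty
graphs.

## Influence measures

Strength centrality of node i is `s_i = sum_j |w_ij|`; global strength is
the sum of absolute edge weights (half the total node strength). Influence
is ranked on z-standardized strengths (population SD; all-equal strengths
give all-zero z by convention). Because the "top scoring" criterion in
this literature is verbal rather than numeric, two explicit selection
rules are implemented and recorded in every report: `z_threshold`
(default z >= 1.0, mirroring a top-few pattern with all other nodes
substantially lower) and `top_gap` (split at the largest gap of the
sorted z sequence; no gap selects nothing). Degree fractions are reported
as 100 * partners / (p - 1), one decimal.

## Communities

Community structure is found by a signed spinglass: minimize

    H(sigma) = - sum_{i<j} [ (w+_ij - g+ p+_ij) - (w-_ij - g- p-_ij) ]
               delta(sigma_i, sigma_j)

where the weight matrix is split into positive and negative layers, each
with its own configuration-model null `p_ij = s_i s_j / (2m)` and
resolution g+ = g- = 1. Minimization is simulated annealing (Metropolis
sweeps, start temperature 1.0, stop 0.01, cooling 0.99, up to 25 spin
states) followed by a greedy descent; the best labeling visited is always
the one returned, and the stored Hamiltonian is recomputed from the final
labels so it is exactly reproducible. Consensus follows the replicable-seed
procedure: run 1000 seeds, take the *lower* median of the community counts
(so a realized count always exists), and report the first seed attaining
it; replaying that seed regenerates the identical assignment. Edgeless
networks are rejected — community analysis is undefined there.

## Accuracy and stability

*Nonparametric bootstrap* (default B = 1000): rows resampled with
replacement (stratified by arm when a treatment column is present, so
group sizes are preserved), the network re-estimated with identical
settings each time. An edge's inclusion proportion is the fraction of
bootstrap networks in which it is estimated strictly above zero; edges at
or above 50% are flagged reliable (boundary inclusive). Because that rule
is articulated for positive associations, a sign-agnostic nonzero
proportion is reported alongside. Replicates whose estimation fails are
skipped and counted; more than 10% failures aborts.

*Case-dropping bootstrap*: drop proportions 0.05–0.75 in steps of 0.10;
at each level, B subsamples without replacement of ceil((1-d) n) rows
(levels whose retained size falls below p+1 are skipped with a warning).
The CS-coefficient is the largest drop proportion at which at least 95% of
subsample strength-centrality correlations with the full sample reach
0.70; it should not fall below 0.25 and is ideally above 0.5. Centralities
are correlated with *Pearson*: a rank correlation degenerates into tie
noise when many nodes have near-equal strengths (hub-like networks), which
is also why the reference stability tooling uses product-moment
correlation here; Spearman is available via `correlation_method`. B for
the case-dropping procedure is a documented knob (default 1000).

## Network comparison

The permutation comparison estimates both networks with identical settings
and reports S = |difference in global strength| and M = max absolute
edge-weight difference. Independent designs permute pooled group labels
preserving group sizes; paired designs (used for the within-arm
baseline-vs-follow-up comparisons, flagged as such in output) swap each
subject's pair of observations with probability 1/2. Both networks are
re-estimated in every permutation. p-values use the add-one convention
(1 + #{permuted >= observed}) / (1 + B), never exactly zero. The
independent-design permutation stream is seeded from a content-ordered
pooling of the two samples, so swapping the argument order changes
nothing. Post-hoc per-node strength and per-edge invariance tests reuse
the parent permutation stream; edge p-values are Holm-adjusted by default
("none" available for literal unadjusted reporting). The pipeline runs
post-hoc tests only when an omnibus p falls below alpha (default 0.05).

A reporting note: in the published analysis this package emulates, the
printed within-minocycline S (1.73) and the "57.6% greater" /
"decreased by 61.0%" connectivity percentages do not reproduce exactly
from the printed global strengths (4.48 - 2.76 = 1.72;
(6.16 - 2.76)/6.16 = 55.2%; (4.48 - 2.76)/4.48 = 38.4%) — presumably
unrounded values and a different base were used. This package reports the
quantities recomputed from its own estimates.

## Synthetic cohorts

The generator is a Gaussian copula: latent scores are multivariate normal
with correlation equal to the standardized inverse of a planted sparse
precision matrix, then pushed through strictly monotone marginals —
`x = loc + scale exp(shape z)` (lognormal-like, skewness > 1 at the
default shape 0.8) for cytokine-like variables, ordinal-probit
thresholding for Likert items, a single threshold for binary variables.
Spearman correlation is invariant under monotone maps, so the rank
structure carries the planted partial network exactly and recovery tests
are analytic. One global seed expands into per-arm substreams via
`SeedSequence([seed, arm_index])`; identical specifications reproduce
byte-identical tables.

Planted matrices are repaired to positive definiteness, when necessary, by
uniform off-diagonal shrinkage found by bisection (eigenvalue tolerance
1e-10), targeting a 5% eigenvalue margin so the implied latent correlation
stays well-conditioned; the shrink factor is recorded, shrinkage never
inflates a planted partial, and a factor below the configured floor raises
an error naming the offending magnitude. Two-arm designs scale the arm-B
off-diagonal by an attenuation factor in [0, 1] — a convex combination
with the diagonal, hence always positive definite.

The full-study generator emulates the trial conditions: ~207 subjects
(104/103 per arm) before screening, 12 cytokines with lognormal marginals
calibrated to the published baseline means/SDs, 9 four-point depression
items, 14 seven-point psychosis items, age/sex/BMI covariates, a screening
CRP column whose lognormal marginal puts roughly 6% of subjects at or
above the 10 mg/L exclusion threshold, and a treatment column coded
1/2. The planted structure is a pro-inflammatory hub (IL-6 strongly tied
to TNF-a and IFN-g), within-instrument symptom blocks, three weak
cytokine-to-depressive-symptom bridges, and covariate edges; partial
magnitudes were sized so an n ~ 194 cohort yields estimated networks at
the connectivity scale the emulated study reports (per-arm global
strengths around 4–6, the trio selected influential, about six
communities, CS in the 0.36–0.67 range). At follow-up the active arm's
network is attenuated by 0.45, the ratio of the published 6-month group
connectivities. Baseline and follow-up are independent draws by default; a
`latent_coupling` parameter correlates a subject's latent scores across
timepoints for paired designs, with no data-derived default (the
within-subject correlation is unreported in the emulated study).

What the generator does *not* emulate: immunoassay noise (detection
limits, plate effects), longitudinal autocorrelation beyond the optional
latent coupling, missing data, and treatment effects on mean levels (only
connectivity attenuation is planted, so synthetic Network-3
treatment-cytokine edges are null by design). Passing tests therefore
show that the estimation and comparison machinery behaves correctly on
data with the trial's dimensions, marginals, and dependence scale — not
that the substantive published findings would re-emerge from new data.

## Problem sizes in the test and acceptance runs

Recovery and stability simulations use n = 2000 cohorts (20 and 10
replicates); permutation-test calibration uses 200 null replicate pairs at
n = 150/arm, p = 8 with 500 permutations, and a 30-replicate power curve
over attenuations 1.0/0.7/0.4; the exhaustive-enumeration oracle runs at
n = 6/arm, p = 3. The permutation and resampling suites and the
acceptance script use a 40-step penalty path with `min_ratio = 0.05`
(path resolution does not affect the selection behavior being tested);
the library default remains 100 steps at 0.01. The acceptance script's
end-to-end run uses B = 500 bootstrap / 250 case-dropping draws, 1000
consensus runs, and 1000 permutations per comparison.

## Known limitations

* The EBIC likelihood on a Spearman matrix is a pseudo-likelihood; no
  nonparanormal correction is applied before the graphical lasso.
* gamma = 0 selection admits trivially small spurious edges at large n
  (see above); users wanting specificity should use gamma = 0.5 and the
  bootstrap reliability rule.
* Binary nodes (sex, treatment) enter the Spearman matrix ranked like any
  column; no polychoric/polyserial correlations.
* The paired permutation scheme is one defensible reading of a
  within-group comparison over time; output flags it as the paired
  variant.
* Whether influential cytokines should be re-derived at follow-up rather
  than reused from baseline is configurable; the default reuses the
  baseline selection.
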