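# Methods

## Model

`latentrules` estimates finite-mixture ("latent class") discrete choice
models on stated-preference panels in which each latent segment may follow a
different decision rule. The data are `C` respondents, each facing `K`
scenarios of `I` unlabeled alternatives described by `M` attributes (the
emulated survey design has `I = 3`, `K = 5`, and eight underlying attributes
that dummy-code to eleven columns).

Segment membership is a multinomial logit on respondent covariates
`z_c` (intercept plus binary demographics): `P_cs ∝ exp(γ_s' z_c)`, with the
first segment's γ fixed at zero for identification. Conditional on
membership, scenario choices follow the segment's rule:

* **RUM** — linear utility `α_s' x_cik`, multinomial-logit probabilities.
* **RRM** — regret `R_cik = Σ_{j≠i} Σ_m softplus(δ_m (x_cjkm − x_cikm))`,
  logit probabilities over negated regrets. With two alternatives and one
  attribute the regret difference equals `δΔx`, so binary RRM coincides with
  binary RUM — a structural identity asserted in the tests.

Random coefficients are normal, parameterized as `β_m + σ_m ξ` with
standard-normal `ξ` — i.e. the mixing density is centered on an estimated
mean with the spread as a deviation component, which is the reading
consistent with reporting both a mean coefficient and a standard deviation
for a mixed attribute. The mixing integral is approximated by averaging over
respondent-level draws that are **reused across the respondent's K
scenarios** (panel mixing), as the product over scenarios sits inside the
integral. Draws are scrambled Halton by default (200 per respondent;
pseudo-random available), seeded and recorded in results.

## Partitioned designs and availability

The emulated survey shows only five attributes per scenario: mean exposure,
maximum exposure and travel time always, plus one roadway attribute (grade,
traffic volume, or road type) and one bike-route attribute (continuity or
segregation) rotated round-robin across respondents. Unshown attributes are
empty cells in the interchange CSV and become `availability = False`;
**unavailable attributes contribute exactly zero to both utility and
regret**. For regret this means the pairwise softplus term is dropped rather
than evaluated at a zero difference (softplus(0) = ln 2 would add an
alternative-constant that cancels in probabilities but would pollute
reported regret levels). How the original survey treated partitioned-out
attributes is not documented; zero contribution is this package's
convention, stated here explicitly.

Categorical attributes are dummy-coded by the reader with fixed base levels
(flat grade, light traffic, residential road, discontinuous, shared), so a
categorical with L levels yields L−1 columns. Numeric attributes (ppb,
minutes) pass through unscaled.

## Estimation

The log-likelihood `LL = Σ_c log Σ_s P_cs L_c|s` is evaluated in log space
(log-sum-exp over segments and over draws; softmax with max-subtraction;
softplus as `max(u,0) + log1p(exp(−|u|))`). Maximization is direct
quasi-Newton (L-BFGS-B) on the unconstrained flat parameter vector — mixing
spreads enter as `log σ` so positivity holds by construction. EM was
deliberately not used: with mixing the M-step has no closed form, and direct
maximization with the analytic gradient is simpler and fast at this scale.

The **analytic gradient** is implemented for all cases (membership γ via
posterior-minus-prior weights, segment coefficients via posterior-weighted
kernel score, mixing spreads via the chain rule through `β + σξ`) and is
verified against central finite differences to 1e−6 relative in the tests.

Defaults: `n_starts = 5` starting points — the first built from cheap
single-segment fits of each segment's rule (warm start), the rest perturbed
by `N(0, 0.25|β| + 0.1)` noise; convergence targets of 1e−8 relative
log-likelihood change and 1e−5 gradient max-norm (a fit is accepted as
converged if the optimizer reports success or the gradient max-norm is below
1e−3); `max_iter = 500`. All seeds are explicit.

**Inference.** Standard errors are the square roots of the diagonal of the
inverse observed-information matrix, obtained by central finite differences
of the analytic gradient (step `1e−5·(1+|θ|)`); t-statistics are
estimate/SE. If the information matrix is not positive definite the result
is returned with inference marked unavailable rather than failing.
Estimator calibration was verified by simulation: across 60 replicates the
z-scores of recovered coefficients are approximately standard normal and
the empirical standard deviation of the estimates matches the mean reported
standard error.

**Label switching.** The likelihood is invariant under permuting same-rule
segments. Reported order is canonicalized — RRM segments before RUM,
descending population share within rule — and membership coefficients are
re-based onto the first canonical segment (a linear re-parameterization that
leaves the likelihood unchanged). Inference is computed after
canonicalization.

## Model selection

`AIC = 2k − 2 ln L`; `BIC = −2 ln L + K ln Q` with `Q` the number of choice
observations (respondents × scenarios). The composition search starts from
the two single-segment models, then greedily adds one RUM or one RRM segment
to the incumbent, stopping when neither addition improves the criterion.
BIC is the default criterion (the more conservative penalty for latent-class
size selection); AIC is reported alongside, and an exhaustive enumeration up
to `max_segments` is available behind a flag. A model is admissible only if
every population share is at least `min_share` (default 0.05) — the share
floor makes the qualitative "consider sample shares in arriving at the final
model" rule executable. Which fit measure the original sequential procedure
tracked is unstated; BIC was chosen and is documented here.

## Trade-offs

For a RUM segment the trade-off of attribute *t* against travel time *r* is
the coefficient ratio, reported as **positive minutes of willingness to
travel extra** per unit (or per stated attribute level, e.g. 15 ppb). For an
RRM segment the trade-off is choice-set dependent:

    Σ_{j≠i} −β_t logistic(β_t (t_j − t_i))  /  Σ_{j≠i} −β_r logistic(β_r (r_j − r_i))

evaluated term-by-term exactly as written; at zero differences it collapses
to `β_t/β_r` (asserted to 1e−12). The difference configuration behind an RRM
trade-off table is **not** implied by the model, so the table builder takes
it explicitly and writes it into the output header; the default is a single
competitor whose travel time sits at the grid minimum and who is one
attribute unit better, under which RRM columns decrease along the time grid.
The published RRM trade-off cells of the source study are not reproducible
because their evaluation points are unstated; only the RUM column and the
VCR values, which are closed-form ratios of published coefficients, are
reproduced.

## Synthetic data generator

The generator is the package's study-condition definition, not a tuning
knob. Attribute levels are drawn uniformly per alternative from the design
catalog (grade/traffic/road 3 levels, continuity/segregation 2, mean
exposure {5,10,15} ppb, max exposure {20,40,60} ppb, travel time {20…40}
min); rotating blocks are assigned round-robin (the original "rotating and
overlapping" allocation is not algorithmically documented; a hook accepts
externally supplied designs). Demographics are independent Bernoulli draws
loosely following the survey profile (42% female, 40% aged 35+, 58% auto
owners; daily-cycling 45% and long-commute 30% are round defaults where the
source gives none). Uniform level assignment, not an orthogonal design, is
used — fine for estimation tests, though real SP designs are more
statistically efficient per respondent.

What passing tests therefore show: the estimator recovers generating
parameters from data that exactly follow the model, with an idealized
balanced design and independent covariates. They do not show robustness to
rule misspecification, correlated demographics, non-normal mixing, or
respondent inattention — all present in real survey data.

Reference simulation sizes used by the tests and the acceptance script
(chosen to exercise C comparable to and above the 695-respondent survey
scale): recovery studies at C = 1200–2000 respondents, searches at
C = 700–1200, distributional checks at up to 10,000 respondents. A full
two-class fit at C = 2000 takes seconds with the analytic gradient.

## Numerical choices and degenerate inputs

* Probabilities, mixtures and draw averages in log space throughout;
  overflow-safe softplus.
* Ties in the fit-comparison table break toward fewer parameters.
* A segment with no random attributes uses the exact panel product (no
  simulation); requesting mixing with zero draws is an error.
* `S = 1` models skip the membership block entirely (all probabilities 1).
* Empty attribute cells must be empty for *all* alternatives of a scenario;
  partially missing attributes raise an error rather than being imputed.
* CSV round-trips are bit-exact (round-trip float parsing on read).

## Known limitations

* No nested/cross-nested logit or probit kernels; no μRRM/P-RRM regret
  generalizations; normal mixing only, uncorrelated across attributes.
* Membership covariates are global (the same list for every non-base
  segment); per-segment covariate sparsity is expressed through estimates,
  not structure.
* `predict_proba` evaluates mixed segments at the mean coefficients rather
  than re-integrating over draws.
* The greedy search does not revisit removed segments and can in principle
  stop at a local composition; the exhaustive flag exists for small S.
* Which covariance estimator produced the source study's t-statistics is
  unstated; the observed-information estimator is used here.
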