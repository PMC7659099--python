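# Methods

## Model

`growthmix` fits growth mixture models (GMMs): finite mixtures of linear
mixed models for a continuous outcome measured at T shared occasions. With
latent class k (k = 1..K, prior probabilities π), subject i's outcome vector
is

    y_i | class k  ~  N( X β_k ,  Σ_k ),      Σ_k = Z Ψ_k Z' + diag(θ_k)

where X is the T×P polynomial design in the time scores (P = 2 by default:
intercept and linear slope; up to quartic trends P ≤ 4 are accepted, with
random effects always restricted to intercept and linear slope), Z = X[:, :2],
Ψ_k is the 2×2 random-effect covariance (ψ_I, ψ_S, ψ_IS) and θ_k the
occasion-specific residual variances. Subjects are independent; missing
occasions are marginalized out by subsetting rows/columns of Σ_k (a missing
at random assumption); no imputation is performed.

Seven constraint schemes tie variance parameters by equality:

| id  | residuals over time | residuals across classes | random effects across classes |
|-----|--------------------|--------------------------|-------------------------------|
| M0  | free | free | free |
| M1A | tied | free | free |
| M1B | free | tied | free |
| M1C | free | free | tied |
| M2A | tied | tied | free |
| M2B | tied | free | tied |
| M2C | free | tied | tied |

M2C — random effects and residual variances both tied across classes — is
the default specification of widely used mixture software. The eighth
combination (everything tied) is constructible but outside the study grid.
The intercept–slope covariance ψ_IS is always freely estimated, and is tied
across classes exactly when the random-effect variances are tied.

## Estimation

The observed-data mixture log-likelihood is maximized directly with
L-BFGS-B using hand-derived analytic gradients. Ties are imposed
structurally: each tied block is one optimization variable, so every scheme
is estimated in its reduced parameter space.

Two parameterizations:

* **bounded** (default): θ via logarithms, Ψ via its log-Cholesky factor,
  π via multinomial logits. Every iterate is admissible; estimates touching
  zero are flagged (`boundary_variance`, threshold 1e-6).
* **unbounded**: θ and (ψ_I, ψ_S, ψ_IS) enter raw, so Heywood-type negative
  variance estimates can be reported (`negative_variance`), mimicking the
  behavior of unconstrained-ML mixture software. Steps whose implied Σ_k has
  smallest eigenvalue ≤ 1e-10 are rejected through a large penalty value.

Log-densities go through Cholesky factors throughout; the mixture sum uses
log-sum-exp. A non-positive-definite Σ_k raises a flagged likelihood failure
(`LikelihoodError`), never a crash, so optimizers and simulation loops can
reject the step or tabulate the failure.

**Multistart protocol** (defaults in `FitOptions`): the base start clusters
complete-case trajectory vectors with k-means (incomplete subjects join the
nearest centroid on their observed coordinates), then takes class-wise OLS
growth curves, moment starts for Ψ and θ (halved, floored at 1e-3, averaged
over tied blocks) and cluster shares for π. The remaining `n_starts − 1 = 19`
starts perturb the base: log-normal multiplicative noise (scale 0.5) on
variances, additive Gaussian noise on growth coefficients and logits. All
starts run 50 L-BFGS iterations; the best 5 continue to convergence
(relative log-likelihood tolerance 1e-8, projected-gradient tolerance 1e-5,
cap 2000 iterations). The best final log-likelihood wins; equal-likelihood
ties go to the lowest start index. `best_loglik_replicated` records whether
the two best finals agree within 1e-4·max(1, |LL|) — the usual check that
the maximum was reached from more than one start. If every start fails, a
`FittedModel` with `converged=False` and NaN indices is returned. Fitted
classes are presented sorted by intercept mean; this is cosmetic and
independent of the data-driven linking below.

## Fit indices

AIC = −2LL + 2p; BIC = −2LL + p·ln N; aBIC = −2LL + p·ln((N+2)/24) (the
Sclove effective-sample-size adjustment, as in the major mixture software);
relative entropy E = 1 − Σᵢₖ(−p_ik ln p_ik)/(N ln K) with 0·ln 0 = 0, so
E ∈ [0, 1]; E for a one-class model is reported as 1 by convention and such
models are excluded from "highest entropy" comparisons. Free parameters:
(K−1) for π, K·P for β, 3 per distinct Ψ, and one per distinct residual
cell after tying.

## Synthetic populations

Eight three-class scenarios at five occasions (time scores 0..4) encode
increasing variance heterogeneity: intercept/slope SD ratios across classes
of 1:2:3 up to 1:5:10, and residual variances that differ over time
(occasions 1–2 share one value, occasions 3–5 another) and across classes.
Low separation places adjacent class intercepts 1 outcome unit apart
(means 3/4/5); high separation doubles the gaps (3/5/7) leaving everything
else unchanged. Mixing proportions default to equal thirds (the source
table states none; the config exposes them). Registry conventions worth
stating plainly:

* Intercept/slope spreads are registered as SDs and squared into Ψ;
  ψ_IS = 0 in every generating population.
* Residual rows are registered as **variances** (the row label wins over an
  ambiguous column header in the source table; neither reading matches the
  table's prose narration exactly, and no silent reconciliation is done).
* Two garbled cells were filled by the surrounding pattern: scenario 7's
  class-1 slope SD (0.10, per the 1:2:3 pattern) and scenario 8's class-2
  slope mean (−0.30, as in every other scenario).
* Time coding 0..4 makes the intercept the first-occasion class mean; the
  fitted model shares the coding, so bias ratios do not depend on it.

The generator draws, in a fixed documented order (classes → random effects
→ residuals, via `numpy.random.default_rng(seed)`), so a dataset is
bit-reproducible from its seed on any platform. What it does **not**
emulate: missingness/dropout, non-normal residuals, covariates of class
membership, autoregressive residual structure. Passing tests therefore
speak to variance-constraint misspecification under clean mixture-of-normals
data, not to those additional real-data complications.

## Evaluation

A mixture likelihood is label-switching invariant, so estimated classes are
first linked to simulated ones: modal posterior assignment per subject, the
K×K confusion matrix, and the one-to-one matching maximizing total matched
count (linear assignment). **Recovery** requires every simulated class to
hand a strict majority (> 50%, a config knob) of its members to its matched
class; otherwise simulated classes were dispersed over several estimated
ones and bias/accuracy are undefined for that replication (explicitly:
`NotRecoveredError`, never silently zero). Linking is membership-based
rather than parameter-proximity-based.

**Relative bias** per replication is signed: (est − true)/true for each
class's intercept and slope mean, plain (est − true) when the generating
value is exactly 0 (the class-1 slope in all scenarios — applied wherever a
true value is zero, which also covers either reading of which parameter
that is). The study-level cell is the absolute value of the
replication-mean signed bias: a Monte-Carlo bias table measures the
systematic offset, which survives averaging, not the sampling noise, which
does not (per-replication |bias| of slopes is ~0.1 even for the correctly
specified model at N = 1000 and would swamp the table).

**Classification accuracy** is the share of subjects whose modal class is
the linked image of their simulated class, conditional on recovery.
**Model selection** per criterion: lowest AIC/BIC/aBIC or highest entropy
among converged fits, ties to the smaller model, then lexicographic id.

## Study driver

`StudyGrid` enumerates scenario × separation × N cells; replication r of
cell c uses dataset seed `base_seed + 100000·c + r` and the fitter reuses
the dataset seed, so results are independent of parallel scheduling
(joblib). Negative-variance tabulation is meaningful only under
`variance_mode="unbounded"`; all other outcome tables default to bounded
mode (the divergence from unbounded-ML software behavior is a documented
knob). Bias cells with no recovered replication are flagged undefined,
mirroring the dashes of printed tables; cells with |bias| ≥ .1 after
two-decimal rounding carry a `large` flag, mirroring their bold face.

## Reduced problem sizes

The shipped acceptance computations and tests use 30–100 replications per
cell instead of 1000, the package's chosen desk scale; proportions carry
binomial Monte-Carlo error and two-decimal bias cells are reproducible to
about ±0.03 at 50 replications. 1000 replications is a config change
(`n_replications`), not a code change.

## Known limitations

* Misspecified-model ("pseudo-true") bias values depend on which local
  optimum a fitter reaches on a multimodal likelihood. This implementation's
  multistart L-BFGS reliably reaches the same optimum from the tied truth
  and from data-driven starts at large N; EM-based software with different
  search heuristics can settle elsewhere, and reported bias magnitudes for
  heavily constrained models (M2B/M2C) can differ by a few hundredths
  conditional on which solutions recover the classes.
* Standard errors / Wald inference, likelihood-ratio class-number tests
  (LMR, VLMR, bootstrap), covariates, categorical outcomes and
  autoregressive or unstructured residual covariances are out of scope.
* At N = 100 many fits sit near variance boundaries; bounded mode keeps
  them admissible but boundary flags should be inspected before
  interpreting such fits.
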