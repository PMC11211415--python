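# Methods

## The model

`tmstraj` clusters patients by their *trajectory of perceived improvement*
across a 20-session course of repetitive transcranial magnetic stimulation
(rTMS).  The observable is a single ordinal self-rating collected at every
session ("much worse" … "much better", raw 1–5).  Raw categories 1 and 2
are merged before modelling (category 1 is rare in practice), giving M = 4
ordered levels, and a session-0 value fixed at "no change" anchors every
series.

The model is a latent class growth analysis (LCGA): a finite mixture of
fixed-effect growth curves with no within-class random effects.  Subject
*i* belongs to class *g* with probability

    pi_g = softmax(zeta)_g            (zeta_1 = 0, reference class)

optionally with subject covariates in the membership logits.  Within class
*g*, a cubic latent process on scaled session time u = t/20,

    Lambda_g(u) = beta_g0 + beta_g1 u + beta_g2 u^2 + beta_g3 u^3,

generates the observed level through a cumulative-probit ("thresholds")
link with cut-points tau_1 < … < tau_{M-1}:

    P(Y_it = m | g) = Phi(tau_m - Lambda_g(u_t)) - Phi(tau_{m-1} - Lambda_g(u_t)),

with tau_0 = -inf, tau_M = +inf.  Missing sessions simply drop out of the
per-subject product; a subject with no observed sessions contributes
log 1 = 0 (with a warning).

**Identifiability.**  The residual scale is fixed at 1 and tau_1 at 0; all
class intercepts are free.  This is likelihood-equivalent to
parameterisations that instead constrain an intercept and estimate a
threshold offset; we chose the variant that is simplest to implement and
test.  Ordered thresholds are enforced by optimising unconstrained
increments whose squares are accumulated (tau_{m+1} = tau_m + delta_m^2).

## Estimation

The observed-data log-likelihood is maximised by multi-start quasi-Newton
(L-BFGS-B) with analytic gradients.  Start 0 replicates the one-class
solution across classes with zero membership logits; subsequent starts add
seeded Gaussian noise to the class intercepts and membership logits
(sd = `start_scale`, default 1.0) *and* to the slope/curvature
coefficients (sd = `shape_scale`, default 4.0).  The shape perturbation
matters: when classes differ mainly in trajectory shape rather than level,
intercept-only perturbations routinely leave a class empty and the
G-class fit collapses onto the (G−1)-class solution.  When classes are
enumerated G = 1, 2, … (as the pipeline does), one further deterministic
start is added that splits the largest class of the (G−1)-class fit in
two — the standard hierarchical-enumeration safeguard against exactly
that collapse.

Convergence follows the three-criterion convention of latent-class
software: max |Δparam| < convB, |Δloglik| < convL, and the scaled gradient
criterion g'H⁻¹g / n_params < convG, all defaulting to 1e-4 with a
1000-iteration cap and 100 starts (tests and examples use smaller,
documented sizes).  L-BFGS is stopped by a callback once convB and convL
hold between accepted iterates; if it stalls on a flat ridge first (tiny
likelihood changes but parameter steps above convB), a damped Newton
polish using the observed-information Hessian finishes within the
iteration budget, and that Hessian is reused for the convG check and for
confidence bands.  Non-convergence of the best start is reported, never
silently accepted.  An EM mode (closed-form class-proportion update plus
an inner quasi-Newton pass on the expected complete-data likelihood) is
provided as a cross-check; its observed log-likelihood trace is monotone
up to the inner-solver tolerance.

Fitted classes are reported in a canonical order — by end-of-course latent
level Lambda_g(1), best first — so class 0 is always the strongest
improver.  Modal-assignment ties break to the lowest class index.

Predicted per-class expected-rating curves carry 95% bands obtained by
sampling parameter vectors from the asymptotic normal of the estimator
(inverse observed information) and taking 2.5/97.5 percentiles of the
expected-rating functional; a singular information matrix yields point
curves with bands flagged unavailable.

## Selection and adequacy

Fits for G = 1..Gmax are screened by three gates: convergence, a minimum
modal-class share (default 5%), and then lowest BIC = −2ℓ + k ln N among
the survivors.  Adequacy of the chosen classification is summarised by
APPA (mean posterior probability among subjects modally assigned to each
class; > 0.7 conventionally acceptable), OCC (odds of correct
classification, [APPA/(1−APPA)] / [pi/(1−pi)]; > 5 acceptable) and
relative entropy E = 1 − Σ(−p log p)/(N log G).  The OCC denominator uses
the model-estimated membership proportion (mean posterior column) by
default; a modal-count variant is provided because published OCC values
are not always exactly recoverable from printed APPA and class sizes, and
the two definitions differ slightly.  APPA of an empty modal class is
reported as missing, and APPA = 1 yields an infinite OCC, flagged as such.

## Coil dispersion and network scoring

From each subject's neuronavigation log (session-mean coil coordinates in
MNI mm, optional within-session samples, planned target) we compute: mean
Euclidean distance from target; mean distance from the session-1 location;
the across-session SD of that distance (s_i, the between-session
variability measure — requiring at least 3 usable sessions); and the mean
within-session SD, defined as the RMS distance of within-session samples
from their session centroid (the estimator is a package choice; the
quantity itself has no canonical definition).  Sample (n−1) SDs are used
throughout.  Because these distances are right-skewed across patients,
group summaries and tests run on cube-root values, back-transformed by
cubing; zeros are legal (no offset).

Network scoring surrounds the target with 400 probes on 20 concentric
spheres of radii (k/10)·s_i, k = 1..20 — so the outermost sphere has
radius 2 s_i — with 20 points per sphere.  Probe placement uses a
spherical Fibonacci lattice under a seeded random rotation per subject
(the 20-point placement is otherwise arbitrary; the rotation makes the
arbitrary orientation explicit and reproducible, and its Monte-Carlo
spread can be examined by varying the seed).  Each probe plus the target
itself (401 points) is mapped to the nearest atlas node (Euclidean
distance, ties to the lowest node id) and the number of distinct network
labels is the per-patient "networks stimulated" count.  Flags record
whether any hit label belongs to the executive-control (fronto-parietal
task control, dorsal attention), default-mode, or ventral-attention
(salience, cingulo-opercular task control, ventral attention) groups;
the grouping table is editable configuration, labels are compared
case-insensitively after trimming, and an ignore-list (e.g. "uncertain")
is available.

## Between-class validation

Follow-up scores (HDRS-17, BDI-II, PHQ-9, GAD-7, WSAS at weeks 8/16/26)
reduce to baseline-minus-follow-up changes; a responder has a reduction of
at least 50% of baseline (boundary counts; zero baseline leaves the flag
undefined).  Continuous variables are compared by one-way ANOVA with
partial eta squared = SSB/(SSB+SSW); binary variables by Pearson
chi-square (no continuity correction) with Cramér's V; coordinate triples
by MANOVA (Pillai's trace).  Pairwise t tests run between all class pairs
with pooled variance unless Levene's test is significant (then Welch), and
pooled-SD Cohen's d (first class minus second).  Tests are two-tailed at
alpha = 0.05 with no multiplicity correction by default — the analysis is
explicitly exploratory — with a Holm adjustment available.  Missing
follow-ups are handled by available-case analysis per time point.
Dispersion–outcome association is the Pearson correlation between s_i and
HDRS-17 reduction per time point, with a variant excluding the strongest
class.  Follow-up CIs are t-based.

## The synthetic-data generator

No public generative model exists for session-level global-impression
ratings, so every generator choice is a synthetic stand-in, labelled as
such.  The generator draws classes from configurable proportions
(defaults: the 5-class fractions 27/54/47/88/12 out of 228) and produces
ratings from exactly the LCGA data-generating process above, on the raw
5-level scale with thresholds (−2.7, 0, 1.7, 3.4) — category 1 stays
below 1% of data points.  Default class shapes (strong early-saturating
rise; delayed flat-then-late-rise; plateau early-rise-then-flat;
non-improver flat at "no change"; worsening slow decline) are cubic
coefficients frozen in `simulate.py`.  Their magnitudes were chosen to
make the default cohort *well separated* — classification adequacy in the
APPA ≈ 0.93–0.99, relative-entropy ≈ 0.95 regime that daily-sampled
improvement ratings can support — with the delayed and plateau classes
ending at similar levels so that their distinction rests on early/mid-
course shape.  Missingness is completely at random on sessions 1–20,
capped at 2 missing sessions per subject to mirror the ≥18-of-20
inclusion rule.

Coil logs place each session mean at the subject's target plus isotropic
Gaussian jitter.  The per-axis scale is calibrated so that the
across-session SD metric has expectation equal to the configured
per-class value: because every distance shares the session-1 draw, the
naive iid constant sqrt(2(3−8/pi)) ≈ 0.952 is biased, and the
Monte-Carlo-calibrated constant 0.8175 (20 sessions) is used instead.
Default per-class dispersions are 4.9/3.3/2.9/2.8/2.1 mm and
within-session SDs 2.3/1.8/1.9/1.6/1.1 mm.  Outcomes are truncated-normal
baselines minus class-shifted reduction draws per scale and week; the
class gradients in dispersion and outcome reductions jointly induce the
positive dispersion–outcome correlation the pipeline measures.  The atlas
generator scatters labelled nodes uniformly on a 55–80 mm cortical shell
with every label used at least once.

**What the generator does not emulate.**  Real rating series show serial
correlation, response styles, and early-course structure that is not a
cubic polynomial; real coil dispersion is anisotropic and scalp-
constrained; real atlas nodes are clustered, not uniform on a shell.
Passing recovery tests therefore shows that the estimator and selection
rule work when the model family is correct and classes are crisp — not
that four temporal samples per course could never distinguish trajectory
subtypes in real data, nor that they always could.

## Weekly-subsampling degradation: a structural note

Thinning each series to sessions {0, 5, 10, 15, 20} degrades
classification (posteriors flatten, small classes fall below the 5% floor
or fail convergence more often, selection usually favours coarser
models).  A specific stronger phenomenon — the *selected* weekly model
pooling the delayed and plateau moderate improvers into one class in most
replicates — is not reproducible under this generator, and the reason is
structural: two cubic trajectories that agree closely at five time points
agree closely everywhere, so any class pair separable from daily data
(needed for high-adequacy recovery) retains enough weekly separation that
BIC still splits it at realistic sample sizes.  Under cubic ground truth
the weekly merge occurs only when the size floor or convergence gate
happens to eliminate the finer models (about half of cohort seeds at
n = 500 under the default conditions).  A reliable merge would require early-course class structure
outside the cubic family — precisely the kind of real-data feature the
generator does not emulate.  The corresponding end-to-end test documents
this honestly rather than asserting a behaviour the generative model
cannot produce; it is expected to fail under the default conditions.

## Numerical choices and edge cases

* Probabilities are floored at 1e-300 inside logs and at 1e-12 inside
  gradient ratios.
* Posteriors are computed in the log domain (log-sum-exp), so long series
  with near-zero session probabilities do not underflow.
* The convG criterion solves H x = g directly, falling back to least
  squares when the observed information is singular.
* Hessians are central finite differences of the analytic gradient
  (step 1e-5, symmetrised); the asymptotic covariance is its
  pseudo-inverse with negative eigenvalues clipped at zero before
  sampling.
* Degenerate inputs: empty rating series warn and contribute zero
  likelihood; fewer than 3 coil sessions leave the SD metric missing;
  absent session-1 leaves session-1-referenced metrics missing; empty
  modal classes are reported as missing APPA rather than an error;
  an all-equal comparison variable returns F = 0, p = 1.

## Default problem sizes

Study-scale analyses use 100 starts, 1000 iterations and Gmax = 8.  The
shipped tests and the acceptance script use a 500-subject cohort with 20
starts and G = 1..6 (recovery and selection), 10 starts across ten
cohorts for the weekly-subsampling experiment, and 60–250-subject cohorts
elsewhere; these sizes are the package's chosen demonstration scale and
are stated wherever used.
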