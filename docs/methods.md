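# Methods

## Task model

A session is a sequence of cue presentations drawn from the serial-reversal
protocol: `n_pairs` = 3 cue pairs, each acquired and then reversed once, for
6 phases in total. Each phase lasts a minimum block of 16 trials, after
which a trigger fires independently on every subsequent trial with hazard
0.25, ending the phase; phase length is therefore 16 + G with
G ~ Geometric(0.25), mean 20. Six such phases have expected total 120
trials, the session length the protocol fixes. Because an open-ended
geometric trigger cannot guarantee that total, the generator reconciles the
two constraints by rejection sampling: the six extensions are redrawn until
they sum to 120 (`fixed_length=True`, the default). Conditioning on the
total biases the *empirical* per-trial hazard slightly below 0.25, so an
unconstrained mode is retained; hazard conformance is always measured in
that mode, with each post-minimum trial treated as an at-risk Bernoulli
event.

Within a session the currently neutral cue must appear exactly twice in
every four trials. This is enforced by slot shuffling: the session is cut
into non-overlapping 4-trial windows, two slots per window are marked
"neutral-cue", and the marks are shuffled within the window. Slots refer to
the cue *role*, so the scheme remains correct across reversals, where the
physical cue filling the role changes. Sides are uniform, inter-trial
intervals uniform on 2–11 s. ITIs are generated for completeness but ignored
by all fitting: every model is trial-indexed. Outcome delivery is an
independent Bernoulli(0.6) per trial; the delivered liquid is determined by
the latent mapping and the presented cue.

Each new pair starts with within-pair cue 1 mapped to the valenced liquid;
since cue labels within a fresh pair are arbitrary, this loses no
generality.

## Learning models

**HMM.** The state space is S ∈ {cue1→valenced, cue2→valenced} jointly with
the reversal-expectation node H ∈ {0, 1}. The concurrent
"both-liquids-valenced" state is omitted from S. Transitions:
P(H: 0→1) = α with H = 1 absorbing; given H = 1 the contingency swaps with
probability β, given H = 0 it is frozen. Emissions: the liquid mapped to the
presented cue is delivered with probability 0.6, nothing with 0.4, and the
other liquid never. At each new-pair onset the belief resets to uniform over
S with H = 0. On every subsequent trial the joint belief is propagated
through the H and S|H transitions *before* the trial; expected value and
precision are read off this predictive belief at cue onset (they model
anticipatory responses to the cue, before the outcome is seen); the belief
is then conditioned on the observed cue–outcome combination and
renormalized. No propagation is applied on a pair's first trial — the reset
defines the prior for that trial, and the hand-checkable two-trial example
in the tests pins this convention down. Expected value is
Q_j = Σ_S P(S)·0.6·R(liquid for cue j under S) with R = +1/0/−1 for
pleasant/neutral/unpleasant, so |Q| ≤ 0.6.

Updates run in linear probability space with explicit renormalization:
traces are 120 trials of 2-state beliefs, so underflow is not a concern; a
log-space recursion serves as an oracle in the tests. An observation with
zero likelihood under every state (possible only for externally supplied,
protocol-inconsistent sequences) raises a numerical error naming the trial.

**Precision.** "Inverse Shannon entropy" admits two readings; both are
implemented as monotone transforms of the posterior entropy over S. The
default is the normalized negentropy 1 − H(P)/log₂K ∈ [0, 1], which is
finite everywhere; a literal reciprocal 1/(H + 1e-6) is available behind
`precision_mode="reciprocal"` but diverges (to ~1e6) at point-mass
posteriors, which is why it is not the default.

**Reduced HMM.** Identical machinery with H clamped to 1: a constant
per-trial swap hazard β. Its EV trace tracks the full model's nearly
perfectly, while its precision lacks the full model's anticipatory decline —
under consistent reinforcement the full model's predictive precision decays
monotonically as H accumulates, whereas the reduced model's is flat.

**α and β defaults.** Both parameters are fixed a priori rather than fitted.
β = 0.25 matches the task's design hazard — the natural a-priori choice for
a learner that knows the protocol. With β fixed, α = 0.35 is the package's
calibrated default: it jointly reproduces the characteristic behavior of
this model pair on default sessions — a mean full-vs-reduced EV correlation
of ≈ 0.987 and a negligible precision-vs-associability correlation
(mean |r| ≈ 0.09–0.12). A sensitivity-sweep utility
(`hmm_parameter_sweep`) exposes how these quantities move with (α, β); the
EV correlation rises toward 1 as α grows or β shrinks.

**Model-free rules.** RW, PH and Hybrid track one value per unique cue
(pair, cue id); novel pairs start at `q_init` = 0 with associability
`assoc_init` = 1 (per-cue associability; initialization and cue-specificity
are modelling choices, stated here because the rules are underdetermined
without them). Rewards are salience-coded, R = 1 iff the valenced liquid
was delivered, in *both* sessions — the deliberate asymmetry with the HMM's
signed coding mirrors how such model-free analyses are conventionally run.
The PH update Q ← Q + S·assoc·R is not error-correcting: for moderate
intensity it converges with vanishing associability, but it can overshoot
R and, at S near 1, oscillate — a property of the rule as specified, which
the tests document rather than patch. The Hybrid's free parameter is the
associability decay η with the scale κ fixed at 1; at η = 0 it reduces
exactly to RW with rate κ·assoc_init.

## Reaction-time model and fitting

Synthetic RTs are log-normal:
log RT = intercept + trend·t + switch·1[side change] + w·EV + ε,
ε ~ N(0, σ²). Defaults: intercept log 0.5 (a ~500 ms simple response),
trend −5e-4 per trial (mild practice speeding), switch cost 0.05, EV weight
−0.3, σ = 0.1. The negative EV weight makes responses faster the stronger
an appetitive prediction and slower the stronger an aversive one (aversive
EVs are negative). σ = 0.1 on the log scale (~10% RT variability) leaves
the EV effect recoverable but far from deterministic; the model-recovery
tests use exactly these conditions.

Fitting first adjusts log RTs by OLS on [1, trial index, side-switch],
dropping missing responses listwise (subjects with over half their
responses missing are excluded). The second stage regresses the residuals
on [1, EV], with the EV predictor passed through the same nuisance
projection. This Frisch–Waugh step makes the two-stage SSE identical to a
joint regression on [1, t, switch, EV] — verified in the tests — and makes
parameter recovery exact in the noise-free limit; regressing raw EV against
adjusted RTs would bias the grid minimum whenever EV correlates with the
trial trend, as learning curves do. Free parameters are grid-searched over
[0, 1] with step 0.001 (ties break toward the smaller value; the grid fit
is vectorized across all 1001 values). BIC = n·ln(SSE/n) + k·ln(n) with
k = 1 for RW/PH/Hybrid and k = 0 for the HMM variants (parameters fixed a
priori) and the baseline. The baseline's constant EV enters regression only
after seeded Gaussian jitter (sd 0.01); without jitter the regression is
singular and an error names the model. Both per-subject fitting (the
default, yielding subject-level evidences for random-effects BMS) and a
pooled mode (one shared parameter, summed SSE, total-trial BIC) are
provided, since group-level fitting conventions differ.

## Model selection and validation

Random-effects BMS uses the standard variational Dirichlet scheme over
log evidences −BIC/2: responsibilities
u_nk ∝ exp(lev_nk + ψ(α_k) − ψ(Σα)) and counts α = 1 + Σ_n u_n iterated to
1e-8 on the counts (error after 10,000 iterations). pp are the Dirichlet
means; xp are Monte-Carlo estimates (default 10⁶ seeded Dirichlet draws,
MC error ~3/√N ≈ 0.003) of the probability that each model's frequency is
maximal. The tests cross-check the exceedance computation against an exact
gamma-quadrature/Beta-tail evaluation of the same Dirichlet. Note the
variational posterior itself is an approximation: on weak-evidence problems
its xp is more confident than the exact posterior, which is a known property
of the scheme, not a defect of the implementation.

Baseline validation draws i.i.d. uniform [0, 1] EV traces (the simplest
defensible reading of "random expected values"), fits each to a subject's
adjusted RTs by a single k = 0 regression, and computes the per-subject
p-value as (wins + 1)/(n_reps + 1) — the add-one correction keeps p in
(0, 1] so Fisher's χ² = −2Σln p (df = 2·subjects) is always defined.
Traces are drawn at the length of each subject's residual vector; for
i.i.d. uniforms this is identical to drawing full-length traces and
discarding dropped trials.

## Reporting conventions

Trace correlations are computed per session and then averaged, matching
per-subject reporting; they are never computed on concatenated traces. EV
two-bin splits are at +0.3 (appetitive) and −0.3 (aversive), with boundary
values in the lower bin; tertile splits use empirical tertiles with ties to
the lower bin (an all-constant trace collapses to a single "low" category).
Trial indices are 0-based internally and 1-based in every emitted table.

## Problem sizes

Defaults used by the shipped analyses: 19-subject cohorts (38 sessions of
120 trials), ≥ 19 sessions per valence for correlation summaries, 200
sessions for the delivery-rate check, 500 unconstrained sessions for the
hazard check, 10,000 validation repetitions in the pipeline (200 in the
scaled-down direction test), and 10⁶ Dirichlet draws for xp. All stages are
seeded through a single master seed via `SeedSequence`-derived child
streams, recorded per subject and session in the manifest, so any subject
can be replayed in isolation.

## What the generator does and does not emulate

It reproduces the protocol's statistical structure (trial counts, block and
hazard schedule, reinforcement rate, neutral-cue balance, counterbalanced
session order) and an RT process whose log-linear structure matches the
fitting model exactly. It does not emulate attentional lapses, RT
autocorrelation beyond the linear trend, heavy-tailed RT distributions,
missing responses, between-subject parameter heterogeneity, or any
physiological response channel. Consequently, passing model-recovery tests
shows the pipeline is correct and identifiable *under its own generating
assumptions*; it cannot show that real behavior is best described by any
of these models, and fits to real data should expect lower evidence
contrasts than the synthetic ones.

## Known limitations

- Forward filtering only; no smoothed (forward–backward) posteriors.
- α, β are fixed, not fitted; only the model-free rules have a free
  parameter, mirroring the intended comparison.
- The PH rule's literal form can leave Q ∈ [0, 1]; violations are reported
  by `check_trace_bounds`, never clipped.
- Exceedance probabilities are unprotected (no correction for the null of
  equal frequencies), and family-level comparisons are out of scope.
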