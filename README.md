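# pavlov

Model-based and model-free learning analyses for a serial-reversal Pavlovian
conditioning protocol, driven end to end by a synthetic task and behavior
generator.

## The problem

In a classic Pavlovian reversal task, paired fractal cues predict delivery of
a valenced (pleasant or unpleasant) or an affectively neutral liquid. Each
session presents 3 cue pairs in succession over 120 trials; after a 16-trial
minimum block, a per-trial trigger (hazard 0.25) either reverses the
cue–outcome mapping or introduces a novel pair, and the scheduled liquid is
delivered with probability 0.6. Did participants learn these contingencies
with a *model-based* system that anticipates reversals, or with *model-free*
error-driven rules? This package implements the competing computational
accounts and the machinery to arbitrate among them from trial-by-trial
reaction times:

- **HMM** — a Bayesian learner over the joint of the contingency state
  S (which cue maps to the valenced liquid) and a latched binary
  reversal-expectation node H: P(H 0→1) = α per trial and, given H = 1, the
  contingency swaps with probability β. Forward filtering yields the
  expected value Q_j = Σ_S P(S)·E[R | S, cue j] with R ∈ {−1, 0, +1}, and a
  *precision* signal, 1 − H(P(S))/log₂K, the normalized negentropy of the
  state posterior.
- **ReducedHMM** — the same filter with H clamped on (constant hazard): EV
  traces nearly identical to the full model, precision signals qualitatively
  different (no anticipatory decline).
- **RW / PH / Hybrid** — Rescorla–Wagner (Q ← Q + α(R − Q)), Pearce–Hall
  (Q ← Q + S·assoc·R with assoc = |R − Q| from the cue's previous
  presentation), and their hybrid (RW value update with a PH associability as
  learning rate), all with salience-coded rewards R ∈ {0, 1}.
- **Baseline** — no learning, EV ≡ 0.5.

Fitting: log RTs are adjusted for a linear trend and a side-switch cost, the
residuals are regressed on each model's EV trace (free parameters
grid-searched over [0, 1] in steps of 0.001), and fits are scored with the
Gaussian-residual BIC = n·ln(SSE/n) + k·ln(n). Subject-level evidences
(−BIC/2) enter random-effects Bayesian model selection (variational Dirichlet
posterior over model frequencies; posterior probabilities *pp* and
Monte-Carlo exceedance probabilities *xp*), and each model is also tested
against a random-EV actor with a nonparametric per-subject p-value combined
across subjects by Fisher's method.

The intended users are computational cognitive-neuroscience researchers who
want a tested, reusable reference implementation of this model family and of
the RT-based model-comparison pipeline, with a generator that reproduces the
task's statistical structure at desk scale.

## Worked example

```sh
pavlov demo --out demo_run --seed 7
```

simulates a counterbalanced 19-subject cohort (two 120-trial sessions each,
RTs generated from the HMM's expected values through the log-linear RT
model), fits all five models per subject and session, and writes
`sessions.csv`, `traces.csv`, `fits.csv`, `bms.json`, `validation.json`,
`report.json` and a `manifest.json`. The same run from Python:

```python
import pavlov
manifest = pavlov.run_pipeline({"n_subjects": 19}, "demo_run", seed=7)
```

Headline numbers from that run (seed 7):

- `bms.json`, appetitive session: xp = 1.00 for the HMM vs 0.00 for RW, PH
  and Hybrid (pp = 0.86 vs ≈ 0.05 each); the aversive session is equivalent.
  With RTs driven by the HMM, model selection decisively recovers it.
- `validation.json`: Fisher-combined p ≈ 5e-36 for the HMM against the
  random-EV baseline (appetitive); PH, whose multiplicative update cannot
  track these RTs, stays at p = 1.
- `report.json`: mean full-vs-reduced HMM EV correlation r = 0.987; mean
  |r| between HMM precision and PH associability = 0.11 — the two
  uncertainty signals are essentially unrelated despite the near-identical
  EV traces; mean trials per appetitive EV bin (split at 0.3): 57.7 high /
  62.3 low.

Individual stages are exposed as `pavlov simulate / trace / fit / compare /
validate / report`; see `pavlov --help`.

## Layout

- `src/pavlov/task.py` — task/RT generator and sequence validation
- `src/pavlov/learners.py` — the six learning models and trace utilities
- `src/pavlov/fitting.py` — RT adjustment, grid search, BIC
- `src/pavlov/selection.py` — random-effects BMS, baseline validation, Fisher
- `src/pavlov/signals.py` — trace correlations and EV binning
- `src/pavlov/pipeline.py`, `src/pavlov/cli.py` — orchestration and CLI
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
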