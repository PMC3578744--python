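"""Trial-by-trial learning models.

Six models produce per-trial expected-value (and uncertainty) traces from a
session:

* ``HMM`` -- a Bayesian hidden Markov learner over the joint of the contingency
  state S (which cue currently maps to the valenced liquid) and a latched
  reversal-expectation node H.  H switches on with probability ``alpha`` per
  trial and never switches back; while H is on, the contingency swaps with
  probability ``beta`` per trial.  Beliefs are filtered forward in linear
  probability space; expected value and precision are read off the predictive
  belief at cue onset, before conditioning on the trial's outcome.
* ``ReducedHMM`` -- the same machinery with H clamped on, i.e. a constant
  per-trial reversal hazard and no anticipatory growth of uncertainty.
* ``RW`` -- Rescorla-Wagner delta rule with learning rate ``alpha``.
* ``PH`` -- Pearce-Hall: the update is gated by an associability term equal to
  the absolute prediction error at the cue's previous presentation.
* ``Hybrid`` -- Rescorla-Wagner value update with a Pearce-Hall associability
  setting the learning rate.
* ``Baseline`` -- constant expected value of 0.5 (no learning), optionally with
  seeded Gaussian jitter so it can enter a regression.

The model-free rules use salience-coded rewards (R = 1 iff the valenced liquid
was delivered, in both sessions) while the HMM codes the liquids as
-1/0/+1 for unpleasant/neutral/pleasant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import entropy, pearsonr

from .errors import NumericalError
from .task import STREAM_JITTER, SessionSequence

MODELS = ("HMM", "ReducedHMM", "RW", "PH", "Hybrid", "Baseline")

#: default transition probabilities of the reversal-expectation node and the
#: contingency swap.  ``beta`` matches the task's design hazard of 0.25; with
#: that fixed, ``alpha`` = 0.35 is calibrated so that the full and reduced
#: models reproduce the characteristic near-unity EV correlation (~0.987) and a
#: negligible precision-vs-associability correlation on default sessions.
DEFAULT_ALPHA = 0.35
DEFAULT_BETA = 0.25


def _reward_coding_for(valence: str) -> dict[str, float]:
    return {
        "valenced": 1.0 if valence == "appetitive" else -1.0,
        "neutral": 0.0,
        "none": 0.0,
    }


@dataclass(frozen=True)
class HMMParams:
    """Parameters of the hidden Markov learner.

    ``reward_coding`` maps the liquid delivered on reinforced trials to a
    scalar reward; ``None`` defers to the session valence (+1 pleasant,
    -1 unpleasant, 0 neutral).  ``emit_deliver``/``emit_none`` are the
    probabilities that the scheduled liquid is or is not delivered.
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    emit_deliver: float = 0.6
    emit_none: float = 0.4
    reward_coding: dict | None = None
    precision_mode: str = "negentropy"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta={self.beta} must lie in [0, 1]")
        if abs(self.emit_deliver + self.emit_none - 1.0) > 1e-12:
            raise ValueError("emit_deliver + emit_none must equal 1")
        if self.precision_mode not in ("negentropy", "reciprocal"):
            raise ValueError("precision_mode must be 'negentropy' or 'reciprocal'")


@dataclass(frozen=True)
class ModelFreeParams:
    """Parameters of the model-free rules and the constant baseline."""

    model: str = "RW"
    rate_or_intensity: float = 0.5
    kappa: float = 1.0
    q_init: float = 0.0
    assoc_init: float = 1.0
    baseline_value: float = 0.5
    baseline_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate_or_intensity <= 1.0:
            raise ValueError("rate_or_intensity must lie in [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


@dataclass
class ModelTraces:
    """Per-trial signals produced by one model on one session."""

    model: str
    ev: np.ndarray
    precision: np.ndarray | None = None
    associability: np.ndarray | None = None
    prediction_error: np.ndarray | None = None
    posterior_s: np.ndarray | None = None  # (n_trials, 2) predictive P(S) at cue onset
    params: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.ev)


# --------------------------------------------------------------------------
# HMM building blocks
# --------------------------------------------------------------------------

def h_transition_matrix(alpha: float) -> np.ndarray:
    """Transition matrix of the reversal-expectation node H.

    Rows index H at trial t-1, columns H at trial t.  Expectation grows with
    probability ``alpha`` and, once on, never switches back off.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} must lie in [0, 1]")
    return np.array([[1.0 - alpha, alpha], [0.0, 1.0]])


def s_transition_given_h(beta: float, h: int) -> np.ndarray:
    """Contingency-state transition conditional on the expectation node.

    With H = 0 the mapping is frozen (identity); with H = 1 it swaps with
    probability ``beta`` on each trial.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta={beta} must lie in [0, 1]")
    if h not in (0, 1):
        raise ValueError("h must be 0 or 1")
    if h == 0:
        return np.eye(2)
    return np.array([[1.0 - beta, beta], [beta, 1.0 - beta]])


def emission_likelihood(state: int, cue: int, outcome: str, params: HMMParams) -> float:
    """P(outcome | contingency state, presented cue).

    ``state`` is the within-pair cue id (1 or 2) currently mapped to the
    valenced liquid.  The scheduled liquid (valenced if the presented cue is
    the mapped one, neutral otherwise) is delivered with ``emit_deliver``;
    otherwise nothing is delivered.  The other liquid can never appear.
    """
    maps_valenced = cue == state
    if outcome == "none":
        return params.emit_none
    if outcome == "valenced":
        return params.emit_deliver if maps_valenced else 0.0
    if outcome == "neutral":
        return params.emit_deliver if not maps_valenced else 0.0
    raise ValueError(f"unknown outcome {outcome!r}")


def precision_from_posterior(posterior_s: np.ndarray, mode: str = "negentropy") -> float:
    """Scalar precision of a posterior over contingency states.

    ``negentropy`` (default): 1 - H(P)/log2(K), which is 0 at the uniform
    distribution and 1 at a point mass.  ``reciprocal``: 1/(H(P) + 1e-6), a
    literal inverse Shannon entropy that diverges (to ~1e6) at a point mass.
    """
    p = np.asarray(posterior_s, dtype=float)
    if p.min() < -1e-12 or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("posterior must be a normalized probability vector")
    h_bits = float(entropy(np.clip(p, 0.0, None), base=2))
    if mode == "negentropy":
        return 1.0 - h_bits / np.log2(len(p))
    if mode == "reciprocal":
        return 1.0 / (h_bits + 1e-6)
    raise ValueError("mode must be 'negentropy' or 'reciprocal'")


def _hmm_expected_reward(p_s: np.ndarray, cue: int, params: HMMParams, valence: str) -> float:
    """Predictive expected reward for the presented cue under belief p_s."""
    coding = params.reward_coding or _reward_coding_for(valence)
    ev = 0.0
    for s_idx, state in enumerate((1, 2)):
        liquid = "valenced" if cue == state else "neutral"
        ev += p_s[s_idx] * params.emit_deliver * coding[liquid]
    return ev


def hmm_filter(
    session: SessionSequence,
    params: HMMParams | None = None,
    reduced: bool = False,
) -> ModelTraces:
    """Forward-filter the joint (S, H) belief over a session.

    At each new-pair onset the belief resets to a uniform prior over S with
    H = 0 (H = 1 when ``reduced``).  On every later trial the belief is first
    propagated through the H and S|H transitions; the predictive EV and
    precision are recorded at cue onset; the belief is then conditioned on the
    observed cue-outcome combination and renormalized.
    """
    params = params or HMMParams()
    n = session.n_trials
    ev = np.empty(n)
    prec = np.empty(n)
    post = np.empty((n, 2))
    t_h = h_transition_matrix(params.alpha)
    t_s = [s_transition_given_h(params.beta, h) for h in (0, 1)]
    joint = None  # (2 S, 2 H)
    for i, trial in enumerate(session.trials):
        if trial.is_new_pair_onset:
            joint = np.zeros((2, 2))
            joint[:, 1 if reduced else 0] = 0.5
        else:
            if reduced:
                propagated = joint  # H is clamped: no H dynamics
            else:
                propagated = joint @ t_h
            joint = np.empty_like(propagated)
            for h in (0, 1):
                joint[:, h] = t_s[h].T @ propagated[:, h]
        p_s = joint.sum(axis=1)
        post[i] = p_s
        ev[i] = _hmm_expected_reward(p_s, trial.cue_id, params, session.valence)
        prec[i] = precision_from_posterior(p_s, params.precision_mode)
        lik = np.array(
            [emission_likelihood(s, trial.cue_id, trial.outcome, params) for s in (1, 2)]
        )
        joint = joint * lik[:, None]
        total = joint.sum()
        if total <= 0.0:
            raise NumericalError(
                f"observation at trial {trial.trial_index} has zero likelihood "
                "under every contingency state"
            )
        joint /= total
    name = "ReducedHMM" if reduced else "HMM"
    return ModelTraces(
        model=name,
        ev=ev,
        precision=prec,
        posterior_s=post,
        params={"alpha": params.alpha, "beta": params.beta, "reduced": reduced},
    )


def reduced_hmm_filter(session: SessionSequence, params: HMMParams | None = None) -> ModelTraces:
    """Constant-hazard variant: the expectation node is clamped on."""
    return hmm_filter(session, params, reduced=True)


def hmm_enumeration_oracle(
    session: SessionSequence, params: HMMParams | None = None, reduced: bool = False
) -> np.ndarray:
    """Predictive P(S) at cue onset by brute-force path enumeration.

    Sums the joint probability of every (S, H) path; exponential in session
    length, intended only to cross-check ``hmm_filter`` on very short
    sessions.
    """
    params = params or HMMParams()
    trials = session.trials
    n = len(trials)
    if n > 10:
        raise ValueError("enumeration oracle is exponential; use <= 10 trials")
    t_h = h_transition_matrix(params.alpha)
    t_s = [s_transition_given_h(params.beta, h) for h in (0, 1)]
    states = list(itertools.product((0, 1), (0, 1)))  # (s_idx, h)

    def prior(s_idx: int, h: int, trial) -> float:
        if not trial.is_new_pair_onset:
            raise AssertionError("oracle sessions must start with a new-pair onset")
        want_h = 1 if reduced else 0
        return 0.5 if h == want_h else 0.0

    predictive = np.zeros((n, 2))
    for t in range(n):
        # enumerate paths over trials 0..t; weight = prior * transitions *
        # emissions on trials 0..t-1 (the trial-t outcome is not yet seen)
        for path in itertools.product(states, repeat=t + 1):
            w = prior(*path[0], trials[0])
            for i in range(1, t + 1):
                if trials[i].is_new_pair_onset:
                    w *= prior(*path[i], trials[i])  # belief reset
                else:
                    (s0, h0), (s1, h1) = path[i - 1], path[i]
                    if reduced:
                        w *= 0.0 if (h0 != 1 or h1 != 1) else t_s[1][s0, s1]
                    else:
                        w *= t_h[h0, h1] * t_s[h1][s0, s1]
                if w == 0.0:
                    break
            else:
                for i in range(t):
                    s_idx = path[i][0]
                    w *= emission_likelihood(
                        s_idx + 1, trials[i].cue_id, trials[i].outcome, params
                    )
                    if w == 0.0:
                        break
                else:
                    predictive[t, path[t][0]] += w
        predictive[t] /= predictive[t].sum()
    return predictive


# --------------------------------------------------------------------------
# model-free rules
# --------------------------------------------------------------------------

def rw_run(session: SessionSequence, alpha: float, q_init: float = 0.0) -> ModelTraces:
    """Rescorla-Wagner: Q <- Q + alpha * (R - Q) for the presented cue."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    rewards = session.rewards01()
    q: dict[tuple[int, int], float] = {}
    ev = np.empty(session.n_trials)
    pe = np.empty(session.n_trials)
    for i, key in enumerate(session.cue_keys()):
        cur = q.get(key, q_init)
        ev[i] = cur
        delta = rewards[i] - cur
        pe[i] = delta
        q[key] = cur + alpha * delta
    return ModelTraces(model="RW", ev=ev, prediction_error=pe, params={"alpha": alpha})


def ph_run(
    session: SessionSequence,
    s_intensity: float,
    q_init: float = 0.0,
    assoc_init: float = 1.0,
) -> ModelTraces:
    """Pearce-Hall: Q <- Q + S * assoc * R, assoc = |R_prev - Q_prev| per cue.

    Associability is the absolute prediction error at the cue's previous
    presentation (``assoc_init`` on its first); the update is proportional to
    the current reward, so unreinforced trials leave Q unchanged.
    """
    if not 0.0 <= s_intensity <= 1.0:
        raise ValueError("s_intensity must lie in [0, 1]")
    rewards = session.rewards01()
    q: dict[tuple[int, int], float] = {}
    assoc: dict[tuple[int, int], float] = {}
    ev = np.empty(session.n_trials)
    a_trace = np.empty(session.n_trials)
    pe = np.empty(session.n_trials)
    for i, key in enumerate(session.cue_keys()):
        cur = q.get(key, q_init)
        a = assoc.get(key, assoc_init)
        ev[i] = cur
        a_trace[i] = a
        pe[i] = rewards[i] - cur
        q[key] = cur + s_intensity * a * rewards[i]
        assoc[key] = abs(rewards[i] - cur)
    return ModelTraces(
        model="PH",
        ev=ev,
        associability=a_trace,
        prediction_error=pe,
        params={"s_intensity": s_intensity},
    )


def hybrid_run(
    session: SessionSequence,
    eta: float,
    kappa: float = 1.0,
    q_init: float = 0.0,
    assoc_init: float = 1.0,
) -> ModelTraces:
    """Hybrid rule: RW value update with a PH associability as learning rate.

    Q <- Q + kappa * assoc * delta;  assoc <- eta * |delta| + (1 - eta) * assoc
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    rewards = session.rewards01()
    q: dict[tuple[int, int], float] = {}
    assoc: dict[tuple[int, int], float] = {}
    ev = np.empty(session.n_trials)
    a_trace = np.empty(session.n_trials)
    pe = np.empty(session.n_trials)
    for i, key in enumerate(session.cue_keys()):
        cur = q.get(key, q_init)
        a = assoc.get(key, assoc_init)
        ev[i] = cur
        a_trace[i] = a
        delta = rewards[i] - cur
        pe[i] = delta
        q[key] = cur + kappa * a * delta
        assoc[key] = eta * abs(delta) + (1.0 - eta) * a
    return ModelTraces(
        model="Hybrid",
        ev=ev,
        associability=a_trace,
        prediction_error=pe,
        params={"eta": eta, "kappa": kappa},
    )


def baseline_run(
    session: SessionSequence,
    params: ModelFreeParams | None = None,
    seed: int | None = None,
) -> ModelTraces:
    """No-learning baseline: EV constant at 0.5.

    When ``seed`` is given, seeded Gaussian jitter (sd ``baseline_noise_sd``)
    is added so that the trace has nonzero variance and can enter the RT
    regression.
    """
    params = params or ModelFreeParams(model="Baseline")
    ev = np.full(session.n_trials, params.baseline_value)
    used = {"baseline_value": params.baseline_value}
    if seed is not None:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), STREAM_JITTER]))
        ev = ev + rng.normal(0.0, params.baseline_noise_sd, size=session.n_trials)
        used["baseline_noise_sd"] = params.baseline_noise_sd
    return ModelTraces(model="Baseline", ev=ev, params=used)


def run_model(
    session: SessionSequence,
    model: str,
    *,
    hmm_params: HMMParams | None = None,
    mf_params: ModelFreeParams | None = None,
    seed: int | None = None,
) -> ModelTraces:
    """Dispatch a model by name with its default or supplied parameters."""
    if model == "HMM":
        return hmm_filter(session, hmm_params)
    if model == "ReducedHMM":
        return reduced_hmm_filter(session, hmm_params)
    mf = mf_params or ModelFreeParams(model=model)
    if model == "RW":
        return rw_run(session, mf.rate_or_intensity, mf.q_init)
    if model == "PH":
        return ph_run(session, mf.rate_or_intensity, mf.q_init, mf.assoc_init)
    if model == "Hybrid":
        return hybrid_run(session, mf.rate_or_intensity, mf.kappa, mf.q_init, mf.assoc_init)
    if model == "Baseline":
        return baseline_run(session, mf, seed)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def check_trace_bounds(traces: ModelTraces, emit_deliver: float = 0.6) -> list[str]:
    """Report (without clipping) violations of the models' value bounds.

    HMM expected values are bounded by ``emit_deliver`` in magnitude; the
    model-free rules keep Q in the convex hull of q_init and the observed
    rewards whenever the effective learning rate stays within [0, 1].
    """
    issues = []
    if traces.model in ("HMM", "ReducedHMM"):
        if np.any(np.abs(traces.ev) > emit_deliver + 1e-12):
            issues.append(f"{traces.model} |EV| exceeds {emit_deliver}")
    else:
        if np.any(traces.ev < -1e-12) or np.any(traces.ev > 1.0 + 1e-12):
            issues.append(f"{traces.model} Q left [0, 1]")
    return issues


def hmm_parameter_sweep(
    sessions: list[SessionSequence],
    alphas: list[float],
    betas: list[float],
) -> pd.DataFrame:
    """Sensitivity sweep: mean full-vs-reduced EV correlation per (alpha, beta)."""
    rows = []
    for a in alphas:
        for b in betas:
            p = HMMParams(alpha=a, beta=b)
            rs = [
                pearsonr(hmm_filter(s, p).ev, hmm_filter(s, p, reduced=True).ev).statistic
                for s in sessions
            ]
            rows.append({"alpha": a, "beta": b, "mean_ev_corr": float(np.mean(rs))})
    return pd.DataFrame(rows)
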