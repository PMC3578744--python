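"""Serial-reversal Pavlovian task generator.

Emulates a two-session conditioning protocol in which paired fractal cues
predict delivery of a valenced (pleasant or unpleasant) or an affectively
neutral liquid.  A session presents ``n_pairs`` cue pairs in succession; each
pair is acquired for a minimum block of trials and then, with a fixed per-trial
hazard, either reverses its cue-outcome mapping or gives way to a novel pair.
Liquid delivery is probabilistic (60% by default) and the currently neutral cue
appears exactly twice in every non-overlapping four-trial window so that both
cues are evenly distributed through the session.

The module also synthesizes reaction times whose log is linear in model
expected value, a temporal trend and a side-switch cost -- the structure the
downstream regression analysis assumes -- and validates externally supplied
trial sequences against the protocol invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError

VALENCES = ("appetitive", "aversive")

#: stream labels used to derive independent child seeds from a master seed
STREAM_TASK = 0
STREAM_RT = 1
STREAM_JITTER = 2

_MAX_REJECTION_DRAWS = 200_000


def child_seed(master_seed: int, *key: int) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed.

    The derivation hashes ``(master_seed, *key)`` through numpy's
    ``SeedSequence`` so that distinct keys give statistically independent
    streams while remaining fully reproducible.
    """
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class TaskConfig:
    """Protocol parameters for one conditioning session.

    With ``fixed_length`` on, the six phase extensions are rejection-sampled
    until phase lengths total exactly ``n_trials_per_session``; with it off the
    session runs open-ended and its length is whatever the geometric triggers
    produce.
    """

    n_trials_per_session: int = 120
    reinforce_prob: float = 0.6
    min_block: int = 16
    trigger_hazard: float = 0.25
    n_pairs: int = 3
    neutral_per_window: int = 2
    balance_window: int = 4
    iti_range_s: tuple[float, float] = (2.0, 11.0)
    fixed_length: bool = True
    session_valence: str = "appetitive"

    def __post_init__(self) -> None:
        for name in ("reinforce_prob", "trigger_hazard"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} must lie in [0, 1]")
        if self.trigger_hazard == 0.0:
            raise ConfigError("trigger_hazard must be positive: phases would never end")
        if self.session_valence not in VALENCES:
            raise ConfigError(f"session_valence must be one of {VALENCES}")
        if self.n_pairs < 1 or self.min_block < 1:
            raise ConfigError("n_pairs and min_block must be positive")
        if not 0 <= self.neutral_per_window <= self.balance_window:
            raise ConfigError("neutral_per_window must fit in the balance window")
        if self.iti_range_s[0] > self.iti_range_s[1] or self.iti_range_s[0] < 0:
            raise ConfigError("iti_range_s must be a nondecreasing pair of seconds")
        if self.fixed_length:
            # every phase is min_block plus a geometric extension of at least 1
            needed = 2 * self.n_pairs * (self.min_block + 1)
            if self.n_trials_per_session < needed:
                raise ConfigError(
                    f"n_trials_per_session={self.n_trials_per_session} cannot fit "
                    f"{2 * self.n_pairs} phases of at least {self.min_block + 1} "
                    f"trials (need >= {needed})"
                )

    @property
    def n_phases(self) -> int:
        return 2 * self.n_pairs


@dataclass(frozen=True)
class TrialRecord:
    """One task event.

    ``latent_state`` is the within-pair id (1 or 2) of the cue currently mapped
    to the valenced liquid; ``cue_id`` is the cue actually shown.
    """

    trial_index: int
    phase_index: int
    pair_index: int
    cue_id: int
    side: str
    outcome: str  # valenced | neutral | none
    latent_state: int
    is_reversal_onset: bool
    is_new_pair_onset: bool
    iti_s: float


@dataclass(frozen=True)
class RTConfig:
    """Parameters of the synthetic log-linear reaction-time model.

    log RT_t = intercept + trend_per_trial * t + switch_effect * switch_t
               + ev_weight * EV_t + Normal(0, noise_sd)

    Defaults emulate a ~0.5 s median simple response with a mild speeding
    trend, a small cost for switching response hand, and faster responses the
    stronger an appetitive outcome is predicted (negative ``ev_weight``; in the
    aversive session the same sign makes responses slower the more strongly an
    unpleasant outcome is predicted, since there EV is negative).
    """

    intercept: float = float(np.log(0.5))
    trend_per_trial: float = -5e-4
    switch_effect: float = 0.05
    ev_weight: float = -0.3
    noise_sd: float = 0.1
    generating_model: str = "HMM"
    generating_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0 (use a tiny value for near-noiseless data)")


@dataclass
class SessionSequence:
    """An ordered realization of one conditioning session."""

    config: TaskConfig
    seed: int
    trials: list[TrialRecord]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def valence(self) -> str:
        return self.config.session_valence

    def cue_keys(self) -> list[tuple[int, int]]:
        """Unique (pair_index, cue_id) identity of the cue shown on each trial."""
        return [(t.pair_index, t.cue_id) for t in self.trials]

    def sides(self) -> np.ndarray:
        return np.array([t.side for t in self.trials])

    def outcomes(self) -> np.ndarray:
        return np.array([t.outcome for t in self.trials])

    def rewards01(self) -> np.ndarray:
        """Salience-coded reward: 1 iff the valenced liquid was delivered."""
        return np.array([1.0 if t.outcome == "valenced" else 0.0 for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; trial indices are 1-based in emitted tables."""
        return pd.DataFrame(
            {
                "trial": [t.trial_index + 1 for t in self.trials],
                "phase": [t.phase_index for t in self.trials],
                "pair": [t.pair_index for t in self.trials],
                "cue": [t.cue_id for t in self.trials],
                "side": [t.side for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
                "latent_state": [t.latent_state for t in self.trials],
                "reversal_onset": [int(t.is_reversal_onset) for t in self.trials],
                "new_pair_onset": [int(t.is_new_pair_onset) for t in self.trials],
                "iti_s": [t.iti_s for t in self.trials],
            }
        )


def _draw_phase_lengths(config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Phase lengths: min_block plus a geometric(trigger_hazard) extension.

    In fixed-length mode the six extensions are redrawn until the lengths sum
    to the session budget, conditioning the geometric draws on the total.
    """
    n_ph = config.n_phases
    for _ in range(_MAX_REJECTION_DRAWS):
        lengths = config.min_block + rng.geometric(config.trigger_hazard, size=n_ph)
        if not config.fixed_length or lengths.sum() == config.n_trials_per_session:
            return lengths
    raise ConfigError(
        "could not draw phase lengths summing to the session budget; "
        "check n_trials_per_session against min_block/n_pairs/trigger_hazard"
    )


def _neutral_slots(total: int, config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean per-trial flags marking slots reserved for the neutral cue.

    Balance is enforced within non-overlapping windows of ``balance_window``
    trials: each full window gets exactly ``neutral_per_window`` neutral slots,
    shuffled; a trailing partial window gets the proportional (floored) count.
    """
    w, k = config.balance_window, config.neutral_per_window
    slots = np.zeros(total, dtype=bool)
    for start in range(0, total, w):
        wlen = min(w, total - start)
        kk = k if wlen == w else (k * wlen) // w
        window = np.zeros(wlen, dtype=bool)
        window[:kk] = True
        rng.shuffle(window)
        slots[start : start + wlen] = window
    return slots


def generate_session(config: TaskConfig, seed: int) -> SessionSequence:
    """Generate one session satisfying the protocol invariants.

    Phases alternate acquisition/reversal per pair; the latent cue-outcome
    mapping swaps exactly at reversal onsets.  Sides are uniform, ITIs uniform
    over ``iti_range_s``, and liquid delivery occurs with ``reinforce_prob``
    independently on each trial.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), STREAM_TASK]))
    lengths = _draw_phase_lengths(config, rng)
    total = int(lengths.sum())
    neutral = _neutral_slots(total, config, rng)
    sides = np.where(rng.random(total) < 0.5, "left", "right")
    deliver = rng.random(total) < config.reinforce_prob
    itis = rng.uniform(*config.iti_range_s, size=total)

    trials: list[TrialRecord] = []
    t = 0
    latent = 1
    for phase in range(config.n_phases):
        pair = phase // 2
        is_reversal_phase = phase % 2 == 1
        if is_reversal_phase:
            latent = 2 if latent == 1 else 1
        else:
            latent = 1  # each new pair starts with cue 1 valenced
        for i in range(int(lengths[phase])):
            neutral_cue = 2 if latent == 1 else 1
            cue = neutral_cue if neutral[t] else latent
            if deliver[t]:
                outcome = "valenced" if cue == latent else "neutral"
            else:
                outcome = "none"
            trials.append(
                TrialRecord(
                    trial_index=t,
                    phase_index=phase,
                    pair_index=pair,
                    cue_id=int(cue),
                    side=str(sides[t]),
                    outcome=outcome,
                    latent_state=latent,
                    is_reversal_onset=is_reversal_phase and i == 0,
                    is_new_pair_onset=(not is_reversal_phase) and i == 0,
                    iti_s=float(itis[t]),
                )
            )
            t += 1
    return SessionSequence(config=config, seed=int(seed), trials=trials)


@dataclass(frozen=True)
class CohortSubject:
    """One synthetic subject: an appetitive and an aversive session."""

    subject: int
    session_order: tuple[str, str]
    appetitive: SessionSequence
    aversive: SessionSequence

    def in_order(self) -> tuple[SessionSequence, SessionSequence]:
        first = getattr(self, self.session_order[0])
        second = getattr(self, self.session_order[1])
        return first, second


def generate_cohort(config: TaskConfig, n_subjects: int, seed: int) -> list[CohortSubject]:
    """Generate a cohort with counterbalanced session order.

    Odd-numbered subjects (1, 3, ...) run the appetitive session first, even
    ones the aversive session first.  Each subject/session draws from an
    independent child stream of ``seed``.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    cohort = []
    for s in range(1, n_subjects + 1):
        sessions = {}
        for code, valence in enumerate(VALENCES):
            cfg = replace(config, session_valence=valence)
            sessions[valence] = generate_session(cfg, child_seed(seed, s, code))
        order = ("appetitive", "aversive") if s % 2 == 1 else ("aversive", "appetitive")
        cohort.append(
            CohortSubject(
                subject=s,
                session_order=order,
                appetitive=sessions["appetitive"],
                aversive=sessions["aversive"],
            )
        )
    return cohort


def simulate_rts(
    session: SessionSequence,
    ev_trace: Sequence[float],
    rt_config: RTConfig,
    seed: int,
) -> np.ndarray:
    """Synthesize reaction times (seconds) with log-normal noise.

    The side-switch indicator is 1 whenever the cue side differs from the
    previous trial's (0 on the first trial).  Returned RTs are strictly
    positive by construction.
    """
    ev = np.asarray(ev_trace, dtype=float)
    if ev.shape != (session.n_trials,):
        raise ValueError(
            f"ev_trace has length {ev.size}, session has {session.n_trials} trials"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), STREAM_RT]))
    sides = session.sides()
    switch = np.zeros(session.n_trials)
    switch[1:] = (sides[1:] != sides[:-1]).astype(float)
    t = np.arange(session.n_trials, dtype=float)
    log_rt = (
        rt_config.intercept
        + rt_config.trend_per_trial * t
        + rt_config.switch_effect * switch
        + rt_config.ev_weight * ev
        + rng.normal(0.0, rt_config.noise_sd, size=session.n_trials)
    )
    return np.exp(log_rt)


@dataclass
class SessionReport:
    """Outcome of validating a session against the protocol invariants."""

    violations: list[str]
    reinforcement_rate: float
    n_trials: int
    n_reversal_onsets: int

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_session(session: SessionSequence) -> SessionReport:
    """Check a (possibly externally supplied) sequence against the protocol.

    Returns an empty violation list iff all invariants hold, together with the
    empirical fraction of trials on which any liquid was delivered.
    """
    cfg = session.config
    trials = session.trials
    v: list[str] = []
    n_rev = sum(t.is_reversal_onset for t in trials)
    if cfg.fixed_length and len(trials) != cfg.n_trials_per_session:
        v.append(
            f"trial count {len(trials)} != configured {cfg.n_trials_per_session}"
        )
    if cfg.fixed_length and n_rev != cfg.n_pairs:
        v.append(f"reversal-onset count {n_rev} != n_pairs {cfg.n_pairs}")

    # phase lengths
    phase_len: dict[int, int] = {}
    for t in trials:
        phase_len[t.phase_index] = phase_len.get(t.phase_index, 0) + 1
    for ph, ln in phase_len.items():
        if ln < cfg.min_block:
            v.append(f"phase {ph} has {ln} trials < min_block {cfg.min_block}")

    # latent state changes exactly at reversal onsets
    for prev, cur in zip(trials, trials[1:]):
        changed = cur.latent_state != prev.latent_state
        if changed and not (cur.is_reversal_onset or cur.is_new_pair_onset):
            v.append(f"latent state changed off-onset at trial {cur.trial_index}")
        if cur.is_reversal_onset and not changed:
            v.append(f"reversal onset without state change at trial {cur.trial_index}")

    # outcome consistency with the latent mapping
    for t in trials:
        maps_valenced = t.cue_id == t.latent_state
        if t.outcome == "valenced" and not maps_valenced:
            v.append(f"valenced outcome for neutral-mapped cue at trial {t.trial_index}")
        if t.outcome == "neutral" and maps_valenced:
            v.append(f"neutral outcome for valenced-mapped cue at trial {t.trial_index}")

    # neutral-cue balance per full non-overlapping window
    w = cfg.balance_window
    for start in range(0, len(trials) - w + 1, w):
        window = trials[start : start + w]
        n_neutral = sum(t.cue_id != t.latent_state for t in window)
        if n_neutral != cfg.neutral_per_window:
            v.append(
                f"window starting at trial {start} has {n_neutral} neutral-cue "
                f"presentations, expected {cfg.neutral_per_window}"
            )

    delivered = sum(t.outcome != "none" for t in trials)
    rate = delivered / len(trials) if trials else float("nan")
    return SessionReport(
        violations=v,
        reinforcement_rate=rate,
        n_trials=len(trials),
        n_reversal_onsets=n_rev,
    )


def phase_hazard_estimate(sessions: Sequence[SessionSequence]) -> tuple[float, int]:
    """Pooled per-trial termination hazard beyond the minimum block.

    For every phase, each trial past ``min_block`` is an at-risk Bernoulli
    trial; the phase's final trial is the one on which the trigger fired.
    Returns ``(hazard, n_at_risk)``.  Meaningful for unconstrained-length
    sessions; conditioning on a fixed total biases the estimate.
    """
    events = 0
    at_risk = 0
    for sess in sessions:
        phase_len: dict[int, int] = {}
        for t in sess.trials:
            phase_len[t.phase_index] = phase_len.get(t.phase_index, 0) + 1
        for ln in phase_len.values():
            extension = ln - sess.config.min_block
            at_risk += extension
            events += 1
    return events / at_risk if at_risk else float("nan"), at_risk
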