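"""Derived comparisons among model traces.

Correlations between trace pairs (full vs reduced HMM expected value;
HMM precision vs Pearce-Hall associability) and the categorical binning of
expected-value traces used when summarizing trial counts and trace levels.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr

from .learners import HMMParams, hmm_filter, ph_run
from .task import SessionSequence

#: default Pearce-Hall intensity for the precision-vs-associability check,
#: a mid-range value of the [0, 1] grid near typical fitted intensities
DEFAULT_PH_INTENSITY = 0.5

#: expected-value split points for the two-bin summaries
EV_SPLIT = {"appetitive": 0.3, "aversive": -0.3}


def trace_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two equally long per-trial traces."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D and of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 trials")
    # constant arrays may carry rounding noise of order eps**2 in their variance
    if np.var(a) < 1e-20 or np.var(b) < 1e-20:
        raise ValueError("a trace has zero variance; correlation is undefined")
    return float(pearsonr(a, b).statistic)


def full_vs_reduced_ev_correlation(
    session: SessionSequence, params: HMMParams | None = None
) -> float:
    """EV-trace correlation between the full and constant-hazard HMMs."""
    full = hmm_filter(session, params)
    reduced = hmm_filter(session, params, reduced=True)
    return trace_correlation(full.ev, reduced.ev)


def precision_vs_associability(
    session: SessionSequence,
    hmm: HMMParams | None = None,
    ph_param: float = DEFAULT_PH_INTENSITY,
) -> float:
    """Correlation of full-HMM precision with Pearce-Hall associability.

    The two quantities both track uncertainty, but from opposite directions
    (precision is prospective and model-based; associability is a reactive
    absolute prediction error), so on this task they are nearly uncorrelated.
    """
    prec = hmm_filter(session, hmm).precision
    assoc = ph_run(session, ph_param).associability
    return trace_correlation(prec, assoc)


def bin_ev(
    ev: np.ndarray, session_type: str, mode: str = "two_bin"
) -> np.ndarray:
    """Categorize an EV trace for reporting.

    ``two_bin`` splits at +0.3 (appetitive) or -0.3 (aversive) into
    low/high; ``tertile`` splits at the empirical tertiles into
    low/medium/high.  Boundary values are assigned to the lower bin.
    """
    ev = np.asarray(ev, dtype=float)
    if mode == "two_bin":
        if session_type not in EV_SPLIT:
            raise ValueError(f"session_type must be one of {sorted(EV_SPLIT)}")
        split = EV_SPLIT[session_type]
        return np.where(ev > split, "high", "low")
    if mode == "tertile":
        q1, q2 = np.quantile(ev, [1 / 3, 2 / 3])
        labels = np.where(ev <= q1, "low", np.where(ev <= q2, "medium", "high"))
        return labels
    raise ValueError("mode must be 'two_bin' or 'tertile'")


def bin_occupancy(labels: np.ndarray) -> dict[str, int]:
    """Trials per bin, in a fixed low/medium/high order."""
    order = ["low", "medium", "high"]
    values, counts = np.unique(np.asarray(labels), return_counts=True)
    got = dict(zip(values.tolist(), counts.tolist()))
    return {k: int(got.get(k, 0)) for k in order if k in got or k != "medium"}


def session_signal_report(
    sessions: list[SessionSequence],
    hmm: HMMParams | None = None,
    ph_param: float = DEFAULT_PH_INTENSITY,
) -> dict:
    """Per-session and mean correlations plus EV-bin occupancy.

    Correlations are computed per session and then averaged, matching
    per-subject reporting conventions.
    """
    ev_rs, pa_rs, occupancy = [], [], []
    for sess in sessions:
        ev_rs.append(full_vs_reduced_ev_correlation(sess, hmm))
        pa_rs.append(precision_vs_associability(sess, hmm, ph_param))
        ev = hmm_filter(sess, hmm).ev
        occupancy.append(bin_occupancy(bin_ev(ev, sess.valence, "two_bin")))
    return {
        "ev_full_vs_reduced_r": ev_rs,
        "mean_ev_full_vs_reduced_r": float(np.mean(ev_rs)),
        "precision_vs_associability_r": pa_rs,
        "mean_abs_precision_vs_associability_r": float(np.mean(np.abs(pa_rs))),
        "ev_two_bin_occupancy": occupancy,
        "mean_trials_high_ev_bin": float(np.mean([o["high"] for o in occupancy])),
        "mean_trials_low_ev_bin": float(np.mean([o["low"] for o in occupancy])),
    }
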