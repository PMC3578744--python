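"""Reaction-time preprocessing and model fitting.

Log reaction times are first adjusted for nuisance structure by regressing
them on an intercept, a linear trial trend and a side-switch indicator; the
residuals are then regressed on each model's expected-value trace.  For the
one-parameter model-free rules the free parameter is grid-searched over [0, 1]
(step 0.001 by default); the hidden Markov variants and the baseline have no
free parameter and need a single regression.  Goodness of fit is summarized by
a Gaussian-residual BIC, n*ln(SSE/n) + k*ln(n), which doubles as an
approximate log model evidence (log evidence ~ -BIC/2) for the random-effects
model selection downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError
from . import learners
from .learners import HMMParams, ModelFreeParams
from .task import SessionSequence, child_seed

GRID_MODELS = ("RW", "PH", "Hybrid")
DEFAULT_GRID_STEP = 0.001
_VAR_EPS = 1e-14


@dataclass(frozen=True)
class FitResult:
    """Best fit of one model to one subject-session's adjusted RTs."""

    model: str
    subject: object
    session: str
    best_param: float | None
    sse: float
    n: int
    k: int
    bic: float


@dataclass
class AdjustedRTs:
    """Residual log-RTs after nuisance adjustment.

    ``kept_idx`` maps each residual back to its 0-based trial index in the
    original session (missing responses are dropped listwise); ``nuisance`` is
    the design matrix the RTs were adjusted with, so that predictors entering
    later regressions can be put through the identical adjustment.
    """

    residuals: np.ndarray
    kept_idx: np.ndarray
    nuisance: np.ndarray

    @property
    def n(self) -> int:
        return len(self.residuals)

    def residualize(self, v: np.ndarray) -> np.ndarray:
        """Project out the nuisance columns from a predictor (or matrix).

        Adjusting the predictor with the same design as the RTs makes the
        two-stage fit equal to a joint regression on
        [nuisance, predictor], so a model generating the data is recovered
        exactly in the noise-free limit.
        """
        coef, *_ = np.linalg.lstsq(self.nuisance, v, rcond=None)
        return v - self.nuisance @ coef


def adjust_rts(rts: np.ndarray, sides: np.ndarray) -> AdjustedRTs:
    """Regress log RTs on [1, trial trend, side switch]; return residuals.

    Missing responses (NaN or non-positive RT) are excluded; the trend column
    keeps the original trial spacing.  The switch indicator is 1 when the
    side differs from the previous trial's.
    """
    rts = np.asarray(rts, dtype=float)
    sides = np.asarray(sides)
    if rts.shape != sides.shape:
        raise ValueError("rts and sides must have equal length")
    switch = np.zeros(len(rts))
    switch[1:] = (sides[1:] != sides[:-1]).astype(float)
    usable = np.isfinite(rts) & (rts > 0)
    kept = np.flatnonzero(usable)
    if kept.size < 4:
        raise FitError(f"only {kept.size} usable trials; need at least 4")
    y = np.log(rts[kept])
    x = np.column_stack([np.ones(kept.size), kept.astype(float), switch[kept]])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return AdjustedRTs(residuals=y - x @ coef, kept_idx=kept, nuisance=x)


def _simple_regression_sse(y: np.ndarray, ev: np.ndarray) -> np.ndarray:
    """SSE of y ~ [1, ev] in closed form, vectorized over EV columns.

    ``ev`` may be 1-D (one trace) or 2-D (trials x grid).  Zero-variance
    columns fall back to the intercept-only fit.
    """
    ev = np.atleast_2d(np.asarray(ev, dtype=float).T).T  # (n, G)
    yc = y - y.mean()
    evc = ev - ev.mean(axis=0)
    syy = float(yc @ yc)
    sxy = yc @ evc
    sxx = np.einsum("ij,ij->j", evc, evc)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = syy - np.where(sxx > _VAR_EPS, sxy**2 / np.where(sxx > 0, sxx, 1.0), 0.0)
    return np.maximum(sse, 0.0)


def compute_bic(sse: float, n: int, k: int) -> float:
    """Gaussian-residual BIC: n*ln(SSE/n) + k*ln(n); lower is better."""
    if not n > k >= 0:
        raise ValueError(f"need n > k >= 0, got n={n}, k={k}")
    if sse <= 0:
        raise FitError("sse must be > 0; a zero-residual fit is degenerate")
    return n * np.log(sse / n) + k * np.log(n)


def make_grid(grid_step: float) -> np.ndarray:
    """Parameter grid over [0, 1]; the step must divide 1 evenly."""
    steps = 1.0 / grid_step
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(f"grid_step={grid_step} does not divide 1 evenly")
    return np.linspace(0.0, 1.0, int(round(steps)) + 1)


# --------------------------------------------------------------------------
# grid-vectorized EV traces for the one-parameter rules
# --------------------------------------------------------------------------

def _grid_ev(session: SessionSequence, model: str, grid: np.ndarray,
             mf: ModelFreeParams) -> np.ndarray:
    """EV trace for every grid value at once; shape (n_trials, len(grid))."""
    rewards = session.rewards01()
    keys = session.cue_keys()
    uniq = {k: i for i, k in enumerate(dict.fromkeys(keys))}
    n_cues = len(uniq)
    g = grid[None, :]  # (1, G)
    q = np.full((n_cues, grid.size), mf.q_init)
    ev = np.empty((len(keys), grid.size))
    if model == "RW":
        for i, key in enumerate(keys):
            c = uniq[key]
            ev[i] = q[c]
            q[c] = q[c] + g[0] * (rewards[i] - q[c])
    elif model == "PH":
        a = np.full((n_cues, grid.size), mf.assoc_init)
        for i, key in enumerate(keys):
            c = uniq[key]
            ev[i] = q[c]
            new_a = np.abs(rewards[i] - q[c])
            q[c] = q[c] + g[0] * a[c] * rewards[i]
            a[c] = new_a
    elif model == "Hybrid":
        a = np.full((n_cues, grid.size), mf.assoc_init)
        for i, key in enumerate(keys):
            c = uniq[key]
            ev[i] = q[c]
            delta = rewards[i] - q[c]
            q[c] = q[c] + mf.kappa * a[c] * delta
            a[c] = g[0] * np.abs(delta) + (1.0 - g[0]) * a[c]
    else:
        raise ValueError(f"{model!r} is not a grid-searched model")
    return ev


def fit_model_to_rts(
    adjusted: AdjustedRTs,
    model: str,
    session: SessionSequence,
    grid_step: float = DEFAULT_GRID_STEP,
    *,
    hmm_params: HMMParams | None = None,
    mf_params: ModelFreeParams | None = None,
    jitter_seed: int = 0,
    subject: object = None,
) -> FitResult:
    """Fit one model's EV trace to one session's adjusted log-RT residuals.

    Grid-searched models report the parameter minimizing the SSE (k = 1);
    the HMM variants (parameters fixed a priori) and the jittered baseline are
    a single regression (k = 0).
    """
    y = adjusted.residuals
    kept = adjusted.kept_idx
    if model in GRID_MODELS:
        grid = make_grid(grid_step)
        mf = mf_params or ModelFreeParams(model=model)
        ev = adjusted.residualize(_grid_ev(session, model, grid, mf)[kept])
        sse = _simple_regression_sse(y, ev)
        best = int(np.argmin(sse))
        best_sse = float(sse[best])
        best_param: float | None = float(grid[best])
        k = 1
    else:
        traces = learners.run_model(
            session, model, hmm_params=hmm_params, mf_params=mf_params,
            seed=jitter_seed if model == "Baseline" else None,
        )
        ev = traces.ev[kept]
        if np.var(ev) <= _VAR_EPS:
            raise FitError(
                f"model {model!r} produced a zero-variance EV trace; "
                "regression against it is singular (baseline needs jitter)"
            )
        ev = adjusted.residualize(ev)
        best_sse = float(_simple_regression_sse(y, ev)[0])
        best_param = None
        k = 0
    return FitResult(
        model=model,
        subject=subject,
        session=session.valence,
        best_param=best_param,
        sse=best_sse,
        n=adjusted.n,
        k=k,
        bic=compute_bic(best_sse, adjusted.n, k),
    )


# --------------------------------------------------------------------------
# cohort-level fitting
# --------------------------------------------------------------------------

@dataclass
class SubjectSessionData:
    """One subject-session ready for fitting: the sequence and its RTs."""

    subject: object
    session: SessionSequence
    rts: np.ndarray


def fit_cohort(
    data: list[SubjectSessionData],
    models: list[str],
    grid_step: float = DEFAULT_GRID_STEP,
    mode: str = "subject",
    *,
    hmm_params: HMMParams | None = None,
    mf_params_by_model: dict[str, ModelFreeParams] | None = None,
    jitter_seed: int = 0,
) -> list[FitResult]:
    """Fit every model to every subject-session (or pooled across subjects).

    ``subject`` mode yields one FitResult per model x subject, giving
    subject-level evidences for random-effects model selection.  ``pooled``
    mode constrains the free parameter to be shared across subjects: each
    grid value is scored by the summed per-subject regression SSE, and the
    BIC uses the total trial count across subjects.
    """
    if mode not in ("subject", "pooled"):
        raise ValueError("mode must be 'subject' or 'pooled'")
    mf_by_model = mf_params_by_model or {}
    # exclude subjects with too few responses (more than half missing)
    usable = []
    for d in data:
        rts = np.asarray(d.rts, dtype=float)
        if np.mean(np.isfinite(rts) & (rts > 0)) < 0.5:
            warnings.warn(
                f"subject {d.subject}: over half of responses missing; excluded",
                stacklevel=2,
            )
        else:
            usable.append(d)
    data = usable
    if not data:
        raise FitError("no subjects with enough responses to fit")
    adjusted = [
        (d, adjust_rts(d.rts, d.session.sides())) for d in data
    ]
    results: list[FitResult] = []
    if mode == "subject":
        for idx, (d, adj) in enumerate(adjusted):
            for model in models:
                results.append(
                    fit_model_to_rts(
                        adj, model, d.session, grid_step,
                        hmm_params=hmm_params,
                        mf_params=mf_by_model.get(model),
                        jitter_seed=child_seed(jitter_seed, idx),
                        subject=d.subject,
                    )
                )
        return results

    valence = data[0].session.valence
    if any(d.session.valence != valence for d in data):
        raise ValueError("pooled fitting mixes sessions of different valence")
    n_total = sum(adj.n for _, adj in adjusted)
    for model in models:
        if model in GRID_MODELS:
            grid = make_grid(grid_step)
            mf = mf_by_model.get(model) or ModelFreeParams(model=model)
            sse_grid = np.zeros(grid.size)
            for d, adj in adjusted:
                ev = adj.residualize(_grid_ev(d.session, model, grid, mf)[adj.kept_idx])
                sse_grid += _simple_regression_sse(adj.residuals, ev)
            best = int(np.argmin(sse_grid))
            sse, best_param, k = float(sse_grid[best]), float(grid[best]), 1
        else:
            sse = 0.0
            for d, adj in adjusted:
                traces = learners.run_model(
                    d.session, model, hmm_params=hmm_params,
                    mf_params=mf_by_model.get(model),
                    seed=jitter_seed if model == "Baseline" else None,
                )
                ev = traces.ev[adj.kept_idx]
                if np.var(ev) <= _VAR_EPS:
                    raise FitError(f"model {model!r} EV trace is degenerate")
                ev = adj.residualize(ev)
                sse += float(_simple_regression_sse(adj.residuals, ev)[0])
            best_param, k = None, 0
        results.append(
            FitResult(
                model=model,
                subject="pooled",
                session=valence,
                best_param=best_param,
                sse=sse,
                n=n_total,
                k=k,
                bic=compute_bic(sse, n_total, k),
            )
        )
    return results


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [f.subject for f in fits],
            "session": [f.session for f in fits],
            "model": [f.model for f in fits],
            "best_param": [f.best_param for f in fits],
            "sse": [f.sse for f in fits],
            "n": [f.n for f in fits],
            "k": [f.k for f in fits],
            "bic": [f.bic for f in fits],
        }
    )
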