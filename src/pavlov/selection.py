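"""Random-effects Bayesian model selection and baseline validation.

``bms_random_effects`` treats the model identity as a random effect across
subjects: model frequencies r follow a Dirichlet whose posterior is estimated
by the standard variational scheme (iterate subject-wise model
responsibilities against Dirichlet counts).  It reports posterior model
frequencies (pp) and exceedance probabilities (xp), the probability that each
model is the most frequent in the population, estimated by Monte-Carlo
sampling of the posterior Dirichlet.

``baseline_validation`` asks whether a model beats a no-learning actor: random
expected-value traces are repeatedly fitted to each subject's adjusted RTs and
the fraction of repetitions on which the random baseline attains the lower BIC
gives a nonparametric per-subject p-value, combined across subjects with
Fisher's method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, logsumexp
from scipy.stats import chi2

from .errors import NumericalError

_MAX_VB_ITER = 10_000
_VB_TOL = 1e-8


@dataclass
class BMSResult:
    """Dirichlet posterior over model frequencies."""

    models: list[str]
    dirichlet_alpha: np.ndarray
    posterior_prob: np.ndarray
    exceedance_prob: np.ndarray
    n_subjects: int
    mc_samples: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "models": list(self.models),
            "dirichlet_alpha": [float(a) for a in self.dirichlet_alpha],
            "pp": {m: float(p) for m, p in zip(self.models, self.posterior_prob)},
            "xp": {m: float(x) for m, x in zip(self.models, self.exceedance_prob)},
            "n_subjects": self.n_subjects,
            "mc_samples": self.mc_samples,
            "seed": self.seed,
        }


@dataclass
class ValidationResult:
    """Per-subject nonparametric p-values against the random baseline."""

    per_subject_p: np.ndarray
    n_reps: int
    fisher_chi2: float
    fisher_df: int
    combined_p: float

    def as_dict(self) -> dict:
        return {
            "per_subject_p": [float(p) for p in self.per_subject_p],
            "n_reps": self.n_reps,
            "fisher_chi2": float(self.fisher_chi2),
            "fisher_df": int(self.fisher_df),
            "combined_p": float(self.combined_p),
        }


def exceedance_from_dirichlet(
    alpha: np.ndarray, mc_samples: int = 10**6, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet distribution."""
    alpha = np.asarray(alpha, dtype=float)
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(mc_samples))
    counts = np.bincount(np.argmax(draws, axis=1), minlength=alpha.size)
    return counts / mc_samples


def bms_random_effects(
    log_evidence: np.ndarray,
    mc_samples: int = 10**6,
    seed: int = 0,
    models: list[str] | None = None,
) -> BMSResult:
    """Variational random-effects model selection over subject evidences.

    ``log_evidence`` is a subjects x models table (e.g. -BIC/2).  Starting
    from a flat Dirichlet prior, subject responsibilities
    u_nk ~ exp(log_evidence_nk + digamma(alpha_k) - digamma(sum alpha)) and
    Dirichlet counts alpha = 1 + sum_n u_n are iterated to convergence.
    """
    lev = np.asarray(log_evidence, dtype=float)
    if lev.ndim != 2 or lev.shape[0] < 2 or lev.shape[1] < 2:
        raise ValueError("log_evidence must be a (>=2 subjects) x (>=2 models) table")
    if not np.all(np.isfinite(lev)):
        raise ValueError("log evidences must be finite")
    n, k = lev.shape
    if models is None:
        models = [f"model{i}" for i in range(k)]
    if len(models) != k:
        raise ValueError("models list must match the number of columns")
    alpha0 = np.ones(k)
    alpha = alpha0.copy()
    for _ in range(_MAX_VB_ITER):
        w = lev + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        new_alpha = alpha0 + u.sum(axis=0)
        if np.abs(new_alpha - alpha).max() < _VB_TOL:
            alpha = new_alpha
            break
        alpha = new_alpha
    else:
        raise NumericalError("variational BMS did not converge")
    pp = alpha / alpha.sum()
    xp = exceedance_from_dirichlet(alpha, mc_samples, seed)
    return BMSResult(
        models=list(models),
        dirichlet_alpha=alpha,
        posterior_prob=pp,
        exceedance_prob=xp,
        n_subjects=n,
        mc_samples=int(mc_samples),
        seed=int(seed),
    )


def fisher_combine(p_values: np.ndarray) -> tuple[float, int, float]:
    """Fisher's combined probability test: chi2 = -2 * sum(ln p), df = 2m."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return stat, df, float(chi2.sf(stat, df))


def baseline_validation(
    model_bics: np.ndarray,
    adjusted_rts: list[np.ndarray],
    n_reps: int = 10_000,
    seed: int = 0,
) -> ValidationResult:
    """Nonparametric test of a model against random expected values.

    For each repetition and subject an i.i.d. uniform [0, 1] EV trace is
    regressed (intercept + slope, no free model parameter, k = 0) against that
    subject's adjusted log-RT residuals.  The per-subject p-value is the
    add-one-corrected fraction of repetitions on which this random baseline
    attains a lower BIC than the model; p-values are combined across subjects
    with Fisher's method.
    """
    bics = np.asarray(model_bics, dtype=float)
    if bics.size != len(adjusted_rts):
        raise ValueError("model_bics and adjusted_rts must be aligned per subject")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    per_p = np.empty(bics.size)
    for i, y in enumerate(adjusted_rts):
        y = np.asarray(y, dtype=float)
        m = y.size
        ev = rng.random((int(n_reps), m))
        yc = y - y.mean()
        evc = ev - ev.mean(axis=1, keepdims=True)
        syy = float(yc @ yc)
        sxy = evc @ yc
        sxx = np.einsum("ij,ij->i", evc, evc)
        sse = np.maximum(syy - sxy**2 / sxx, np.finfo(float).tiny)
        rep_bic = m * np.log(sse / m)  # k = 0
        wins = int(np.sum(rep_bic < bics[i]))
        per_p[i] = (wins + 1) / (n_reps + 1)
    stat, df, combined = fisher_combine(per_p)
    return ValidationResult(
        per_subject_p=per_p,
        n_reps=int(n_reps),
        fisher_chi2=stat,
        fisher_df=df,
        combined_p=combined,
    )
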