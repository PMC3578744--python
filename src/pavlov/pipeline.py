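"""End-to-end orchestration and file I/O.

Ties the stages into one reproducible pipeline: simulate a cohort, compute
model traces, adjust and fit reaction times, run random-effects model
selection and the baseline validation, and emit the trace-comparison report.
All artifacts are plain CSV/JSON with '.' decimals and UTF-8 encoding; a
manifest records the master seed, the resolved configuration and the package
version so any run can be replayed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .fitting import FitResult, SubjectSessionData, adjust_rts, fit_cohort, fits_to_frame
from .learners import MODELS, HMMParams, ModelFreeParams, run_model
from .selection import baseline_validation, bms_random_effects
from .signals import DEFAULT_PH_INTENSITY, session_signal_report
from .task import (
    RTConfig,
    SessionSequence,
    TaskConfig,
    TrialRecord,
    child_seed,
    generate_cohort,
    simulate_rts,
    validate_session,
)

VALENCE_CODE = {"appetitive": 0, "aversive": 1}

DEFAULT_PIPELINE_CONFIG: dict = {
    "n_subjects": 19,
    "task": {},
    "rt": {},
    "hmm": {},
    "ph_intensity": DEFAULT_PH_INTENSITY,
    "grid_step": 0.001,
    "fit_mode": "subject",
    "fit_models": ["HMM", "RW", "PH", "Hybrid", "Baseline"],
    "bms_models": ["HMM", "RW", "PH", "Hybrid"],
    "bms_mc_samples": 1_000_000,
    "validation_reps": 10_000,
}


def load_config(config: dict | str | Path | None) -> dict:
    """Merge a user config (dict or JSON path) over the pipeline defaults."""
    merged = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    if config is None:
        return merged
    if not isinstance(config, dict):
        with open(config, encoding="utf-8") as fh:
            config = json.load(fh)
    for key, value in config.items():
        if key not in merged:
            raise ConfigError(f"unknown configuration key {key!r}")
        if isinstance(merged[key], dict) and isinstance(value, dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def _task_config(cfg: dict, valence: str) -> TaskConfig:
    return TaskConfig(session_valence=valence, **cfg["task"])


def build_cohort_frame(cfg: dict, seed: int) -> tuple[pd.DataFrame, dict]:
    """Simulate the cohort with reaction times; return sessions table + seeds.

    Reaction times are generated from the configured generating model's EV
    trace (full HMM by default) through the log-linear RT model.
    """
    n_subjects = int(cfg["n_subjects"])
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    rt_cfg = RTConfig(**cfg["rt"])
    hmm = HMMParams(**cfg["hmm"])
    base_task = _task_config(cfg, "appetitive")
    cohort = generate_cohort(base_task, n_subjects, seed)
    frames = []
    seeds: dict = {"master": int(seed), "subjects": {}}
    for subj in cohort:
        seeds["subjects"][subj.subject] = {}
        for valence in subj.session_order:
            session: SessionSequence = getattr(subj, valence)
            gen = run_model(
                session, rt_cfg.generating_model, hmm_params=hmm,
                seed=child_seed(seed, subj.subject, VALENCE_CODE[valence], 9),
            )
            rt_seed = child_seed(seed, subj.subject, VALENCE_CODE[valence], 1)
            rts = simulate_rts(session, gen.ev, rt_cfg, rt_seed)
            frame = session.to_frame()
            frame.insert(0, "session", valence)
            frame.insert(0, "subject", subj.subject)
            frame["rt_s"] = rts
            frames.append(frame)
            seeds["subjects"][subj.subject][valence] = {
                "task": session.seed,
                "rt": rt_seed,
            }
    return pd.concat(frames, ignore_index=True), seeds


def session_from_frame(frame: pd.DataFrame, config: TaskConfig, seed: int = -1) -> SessionSequence:
    """Rebuild a SessionSequence from one subject-session block of sessions.csv."""
    trials = [
        TrialRecord(
            trial_index=int(row.trial) - 1,
            phase_index=int(row.phase),
            pair_index=int(row.pair),
            cue_id=int(row.cue),
            side=str(row.side),
            outcome=str(row.outcome),
            latent_state=int(row.latent_state),
            is_reversal_onset=bool(row.reversal_onset),
            is_new_pair_onset=bool(row.new_pair_onset),
            iti_s=float(row.iti_s),
        )
        for row in frame.sort_values("trial").itertuples()
    ]
    return SessionSequence(config=config, seed=seed, trials=trials)


def frame_to_subject_data(
    frame: pd.DataFrame, cfg: dict, valence: str
) -> list[SubjectSessionData]:
    """Split a sessions table into per-subject fitting inputs for one valence."""
    task = _task_config(cfg, valence)
    out = []
    sub = frame[frame["session"] == valence]
    for subject, block in sub.groupby("subject"):
        session = session_from_frame(block, task)
        rts = block.sort_values("trial")["rt_s"].to_numpy(dtype=float)
        out.append(SubjectSessionData(subject=subject, session=session, rts=rts))
    return out


def trace_frame(cfg: dict, data: list[SubjectSessionData], valence: str) -> pd.DataFrame:
    """Per-trial traces of every model for every subject-session."""
    hmm = HMMParams(**cfg["hmm"])
    rows = []
    for d in data:
        for model in MODELS:
            mf = None
            if model in ("RW", "PH", "Hybrid"):
                mf = ModelFreeParams(model=model, rate_or_intensity=cfg["ph_intensity"])
            traces = run_model(
                d.session, model, hmm_params=hmm, mf_params=mf,
                seed=child_seed(0, VALENCE_CODE[valence], int(d.subject)),
            )
            n = d.session.n_trials

            def col(x):
                return x if x is not None else np.full(n, np.nan)

            rows.append(
                pd.DataFrame(
                    {
                        "subject": d.subject,
                        "session": valence,
                        "trial": np.arange(1, n + 1),
                        "model": model,
                        "ev": traces.ev,
                        "precision": col(traces.precision),
                        "associability": col(traces.associability),
                        "prediction_error": col(traces.prediction_error),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path, seed: int) -> dict:
    """Simulate, trace, fit, compare, validate and report in one pass.

    Returns the manifest (also written to ``manifest.json``).  The run is
    idempotent for a fixed seed: every random draw derives from it.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hmm = HMMParams(**cfg["hmm"])

    sessions_df, seeds = build_cohort_frame(cfg, seed)
    sessions_df.to_csv(out / "sessions.csv", index=False)

    all_fits: list[FitResult] = []
    bms_out: dict = {}
    validation_out: dict = {}
    report_out: dict = {}
    traces_frames = []
    for valence in ("appetitive", "aversive"):
        data = frame_to_subject_data(sessions_df, cfg, valence)
        for d in data:
            report = validate_session(d.session)
            if not report.ok:
                raise ConfigError(
                    f"generated session failed validation (subject {d.subject}, "
                    f"{valence}): {report.violations[:3]}"
                )
        traces_frames.append(trace_frame(cfg, data, valence))

        fits = fit_cohort(
            data,
            cfg["fit_models"],
            grid_step=cfg["grid_step"],
            mode=cfg["fit_mode"],
            hmm_params=hmm,
            jitter_seed=child_seed(seed, VALENCE_CODE[valence], 2),
        )
        all_fits.extend(fits)

        if cfg["fit_mode"] == "subject":
            fit_df = fits_to_frame(fits)
            models = list(cfg["bms_models"])
            lev = (
                fit_df[fit_df["model"].isin(models)]
                .pivot(index="subject", columns="model", values="bic")[models]
                .to_numpy()
            )
            bms = bms_random_effects(
                -lev / 2.0,
                mc_samples=int(cfg["bms_mc_samples"]),
                seed=child_seed(seed, VALENCE_CODE[valence], 3),
                models=models,
            )
            bms_out[valence] = bms.as_dict()

            adjusted = {d.subject: adjust_rts(d.rts, d.session.sides()) for d in data}
            validation_out[valence] = {}
            for model_idx, model in enumerate(models):
                rows = fit_df[fit_df["model"] == model].set_index("subject")
                subjects = sorted(adjusted)
                result = baseline_validation(
                    rows.loc[subjects, "bic"].to_numpy(),
                    [adjusted[s].residuals for s in subjects],
                    n_reps=int(cfg["validation_reps"]),
                    seed=child_seed(seed, VALENCE_CODE[valence], 4, model_idx),
                )
                validation_out[valence][model] = result.as_dict()

        report_out[valence] = session_signal_report(
            [d.session for d in data], hmm, cfg["ph_intensity"]
        )

    pd.concat(traces_frames, ignore_index=True).to_csv(out / "traces.csv", index=False)
    fits_to_frame(all_fits).to_csv(out / "fits.csv", index=False)
    for name, payload in (
        ("bms.json", bms_out),
        ("validation.json", validation_out),
        ("report.json", report_out),
    ):
        with open(out / name, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    artifacts = [
        "sessions.csv", "traces.csv", "fits.csv", "bms.json",
        "validation.json", "report.json",
    ]
    manifest = {
        "package": "pavlov",
        "version": __version__,
        "seed": int(seed),
        "seeds": seeds,
        "config": cfg,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def hmm_params_to_json(params: HMMParams) -> dict:
    return dataclasses.asdict(params)
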