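"""Learning models: transition/emission building blocks, filters, update rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pavlov
from pavlov import HMMParams, NumericalError
from pavlov.learners import hmm_enumeration_oracle

from conftest import make_session, random_short_session


class TestHMMBuildingBlocks:
    @pytest.mark.parametrize(
        "alpha,expected",
        [
            (0.0, [[1, 0], [0, 1]]),
            (1.0, [[0, 1], [0, 1]]),
            (0.25, [[0.75, 0.25], [0, 1]]),
        ],
    )
    def test_h_transition(self, alpha, expected):
        np.testing.assert_allclose(pavlov.h_transition_matrix(alpha), expected)

    def test_h_transition_is_absorbing(self):
        m = pavlov.h_transition_matrix(0.4)
        assert m[1, 0] == 0.0 and m[1, 1] == 1.0
        np.testing.assert_allclose(m.sum(axis=1), 1.0)

    @pytest.mark.parametrize("beta", [0.0, 0.25, 0.9])
    def test_s_transition_frozen_without_expectation(self, beta):
        np.testing.assert_allclose(pavlov.s_transition_given_h(beta, 0), np.eye(2))

    def test_s_transition_swaps_under_expectation(self):
        m = pavlov.s_transition_given_h(0.25, 1)
        np.testing.assert_allclose(m, [[0.75, 0.25], [0.25, 0.75]])
        np.testing.assert_allclose(pavlov.s_transition_given_h(1.0, 1), [[0, 1], [1, 0]])

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            pavlov.h_transition_matrix(1.5)
        with pytest.raises(ValueError):
            pavlov.s_transition_given_h(-0.1, 1)

    @pytest.mark.parametrize(
        "state,cue,outcome,expected",
        [
            (1, 1, "none", 0.4),
            (1, 1, "valenced", 0.6),
            (1, 1, "neutral", 0.0),
            (1, 2, "neutral", 0.6),
            (1, 2, "valenced", 0.0),
            (2, 1, "none", 0.4),
        ],
    )
    def test_emission_likelihood(self, state, cue, outcome, expected):
        assert pavlov.emission_likelihood(state, cue, outcome, HMMParams()) == expected


class TestPrecision:
    def test_uniform_posterior_has_zero_precision(self):
        assert pavlov.precision_from_posterior([0.5, 0.5]) == pytest.approx(0.0)

    def test_point_mass_has_unit_precision(self):
        assert pavlov.precision_from_posterior([1.0, 0.0]) == pytest.approx(1.0)

    def test_skewed_posterior_matches_entropy_arithmetic(self):
        # H(0.9, 0.1) = 0.4690 bits -> negentropy precision 0.5310
        assert pavlov.precision_from_posterior([0.9, 0.1]) == pytest.approx(0.531, abs=5e-4)

    def test_reciprocal_mode_is_monotone_with_negentropy(self):
        ps = [[0.5, 0.5], [0.6, 0.4], [0.8, 0.2], [0.99, 0.01]]
        neg = [pavlov.precision_from_posterior(p, "negentropy") for p in ps]
        rec = [pavlov.precision_from_posterior(p, "reciprocal") for p in ps]
        assert np.all(np.diff(neg) > 0) and np.all(np.diff(rec) > 0)

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            pavlov.precision_from_posterior([0.9, 0.3])

    @given(st.floats(0.001, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_precision_strictly_decreasing_in_entropy(self, p):
        # entropy of (p, 1-p) increases toward p=0.5; precision must decrease
        closer = p + (0.5 - p) * 0.1
        assert pavlov.precision_from_posterior([p, 1 - p]) >= pavlov.precision_from_posterior(
            [closer, 1 - closer]
        ) - 1e-12


class TestHMMFilter:
    def test_fresh_pair_expected_value_is_symmetric(self, one_session):
        traces = pavlov.hmm_filter(one_session)
        onsets = [t.trial_index for t in one_session.trials if t.is_new_pair_onset]
        for i in onsets:
            assert traces.ev[i] == pytest.approx(0.3)
            assert traces.precision[i] == pytest.approx(0.0)

    def test_hand_forward_recursion_two_trials(self):
        # cue 1 shown, valenced delivered: posterior is a point mass; next
        # trial's predictive stay-probability is 0.8*1 + 0.2*0.75 = 0.95
        s = make_session([(1, "valenced"), (1, "none")])
        traces = pavlov.hmm_filter(s, HMMParams(alpha=0.2, beta=0.25))
        assert traces.posterior_s[1, 0] == pytest.approx(0.95)
        assert traces.ev[1] == pytest.approx(0.57)

    def test_certain_aversive_state_gives_minus_point_six(self):
        s = make_session(
            [(1, "valenced"), (1, "valenced"), (1, "none")], valence="aversive"
        )
        traces = pavlov.hmm_filter(s, HMMParams(alpha=0.0, beta=0.25))
        # alpha=0 keeps H off, so the point-mass belief after trial 1 persists
        assert traces.ev[1] == pytest.approx(-0.6)
        assert abs(traces.ev[2]) == pytest.approx(0.6)

    def test_filter_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for case in range(12):
            n = int(rng.integers(3, 9))
            s = random_short_session(rng, n)
            for reduced in (False, True):
                traces = pavlov.hmm_filter(s, reduced=reduced)
                oracle = hmm_enumeration_oracle(s, reduced=reduced)
                np.testing.assert_allclose(traces.posterior_s, oracle, atol=1e-10)

    def test_filter_matches_log_space_recursion(self, one_session):
        # independent oracle: same recursion in log space on the S marginal path
        traces = pavlov.hmm_filter(one_session)
        oracle = _log_space_filter(one_session, HMMParams())
        np.testing.assert_allclose(traces.posterior_s, oracle, atol=1e-10)

    def test_belief_stays_normalized_and_bounded(self, appetitive_sessions):
        for s in appetitive_sessions[:5]:
            for reduced in (False, True):
                traces = pavlov.hmm_filter(s, reduced=reduced)
                np.testing.assert_allclose(
                    traces.posterior_s.sum(axis=1), 1.0, atol=1e-12
                )
                assert np.all(np.abs(traces.ev) <= 0.6 + 1e-12)
                assert not pavlov.check_trace_bounds(traces)

    def test_impossible_observation_raises_with_trial_index(self):
        # point-mass on cue1->valenced (alpha=0 freezes it), then cue 1 yields
        # the neutral liquid: zero likelihood under every state
        s = make_session([(1, "valenced"), (1, "neutral")])
        with pytest.raises(NumericalError, match="trial 1"):
            pavlov.hmm_filter(s, HMMParams(alpha=0.0, beta=0.25))


class TestReducedHMM:
    def test_reduced_tracks_full_ev_closely(self, appetitive_sessions):
        rs = [pavlov.full_vs_reduced_ev_correlation(s) for s in appetitive_sessions]
        assert min(rs) > 0.95

    def test_clamped_beta_zero_never_infers_reversal(self):
        # once certain, a beta=0 learner can never revise: EV stays pinned at
        # 0.6 through a run of unreinforced outcomes
        events = [(1, "valenced")] * 3 + [(1, "none")] * 7
        s = make_session(events)
        traces = pavlov.reduced_hmm_filter(s, HMMParams(alpha=0.2, beta=0.0))
        np.testing.assert_allclose(traces.ev[1:], 0.6)

    def test_full_precision_declines_in_anticipation_reduced_stays_flat(self):
        # consistent reinforcement: each outcome restores certainty, so any
        # decline in predictive precision is driven purely by the growing
        # reversal expectation -- present in the full model, absent (flat
        # constant hazard) in the reduced one
        events = [(1, "valenced")] * 12
        s = make_session(events)
        full = pavlov.hmm_filter(s).precision
        red = pavlov.reduced_hmm_filter(s).precision
        assert np.all(np.diff(full[1:]) < 0)
        np.testing.assert_allclose(np.diff(red[1:]), 0.0, atol=1e-12)
        assert full[1] > red[1] + 0.2


class TestModelFreeRules:
    def test_rw_update_examples(self, one_session):
        s = make_session([(1, "valenced"), (1, "none"), (1, "none")])
        traces = pavlov.rw_run(s, alpha=0.5)
        assert traces.ev[1] == pytest.approx(0.5)  # half-step from zero
        frozen = pavlov.rw_run(s, alpha=0.0, q_init=0.4)
        np.testing.assert_allclose(frozen.ev, 0.4)
        # Q=0.5, R=0, alpha=0.54 -> 0.5 + 0.54*(0-0.5) = 0.23
        t2 = pavlov.rw_run(s, alpha=0.54, q_init=0.5)
        assert t2.ev[1] == pytest.approx(0.77)   # after R=1: 0.5+0.54*0.5
        t3 = pavlov.rw_run(make_session([(1, "none"), (1, "none")]), 0.54, q_init=0.5)
        assert t3.ev[1] == pytest.approx(0.23)

    def test_ph_first_presentation_update(self):
        s = make_session([(1, "valenced"), (1, "none")])
        traces = pavlov.ph_run(s, s_intensity=0.4)
        assert traces.ev[1] == pytest.approx(0.4)  # 0 + 0.4*1*1

    def test_ph_unreinforced_trials_leave_q_unchanged(self):
        s = make_session([(1, "valenced"), (1, "none"), (1, "none"), (1, "none")])
        traces = pavlov.ph_run(s, s_intensity=0.7)
        assert traces.ev[2] == traces.ev[1] == traces.ev[3]

    def test_ph_associability_vanishes_as_predictions_sharpen(self):
        # consistent reinforcement: Q approaches R, so the absolute error that
        # feeds associability decays toward zero
        s = make_session([(1, "valenced")] * 12)
        traces = pavlov.ph_run(s, s_intensity=0.3)
        assoc = traces.associability
        # monotone decline while Q climbs toward R (the rule is not
        # error-correcting, so a slight overshoot keeps a small residual error)
        assert np.all(np.diff(assoc[1:7]) < 1e-12)
        assert assoc.min() < 0.05
        assert traces.ev[-1] == pytest.approx(1.0, abs=0.05)

    def test_hybrid_two_step_hand_example(self):
        s = make_session([(1, "valenced"), (1, "valenced"), (1, "valenced")])
        traces = pavlov.hybrid_run(s, eta=0.5, kappa=1.0)
        np.testing.assert_allclose(traces.ev, [0.0, 1.0, 1.0])
        np.testing.assert_allclose(traces.associability, [1.0, 1.0, 0.5])

    def test_hybrid_with_eta_zero_reduces_to_rw(self, one_session):
        hybrid = pavlov.hybrid_run(one_session, eta=0.0, kappa=0.3, assoc_init=1.0)
        rw = pavlov.rw_run(one_session, alpha=0.3)
        np.testing.assert_allclose(hybrid.ev, rw.ev)

    def test_hybrid_zero_error_fixed_point(self):
        s = make_session([(1, "valenced")] * 5)
        traces = pavlov.hybrid_run(s, eta=0.5, kappa=1.0, q_init=1.0)
        np.testing.assert_allclose(traces.ev, 1.0)
        np.testing.assert_allclose(traces.prediction_error, 0.0)

    def test_model_free_q_bounded_for_unit_rates(self, appetitive_sessions):
        for s in appetitive_sessions[:5]:
            for traces in (
                pavlov.rw_run(s, 0.9),
                pavlov.hybrid_run(s, eta=0.7, kappa=1.0),
            ):
                assert not pavlov.check_trace_bounds(traces)

    def test_baseline_constant_and_jitter(self, one_session):
        plain = pavlov.baseline_run(one_session)
        np.testing.assert_allclose(plain.ev, 0.5)
        j1 = pavlov.baseline_run(one_session, seed=3)
        j2 = pavlov.baseline_run(one_session, seed=3)
        np.testing.assert_allclose(j1.ev, j2.ev)
        assert np.var(j1.ev) > 0
        long = make_session([(1, "none")] * 10_000)
        jl = pavlov.baseline_run(long, seed=1)
        assert jl.ev.mean() == pytest.approx(0.5, abs=3 * 0.01 / np.sqrt(10_000))


def _log_space_filter(session, params):
    """Forward recursion carried in log space: an underflow-proof oracle."""
    t_h = pavlov.h_transition_matrix(params.alpha)
    t_s = [pavlov.s_transition_given_h(params.beta, h) for h in (0, 1)]
    out = np.empty((session.n_trials, 2))
    log_joint = None
    with np.errstate(divide="ignore"):
        for i, trial in enumerate(session.trials):
            if trial.is_new_pair_onset:
                log_joint = np.log(np.array([[0.5, 0.0], [0.5, 0.0]]))
            else:
                lin = np.exp(log_joint - log_joint.max())
                lin = lin @ t_h
                new = np.empty_like(lin)
                for h in (0, 1):
                    new[:, h] = t_s[h].T @ lin[:, h]
                log_joint = np.log(new) + log_joint.max()
            p = np.exp(log_joint)
            out[i] = p.sum(axis=1) / p.sum()
            lik = np.array(
                [
                    pavlov.emission_likelihood(s, trial.cue_id, trial.outcome, params)
                    for s in (1, 2)
                ]
            )
            log_joint = log_joint + np.log(lik)[:, None]
            norm = np.exp(log_joint - log_joint.max()).sum()
            log_joint -= np.log(norm) + log_joint.max()
    return out
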