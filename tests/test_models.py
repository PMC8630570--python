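"""Generative-model contracts: choice rules, updates, exact likelihoods.

The likelihood tests use independent brute-force oracles: tiny recursive
enumerations of every choice path, written with their own arithmetic, never
calling the implementation under test for probabilities.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import setshift as ss
from setshift._kernels import prl_loglik_batch, wcst_loglik_batch
from setshift.fitting import pack_trials
from setshift.models import MATCH_EPS
from setshift.tasks import Card, DIMENSIONS, WCSTConfig, wcst_match


def make_prl_trials(choices, outcomes):
    n = len(choices)
    return pd.DataFrame(
        {
            "subject_id": ["s"] * n,
            "trial_index": range(1, n + 1),
            "choice": list(choices),
            "feedback": list(outcomes),
        }
    )


# ---------------------------------------------------------------------------
# PRL
# ---------------------------------------------------------------------------


class TestPRLChoice:
    def test_symmetry_and_zero_sensitivity(self):
        p = ss.PRLParams(0.3, 0.3, 2.0, 0.0)
        probs = ss.prl_choice_probs(p, ss.PRLAgentState(q_values=(0.5, 0.5)))
        assert probs["A"] == pytest.approx(0.5)
        p0 = ss.PRLParams(0.3, 0.3, 0.0, 0.0)
        probs = ss.prl_choice_probs(p0, ss.PRLAgentState(q_values=(0.9, 0.1)))
        assert probs["A"] == pytest.approx(0.5)

    def test_sticky_softmax_value(self):
        # logistic of beta*(Q_A - Q_B) + kappa = 3*0.6 + 0.5
        p = ss.PRLParams(0.3, 0.3, 3.0, 0.5)
        state = ss.PRLAgentState(q_values=(0.8, 0.2), prev_choice="A")
        expected = 1.0 / (1.0 + math.exp(-(3 * 0.6 + 0.5)))
        assert ss.prl_choice_probs(p, state)["A"] == pytest.approx(expected)
        assert expected == pytest.approx(0.909, abs=5e-4)

    @given(
        q=st.tuples(
            st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)
        ),
        beta=st.floats(0, 20),
        kappa=st.floats(-3, 3),
        shift=st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, q, beta, kappa, shift):
        """Adding a constant to both Q values leaves choice probabilities
        unchanged (softmax property the stickiness term must not break)."""
        p = ss.PRLParams(0.3, 0.3, beta, kappa)
        s1 = ss.PRLAgentState(q_values=q, prev_choice="B")
        s2 = ss.PRLAgentState(q_values=(q[0] + shift, q[1] + shift), prev_choice="B")
        p1, p2 = ss.prl_choice_probs(p, s1), ss.prl_choice_probs(p, s2)
        assert p1["A"] == pytest.approx(p2["A"], abs=1e-9)
        assert p1["A"] + p1["B"] == pytest.approx(1.0, abs=1e-9)


class TestPRLUpdate:
    @pytest.mark.parametrize(
        "q0,outcome,a_rew,a_pun,expected",
        [
            (0.5, 1, 0.0, 0.3, 0.5),  # zero reward rate: no change
            (0.5, 1, 0.4, 0.3, 0.7),
            (0.6, 0, 0.4, 0.25, 0.45),
        ],
    )
    def test_delta_rule(self, q0, outcome, a_rew, a_pun, expected):
        p = ss.PRLParams(a_rew, a_pun, 1.0, 0.0)
        new = ss.prl_update(p, ss.PRLAgentState(q_values=(q0, 0.5)), "A", outcome)
        assert new.q_values[0] == pytest.approx(expected)
        assert new.q_values[1] == 0.5  # unchosen untouched
        assert new.prev_choice == "A"

    def test_invalid_outcome(self):
        p = ss.PRLParams(0.3, 0.3, 1.0, 0.0)
        with pytest.raises(ValueError):
            ss.prl_update(p, ss.PRLAgentState(), "A", 2)

    @given(
        seq=st.lists(
            st.tuples(st.sampled_from(["A", "B"]), st.sampled_from([0, 1])),
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_q_stays_in_unit_interval(self, seq):
        p = ss.PRLParams(0.7, 0.9, 1.0, 0.0)
        state = ss.PRLAgentState()
        for choice, outcome in seq:
            state = ss.prl_update(p, state, choice, outcome)
            assert all(0.0 <= q <= 1.0 for q in state.q_values)


def prl_path_logprob(params, choices, outcomes):
    """Independent oracle: log path probability by explicit recursion."""
    qa, qb = 0.5, 0.5
    prev = None
    lp = 0.0
    for c, o in zip(choices, outcomes):
        la = params.beta * qa + (params.kappa if prev == "A" else 0.0)
        lb = params.beta * qb + (params.kappa if prev == "B" else 0.0)
        pa = math.exp(la) / (math.exp(la) + math.exp(lb))
        lp += math.log(pa if c == "A" else 1 - pa)
        rate = params.alpha_rew if o == 1 else params.alpha_pun
        if c == "A":
            qa += rate * (o - qa)
        else:
            qb += rate * (o - qb)
        prev = c
    return lp


class TestPRLLoglik:
    def test_uniform_policy_closed_form(self):
        p = ss.PRLParams(0.4, 0.2, 0.0, 0.0)
        for n in (1, 7, 80):
            trials = make_prl_trials(["A"] * n, [1] * n)
            assert ss.prl_loglik(p, trials) == pytest.approx(n * math.log(0.5))

    def test_exhaustive_enumeration_all_length3_paths(self):
        """Likelihood equals the brute-force path probability for every
        choice x outcome sequence of length <= 3, and path probabilities sum
        to 1 over choices for any fixed outcome rule."""
        p = ss.PRLParams(0.35, 0.55, 2.7, 0.8)
        for n in (1, 2, 3):
            for outcomes in itertools.product([0, 1], repeat=n):
                total = 0.0
                for choices in itertools.product("AB", repeat=n):
                    trials = make_prl_trials(choices, outcomes)
                    lp = ss.prl_loglik(p, trials)
                    assert lp == pytest.approx(
                        prl_path_logprob(p, choices, outcomes), abs=1e-10
                    )
                    # with the outcome schedule fixed irrespective of choice,
                    # the choice paths partition probability 1
                    total += math.exp(lp)
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_relabeling_symmetry(self, prl_session):
        """Swapping the A/B labels of choices leaves the likelihood
        unchanged (the model is label-agnostic)."""
        params, trials = prl_session
        swapped = trials.copy()
        swapped["choice"] = swapped["choice"].map({"A": "B", "B": "A"})
        assert ss.prl_loglik(params, trials) == pytest.approx(
            ss.prl_loglik(params, swapped)
        )

    def test_true_params_beat_distant_params(self):
        """Average log-likelihood under the generating parameters exceeds a
        distant parameter set over 50 simulated subjects."""
        truth = ss.PRLParams(0.4, 0.4, 6.0, 0.5)
        distant = ss.PRLParams(0.9, 0.05, 0.5, -2.0)
        gap = 0.0
        for seed in range(50):
            trials = ss.prl_simulate(truth, seed=seed)
            gap += ss.prl_loglik(truth, trials) - ss.prl_loglik(distant, trials)
        assert gap / 50 > 0

    def test_mixed_subject_rejected(self):
        trials = make_prl_trials("AAB", [1, 0, 1])
        trials.loc[2, "subject_id"] = "other"
        with pytest.raises(ss.TrialDataError):
            ss.prl_loglik(ss.PRLParams(0.3, 0.3, 1.0, 0.0), trials)


class TestPRLSimulate:
    def test_seed_determinism(self):
        p = ss.PRLParams(0.4, 0.3, 4.0, 0.3)
        a = ss.prl_simulate(p, seed=11)
        b = ss.prl_simulate(p, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_value_greedy_agent_learns(self):
        p = ss.PRLParams(0.5, 0.5, 100.0, 0.0)
        trials = ss.prl_simulate(p, seed=3)
        acq = trials[trials.phase_or_set == "acquisition"]
        acc = (acq.choice == acq.stimulus_or_card).mean()
        assert acc > 0.7

    def test_uniform_agent(self):
        p = ss.PRLParams(0.4, 0.4, 0.0, 0.0)
        trials = pd.concat(
            [ss.prl_simulate(p, seed=s) for s in range(20)], ignore_index=True
        )
        assert abs((trials.choice == "A").mean() - 0.5) < 0.03

    def test_stickiness_dominant_agent_repeats(self):
        p = ss.PRLParams(0.0, 0.0, 0.0, 10.0)
        trials = ss.prl_simulate(p, seed=5)
        first = trials.choice.iloc[0]
        assert (trials.choice == first).mean() > 0.95


# ---------------------------------------------------------------------------
# WCST
# ---------------------------------------------------------------------------


class TestWCSTChoice:
    def test_uniform_attention_hand_case(self):
        p = ss.WCSTParams(0.3, 0.3, 1.0)
        card = Card("red", "triangle", 2)
        probs = ss.wcst_choice_probs(p, ss.WCSTAgentState(), card)
        m = np.array([2 / 3, 1 / 3, MATCH_EPS, MATCH_EPS])
        np.testing.assert_allclose(probs, m / m.sum(), rtol=1e-9)

    def test_zero_consistency_is_uniform(self):
        p = ss.WCSTParams(0.3, 0.3, 0.0)
        state = ss.WCSTAgentState(attention=(0.7, 0.2, 0.1))
        probs = ss.wcst_choice_probs(p, state, Card("blue", "star", 3))
        np.testing.assert_allclose(probs, 0.25)

    def test_large_consistency_concentrates(self):
        p = ss.WCSTParams(0.3, 0.3, 50.0)
        probs = ss.wcst_choice_probs(p, ss.WCSTAgentState(), Card("red", "triangle", 2))
        assert probs[0] > 0.999  # deck 1 has the largest match signal


class TestWCSTUpdate:
    def test_reward_reallocation_hand_case(self):
        # card chosen deck matches {color}; lambda = r = 0.4
        p = ss.WCSTParams(0.4, 0.9, 1.0)
        state = ss.WCSTAgentState(attention=(0.5, 0.3, 0.2))
        card = Card("red", "star", 3)  # deck 1: matches color only
        new = ss.wcst_update(p, state, card, 1, 1)
        np.testing.assert_allclose(new.attention, (0.7, 0.18, 0.12), atol=1e-12)

    def test_punishment_reallocation_hand_case(self):
        # negative feedback on a color-only match: consistent = {shape, number}
        p = ss.WCSTParams(0.9, 0.5, 1.0)
        state = ss.WCSTAgentState(attention=(0.5, 0.3, 0.2))
        card = Card("red", "star", 3)
        new = ss.wcst_update(p, state, card, 1, 0)
        np.testing.assert_allclose(new.attention, (0.25, 0.45, 0.30), atol=1e-12)

    def test_zero_rate_no_change(self):
        p = ss.WCSTParams(0.0, 0.0, 1.0)
        state = ss.WCSTAgentState(attention=(0.6, 0.3, 0.1))
        card = Card("red", "star", 3)
        for fb in (0, 1):
            new = ss.wcst_update(p, state, card, 1, fb)
            np.testing.assert_allclose(new.attention, state.attention)

    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 63), st.integers(1, 4), st.sampled_from([0, 1])
            ),
            max_size=30,
        ),
        r=st.floats(0.01, 0.99),
        p_=st.floats(0.01, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_attention_stays_on_simplex(self, data, r, p_):
        from setshift.tasks import full_deck

        deck = full_deck()
        params = ss.WCSTParams(r, p_, 1.0)
        state = ss.WCSTAgentState()
        for card_i, choice, fb in data:
            card = deck[card_i]
            # the task never gives positive feedback on a zero-match deck
            if fb == 1 and len(wcst_match(card, choice)) == 0:
                fb = 0
            state = ss.wcst_update(params, state, card, choice, fb)
            a = np.array(state.attention)
            assert (a >= -1e-12).all()
            assert a.sum() == pytest.approx(1.0, abs=1e-9)


def make_wcst_trials(cards, choices, feedback):
    from setshift.io import card_to_str

    n = len(cards)
    return pd.DataFrame(
        {
            "subject_id": ["s"] * n,
            "trial_index": range(1, n + 1),
            "stimulus_or_card": [card_to_str(c) for c in cards],
            "choice": list(choices),
            "feedback": list(feedback),
        }
    )


def wcst_path_logprob(params, cards, choices, feedback):
    """Independent oracle: sequential attention model by direct arithmetic."""
    att = {"color": 1 / 3, "shape": 1 / 3, "number": 1 / 3}
    lp = 0.0
    for card, choice, fb in zip(cards, choices, feedback):
        m = []
        for k in range(1, 5):
            dims = wcst_match(card, k)
            m.append(max(sum(att[d] for d in dims), MATCH_EPS))
        w = [x**params.d for x in m]
        lp += math.log(w[choice - 1] / sum(w))
        dims = wcst_match(card, choice)
        consistent = dims if fb == 1 else set(DIMENSIONS) - dims
        if consistent:
            mass = sum(att[d] for d in consistent)
            lam = params.r if fb == 1 else params.p
            target = {
                d: (att[d] / mass if d in consistent else 0.0) for d in DIMENSIONS
            }
            att = {d: (1 - lam) * att[d] + lam * target[d] for d in DIMENSIONS}
            tot = sum(att.values())
            att = {d: v / tot for d, v in att.items()}
    return lp


class TestWCSTLoglik:
    def test_uniform_policy_closed_form(self):
        p = ss.WCSTParams(0.4, 0.3, 0.0)
        cards = [Card("red", "star", 3)] * 12
        trials = make_wcst_trials(cards, [1] * 12, [0] * 12)
        assert ss.wcst_loglik(p, trials) == pytest.approx(12 * math.log(0.25))

    def test_exhaustive_enumeration_length3(self):
        """Likelihood equals independent path arithmetic over all 64 deck
        choice paths of a 3-trial sequence, and those paths sum to 1."""
        p = ss.WCSTParams(0.45, 0.65, 1.7)
        cards = [Card("red", "star", 3), Card("blue", "triangle", 2), Card("yellow", "cross", 3)]
        rule = "color"
        total = 0.0
        for choices in itertools.product(range(1, 5), repeat=3):
            feedback = [int(rule in wcst_match(c, k)) for c, k in zip(cards, choices)]
            trials = make_wcst_trials(cards, choices, feedback)
            lp = ss.wcst_loglik(p, trials)
            oracle = wcst_path_logprob(p, cards, choices, feedback)
            assert lp == pytest.approx(oracle, abs=1e-10)
            total += math.exp(lp)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_consistency_raises_likelihood_of_rule_consistent_sorting(self):
        """Before any rule switch, data from a rule-consistent sorter becomes
        more likely as decision consistency grows away from the uniform limit.

        (Only pre-switch data: immediately after a rule change the sorter's
        correct choices contradict the learned attention, so across a whole
        multi-set session higher consistency is penalised, not rewarded.)
        """
        _, trials = _oracle_session()
        first_set = trials[trials.phase_or_set == 1]
        lls = [
            ss.wcst_loglik(ss.WCSTParams(0.5, 0.5, d), first_set)
            for d in (0.0, 0.5, 1.0)
        ]
        assert lls[0] == pytest.approx(len(first_set) * math.log(0.25))
        assert lls[0] < lls[1] < lls[2]

    def test_missing_card_column(self):
        trials = make_wcst_trials([Card("red", "star", 3)], [1], [1]).drop(
            columns="stimulus_or_card"
        )
        with pytest.raises(ss.TrialDataError):
            ss.wcst_loglik(ss.WCSTParams(0.3, 0.3, 1.0), trials)


def _oracle_session():
    """Simulate a session where choices always follow the active rule."""
    from setshift.io import card_to_str
    from setshift.tasks import shuffled_deck, wcst_initial_state, wcst_step

    cfg = WCSTConfig()
    deck = shuffled_deck(cfg)
    state = wcst_initial_state(cfg)
    rows = []
    while not state.finished:
        card = deck[(state.trial_index - 1) % 64]
        rule = state.active_rule(cfg)
        choice = next(k for k in range(1, 5) if rule in wcst_match(card, k))
        t, s_idx = state.trial_index, state.set_index
        fb, state = wcst_step(state, card, choice, cfg)
        rows.append(
            {
                "subject_id": "oracle",
                "group": "oracle",
                "task": "wcst",
                "trial_index": t,
                "phase_or_set": s_idx,
                "rule": rule,
                "stimulus_or_card": card_to_str(card),
                "choice": choice,
                "feedback": fb,
            }
        )
    return cfg, pd.DataFrame(rows)


class TestWCSTSimulate:
    def test_seed_determinism(self):
        p = ss.WCSTParams(0.5, 0.5, 3.0)
        pd.testing.assert_frame_equal(
            ss.wcst_simulate(p, seed=4), ss.wcst_simulate(p, seed=4)
        )

    def test_competent_agent_completes_most_sessions(self):
        p = ss.WCSTParams(0.9, 0.9, 50.0)
        done = sum(
            ss.wcst_simulate(p, seed=s).phase_or_set.max() == 9 and True
            for s in range(10)
        )
        completed = [
            ss.wcst_measures(ss.wcst_simulate(p, seed=s)).sets_completed
            for s in range(10)
        ]
        assert sum(c == 9 for c in completed) >= 7

    def test_random_agent_accuracy_band(self):
        """A consistency-zero agent picks decks uniformly; expected accuracy
        lies in the 0.25-0.5 band implied by the match structure."""
        p = ss.WCSTParams(0.5, 0.5, 0.0)
        accs = [ss.wcst_simulate(p, seed=s).feedback.mean() for s in range(10)]
        assert 0.2 < np.mean(accs) < 0.5


# ---------------------------------------------------------------------------
# Kernels agree with the reference implementation
# ---------------------------------------------------------------------------


class TestKernels:
    def test_prl_kernel_matches_reference(self, prl_session):
        _, trials = prl_session
        packed = pack_trials(trials, "prl")
        for vals in [(0.3, 0.2, 2.0, 0.5), (0.8, 0.6, 0.0, -1.0), (0.05, 0.95, 15.0, 2.0)]:
            params = ss.PRLParams(*vals)
            ll = prl_loglik_batch(
                packed["choices"],
                packed["outcomes"],
                packed["n_trials"],
                np.array([vals]),
            )[0]
            assert ll == pytest.approx(ss.prl_loglik(params, trials), abs=1e-9)

    def test_wcst_kernel_matches_reference(self, wcst_session):
        _, trials = wcst_session
        packed = pack_trials(trials, "wcst")
        for vals in [(0.5, 0.5, 3.0), (0.1, 0.9, 0.0), (0.95, 0.05, 8.0)]:
            params = ss.WCSTParams(*vals)
            ll = wcst_loglik_batch(
                packed["match_bits"],
                packed["choices"],
                packed["feedback"],
                packed["n_trials"],
                np.array([vals]),
            )[0]
            assert ll == pytest.approx(ss.wcst_loglik(params, trials), abs=1e-9)
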