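"""Task structure: cards, feedback logic, switch schedule, session runner."""

import numpy as np
import pytest

from cwcst.task import (
    COLOR,
    KEY_CARDS,
    NUMBER,
    OTHER,
    SHAPE,
    VALID_STIMULI,
    ParticipantLog,
    StimulusCard,
    TaskConfig,
    evaluate_response,
    generate_stimulus,
    next_category_schedule,
    run_session,
)
from cwcst.simulate import AgentParams

from .conftest import make_log


class TestCards:
    def test_key_cards_are_pairwise_distinct_on_every_dimension(self):
        numbers = {c[0] for c in KEY_CARDS.values()}
        colors = {c[1] for c in KEY_CARDS.values()}
        shapes = {c[2] for c in KEY_CARDS.values()}
        assert numbers == colors == shapes == {1, 2, 3, 4}

    def test_valid_stimuli_match_bruteforce_enumeration(self):
        # brute force over all 4^3 attribute combinations: a card is valid
        # iff its three matched key positions are pairwise distinct
        brute = {
            (n, c, s)
            for n in range(1, 5)
            for c in range(1, 5)
            for s in range(1, 5)
            if len({n, c, s}) == 3
        }
        assert {(c.number, c.color, c.shape) for c in VALID_STIMULI} == brute
        assert len(VALID_STIMULI) == 24

    def test_ambiguous_card_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            StimulusCard(number=2, color=2, shape=3)

    def test_every_card_leaves_exactly_one_unmatched_key(self):
        for card in VALID_STIMULI:
            unmatched = {1, 2, 3, 4} - {card.number, card.color, card.shape}
            assert len(unmatched) == 1
            (key,) = unmatched
            applied, _ = evaluate_response(card, key, COLOR)
            assert applied == OTHER

    def test_generate_stimulus_draws_valid_and_non_repeating(self):
        rng = np.random.default_rng(7)
        prev = None
        seen = set()
        for _ in range(10_000):
            card = generate_stimulus(rng, prev)
            assert len({card.number, card.color, card.shape}) == 3
            if prev is not None:
                assert (card.number, card.color, card.shape) != (
                    prev.number,
                    prev.color,
                    prev.shape,
                )
            seen.add((card.number, card.color, card.shape))
            prev = card
        assert len(seen) == 24  # the full valid-card space is reachable


class TestEvaluateResponse:
    # the green-cross card: matches key 1 on number, key 2 on color, key 3 on shape
    card = StimulusCard(1, 2, 3)

    @pytest.mark.parametrize(
        "response, prevailing, want_applied, want_feedback",
        [
            (3, SHAPE, SHAPE, True),  # shape sort under the shape rule
            (3, COLOR, SHAPE, False),  # shape sort under the color rule
            (4, COLOR, OTHER, False),  # the no-match key is never correct
            (4, SHAPE, OTHER, False),
            (4, NUMBER, OTHER, False),
            (1, NUMBER, NUMBER, True),
            (2, COLOR, COLOR, True),
        ],
    )
    def test_mapping_and_feedback(self, response, prevailing, want_applied, want_feedback):
        applied, feedback = evaluate_response(self.card, response, prevailing)
        assert applied == want_applied
        assert feedback is want_feedback

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            evaluate_response(self.card, 5, COLOR)
        with pytest.raises(ValueError):
            evaluate_response(self.card, 1, OTHER)


class TestSchedule:
    def test_degenerate_support_gives_constant_run_lengths(self):
        config = TaskConfig(run_length_support=(2,))
        lengths, _ = next_category_schedule(np.random.default_rng(0), config, 50)
        assert (lengths == 2).all()

    def test_successor_category_never_repeats(self):
        config = TaskConfig()
        _, cats = next_category_schedule(np.random.default_rng(1), config, 1000)
        assert (cats[1:] != cats[:-1]).all()
        assert set(np.unique(cats)) <= {0, 1, 2}

    def test_lengths_drawn_from_support(self):
        config = TaskConfig(run_length_support=(2, 2, 2, 3))
        lengths, _ = next_category_schedule(np.random.default_rng(2), config, 2000)
        assert set(np.unique(lengths)) == {2, 3}
        # P(2) = 3/4 by weighting
        assert abs((lengths == 2).mean() - 0.75) < 0.05

    def test_run_length_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            TaskConfig(run_length_support=(1, 2))


class TestRunSession:
    def test_error_free_agent_completes_all_switches(self):
        config = TaskConfig()
        rng = np.random.default_rng(3)
        log = run_session(AgentParams.error_free(), config, rng)
        log.validate()
        assert len(log) <= config.max_total_trials
        # replay the hidden schedule with an identically seeded generator
        rng2 = np.random.default_rng(3)
        next_category_schedule(rng2, config, config.n_practice_switches)
        e_lengths, _ = next_category_schedule(rng2, config, config.n_experimental_switches)
        exp = log.experimental
        n_correct = int(exp.feedback.sum())
        n_switch_trials = int((~exp.feedback[:-1]).sum())
        # every positive sort fills a scheduled run; every negative announces
        # or follows a covert switch, and its successor is a switch trial
        assert n_correct == int(e_lengths.sum())
        assert len(exp) == n_correct + n_switch_trials + (0 if exp.feedback[-1] else 1)

    def test_always_perseverating_agent_hits_trial_cap(self):
        agent = AgentParams(p_persev=1.0, participant_id="stuck")
        log = run_session(agent, TaskConfig(), np.random.default_rng(4))
        assert len(log) == TaskConfig().max_total_trials

    def test_fixed_seed_reproduces_byte_identical_log(self):
        agent = AgentParams(p_persev=0.2, p_setloss=0.1, p_inferr=0.2, p_other=0.05)
        a = run_session(agent, TaskConfig(), np.random.default_rng(5))
        b = run_session(agent, TaskConfig(), np.random.default_rng(5))
        for name in ParticipantLog.__slots__[1:]:
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_feedback_consistency_on_generated_logs(self):
        rng = np.random.default_rng(6)
        for i in range(10):
            agent = AgentParams(
                p_persev=float(rng.uniform(0, 0.8)),
                p_setloss=float(rng.uniform(0, 0.4)),
                p_inferr=float(rng.uniform(0, 0.8)),
                p_other=float(rng.uniform(0, 0.4)),
            )
            log = run_session(agent, TaskConfig(), rng)
            log.validate()
            assert int(log.feedback.sum()) == int((log.applied == log.prevailing).sum())
            assert log.experimental.trial_index[0] == 1

    def test_practice_block_flagged_and_precedes_experimental(self):
        log = run_session(AgentParams.error_free(), TaskConfig(), np.random.default_rng(8))
        assert log.is_practice[0]
        assert not log.is_practice[-1]
        switch_points = np.flatnonzero(np.diff(log.is_practice.astype(int)))
        assert len(switch_points) == 1


class TestLogValidation:
    def test_inconsistent_feedback_rejected(self):
        log = make_log("x", [("shape", "shape"), ("color", "shape")])
        log.feedback[1] = True  # claims positive for a wrong sort
        with pytest.raises(ValueError, match="feedback"):
            log.validate()

    def test_from_records_roundtrip(self):
        log = make_log("x", [("shape", "color"), ("number", "color")])
        records = list(log.records())
        again = ParticipantLog.from_records(records)
        assert np.array_equal(again.applied, log.applied)
        assert np.array_equal(again.rt_ms, log.rt_ms)
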