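"""Markov chain estimation, sequence probabilities and the relative mean."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rmpmic import (MarkovProfiler, PositionalMarkovChain, SequenceRecord,
                    entropy_score, fit_markov, generate_group_x,
                    profile_sequences, relative_mean_probability,
                    sequence_probability)
from rmpmic.markov import (EmptyTrainingError, HeterogeneousLengthError,
                           LengthMismatchError, OrderError)

from _oracles import naive_chain_probability

FOUR_SEQS = ["UAAUC", "UACCG", "CGAUC", "CGCCG"]


class TestFit:
    def test_hand_tallied_counts(self):
        m = fit_markov(FOUR_SEQS, order=1)
        assert m.initial == {"U": 0.5, "C": 0.5}
        assert m.conditional(2, "U", "A") == 1.0
        assert m.conditional(2, "C", "G") == 1.0
        # position 3 after A: {A: 1 of 2, C: 1 of 2}
        assert m.conditional(3, "A", "A") == 0.5
        assert m.conditional(3, "A", "C") == 0.5

    def test_degenerate_training_set_gives_unit_transitions(self):
        m = fit_markov(["UAAUC"] * 5, order=1)
        assert m.initial == {"U": 1.0}
        for j, (ctx, base) in enumerate(zip("UAAU", "AAUC"), start=2):
            assert m.conditional(j, ctx, base) == 1.0
        assert m.sequence_probability("UAAUC") == 1.0

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_distributions_normalize(self, order):
        seqs = [r.seq for r in generate_group_x(200, seed=3, length=8)]
        m = fit_markov(seqs, order=order)
        assert abs(sum(m.initial.values()) - 1.0) < 1e-12
        for pos, table in m.transitions.items():
            for ctx, cell in table.items():
                assert abs(sum(cell.values()) - 1.0) < 1e-12
                assert all(0.0 <= p <= 1.0 for p in cell.values())

    def test_distinct_errors(self):
        with pytest.raises(EmptyTrainingError):
            fit_markov([], order=1)
        with pytest.raises(HeterogeneousLengthError):
            fit_markov(["AAAA", "AAAAA"], order=1)
        with pytest.raises(OrderError):
            fit_markov(FOUR_SEQS, order=4)

    def test_parameter_recovery_improves_with_n(self):
        errs = []
        for n in (1_000, 100_000):
            seqs = [r.seq for r in generate_group_x(n, seed=11)]
            m = fit_markov(seqs, order=1)
            errs.append(max(abs(m.conditional(2, "U", "A") - 0.75),
                            abs(m.conditional(2, "U", "U") - 0.25),
                            abs(m.conditional(2, "C", "G") - 1.0),
                            abs(m.initial["U"] - 0.75)))
        assert errs[1] < errs[0]
        assert errs[1] < 0.01

    def test_pseudocount_removes_zeros(self):
        m0 = fit_markov(FOUR_SEQS, order=1)
        m1 = fit_markov(FOUR_SEQS, order=1, pseudocount=0.5)
        assert m0.sequence_probability("GGGGG") == 0.0
        assert m1.sequence_probability("GGGGG") > 0.0
        # every valid 5-mer is scorable under smoothing
        assert m1.sequence_probability("AAAAA") > 0.0

    def test_homogeneous_pools_positions(self):
        m = fit_markov(["AUAUA", "AUAUA"], order=1, position_specific=False)
        # pooled table: U->A twice, A->U twice, shared across positions
        assert m.conditional(2, "A", "U") == 1.0
        assert m.conditional(5, "A", "U") == 1.0


class TestSequenceProbability:
    def test_worked_example_values(self, xmodel):
        assert xmodel.sequence_probability("UAAUC") == pytest.approx(
            0.0087890625, abs=0)
        assert xmodel.sequence_probability("AACGA") == 0.0

    def test_uniform_model_closed_form(self):
        uniform = {b: 0.25 for b in "ACGU"}
        m = PositionalMarkovChain(
            order=1, length=5, initial=dict(uniform),
            transitions={j: {b: dict(uniform) for b in "ACGU"}
                         for j in range(2, 6)})
        assert m.sequence_probability("GAUCC") == pytest.approx(0.25 ** 5, abs=0)

    def test_length_mismatch_raises(self, xmodel):
        with pytest.raises(LengthMismatchError):
            xmodel.sequence_probability("UAAUCA")

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_matches_naive_product_oracle(self, order):
        seqs = [r.seq for r in generate_group_x(80, seed=5, length=9)]
        m = fit_markov(seqs, order=order)
        queries = [r.seq for r in generate_group_x(30, seed=6, length=9)]
        for s in queries:
            expected = naive_chain_probability(s, m.initial, m.transitions,
                                               order)
            assert sequence_probability(m, s) == pytest.approx(expected, rel=1e-12)


class TestRelativeMean:
    @pytest.mark.parametrize("qs,expected", [
        ((0.0, 0.0, 0.0), 0.0),
        ((0.4, 0.4, 0.4), 0.4),
        ((0.3, 0.0, 0.1), 0.2),
        ((0.0, 0.0, 0.5), 0.5),
    ])
    def test_examples(self, qs, expected):
        assert relative_mean_probability(*qs) == pytest.approx(expected,
                                                               rel=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            relative_mean_probability(1.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            relative_mean_probability(-0.1, 0.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.one_of(st.just(0.0),
                                 st.floats(1e-12, 1.0)) for _ in range(3)]))
    def test_bracketing_invariant(self, qs):
        q4 = relative_mean_probability(*qs)
        positive = [q for q in qs if q > 0.0]
        if positive:
            eps = 1e-12  # summation round-off
            assert min(positive) - eps <= q4 <= max(positive) + eps
        else:
            assert q4 == 0.0


class TestProfiles:
    def test_batch_matches_single(self):
        train = [r.seq for r in generate_group_x(60, seed=9, length=7)]
        models = {h: fit_markov(train, h) for h in (1, 2, 3)}
        queries = train[:10]
        batch = profile_sequences(models, queries)
        for s, p in zip(queries, batch):
            q1, q2, q3 = (models[h].sequence_probability(s) for h in (1, 2, 3))
            assert p.as_tuple() == (q1, q2, q3,
                                    relative_mean_probability(q1, q2, q3))

    def test_empty_input_gives_empty_output(self):
        models = {h: fit_markov(FOUR_SEQS, h) for h in (1, 2, 3)}
        assert profile_sequences(models, []) == []

    def test_missing_order_raises(self):
        models = {1: fit_markov(FOUR_SEQS, 1)}
        with pytest.raises(OrderError):
            profile_sequences(models, FOUR_SEQS)


class TestEntropy:
    def test_values_and_monotonicity(self):
        assert entropy_score(1.0) == 0.0
        assert entropy_score(0.0087890625) == pytest.approx(
            abs(math.log(0.0087890625)), rel=1e-12)
        assert entropy_score(0.0087890625) == pytest.approx(4.7342472, abs=5e-6)
        assert entropy_score(0.1) > entropy_score(0.2)

    def test_zero_is_a_domain_error(self):
        with pytest.raises(ValueError):
            entropy_score(0.0)


class TestSerialization:
    @pytest.mark.parametrize("pseudocount", [0.0, 0.25])
    def test_json_round_trip_is_exact(self, pseudocount):
        m = fit_markov(FOUR_SEQS, order=2, pseudocount=pseudocount)
        m2 = PositionalMarkovChain.from_json(m.to_json())
        assert m2.initial == m.initial
        assert m2.transitions == m.transitions
        assert (m2.order, m2.length, m2.pseudocount, m2.n_train) == \
               (m.order, m.length, m.pseudocount, m.n_train)
        for s in FOUR_SEQS + ["GGGGG"]:
            assert m2.sequence_probability(s) == m.sequence_probability(s)


class TestMarkovProfiler:
    def test_sklearn_contract(self):
        from sklearn.base import clone
        prof = MarkovProfiler(pseudocount=0.1)
        assert clone(prof).get_params()["pseudocount"] == 0.1
        X = [r.seq for r in generate_group_x(40, seed=2, length=6)]
        out = prof.fit(X).transform(X[:5])
        assert out.shape == (5, 4)
        assert np.all((out >= 0) & (out <= 1))
        assert list(prof.get_feature_names_out()) == ["q1", "q2", "q3", "q4"]

    def test_unfitted_transform_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            MarkovProfiler().transform(["AAAA"])

    def test_accepts_records(self):
        recs = [SequenceRecord(f"s{i}", s) for i, s in enumerate(FOUR_SEQS)]
        out = MarkovProfiler().fit(recs).transform(recs)
        assert out.shape == (4, 4)
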