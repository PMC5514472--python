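import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemhmm.hmm_engine import (
    HmmModel,
    build_emission_matrix,
    build_model,
    build_start_probs,
    build_states,
    build_transition_matrix,
    encode_observations,
    repeat_count_from_path,
    viterbi,
    StatePath,
)
from tandemhmm.repeat_spec import ErrorProfile, RepeatSpec


def brute_force_viterbi(obs: str, model: HmmModel) -> float:
    """Independent oracle: exhaustive max over all N^L state paths."""
    codes = encode_observations(obs)
    ls, lt, le = model.log_matrices()
    best = -np.inf
    n = model.n_states
    for path in itertools.product(range(n), repeat=len(codes)):
        lp = ls[path[0]] + le[path[0], codes[0]]
        for t in range(1, len(codes)):
            lp += lt[path[t - 1], path[t]] + le[path[t], codes[t]]
        best = max(best, lp)
    return best


class TestStates:
    @pytest.mark.parametrize("e,n", [(3, 10), (1, 4), (5, 16)])
    def test_state_count(self, e, n):
        assert len(build_states(e)) == n

    def test_cag_order_matches_canonical_layout(self):
        assert build_states(3) == [
            "NonRepeat", "r1", "r2", "r3", "Ir1", "Ir2", "Ir3", "Dr1", "Dr2", "Dr3",
        ]

    def test_invalid_unit_length(self):
        with pytest.raises(ValueError):
            build_states(0)


class TestEmissionMatrix:
    def test_cag_constants(self, cag_spec):
        emit = build_emission_matrix(cag_spec, 0.02)
        # match states: expected base 0.985, each unexpected base 0.005
        assert emit[1, 1] == pytest.approx(0.985)  # r1 emits C
        assert emit[1, 0] == pytest.approx(0.005)
        assert emit[2, 0] == pytest.approx(0.985)  # r2 emits A
        assert emit[3, 2] == pytest.approx(0.985)  # r3 emits G
        # insertion rows uniform over the four nucleotides, never N
        assert np.allclose(emit[4:7, :4], 0.25) and np.allclose(emit[4:7, 4], 0.0)
        # NonRepeat spreads over all five symbols
        assert np.allclose(emit[0], 0.2)
        # deletion state Dr_k emits the following unit base (DrE wraps)
        assert emit[7, 0] == pytest.approx(0.985)  # Dr1 emits A
        assert emit[9, 1] == pytest.approx(0.985)  # Dr3 emits C (wrap)

    def test_noise_free_limit(self, cag_spec):
        emit = build_emission_matrix(cag_spec, 0.0)
        assert emit[1, 1] == 1.0
        assert emit[1, 0] == 0.0

    def test_mixed_pattern_blending(self):
        spec = RepeatSpec(
            "ATXN10", "chr22", 1, 50, "ATTCT", mixed_weights={3: {"C": 0.4, "T": 0.6}}
        )
        emit = build_emission_matrix(spec, 0.02)
        r3 = emit[3]  # third match state
        assert r3[1] == pytest.approx(0.98 * 0.4 + 0.005)  # C
        assert r3[3] == pytest.approx(0.98 * 0.6 + 0.005)  # T
        assert r3[0] == pytest.approx(0.005)

    @settings(derandomize=True, max_examples=40)
    @given(
        pattern=st.text(alphabet="ACGT", min_size=1, max_size=6),
        sub=st.floats(min_value=0.0, max_value=0.5),
        ins=st.floats(min_value=0.0, max_value=0.4),
        dele=st.floats(min_value=0.0, max_value=0.3),
    )
    def test_rows_stochastic_for_any_profile(self, pattern, sub, ins, dele):
        spec = RepeatSpec("G", "c", 1, len(pattern), pattern)
        profile = ErrorProfile(ins_rate=ins, del_rate=dele, sub_rate=sub)
        emit = build_emission_matrix(spec, sub)
        trans = build_transition_matrix(spec.unit_length, profile)
        start = build_start_probs(spec.unit_length, profile)
        assert np.allclose(emit.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(trans.sum(axis=1), 1.0, atol=1e-9)
        assert start.sum() == pytest.approx(1.0, abs=1e-9)
        assert (emit >= 0).all() and (trans >= 0).all() and (start >= 0).all()


class TestTransitionMatrix:
    def test_default_pacbio_rates(self, default_profile):
        t = build_transition_matrix(3, default_profile)
        assert t[1, 4] == pytest.approx(0.11)  # r1 -> Ir1
        assert t[1, 8] == pytest.approx(0.02)  # r1 -> Dr2
        assert t[1, 2] == pytest.approx(0.87, abs=1e-6)  # r1 -> r2 absorbs
        assert t[0, 0] == pytest.approx(0.96, abs=1e-6)
        assert t[0, 1] == pytest.approx(0.02, abs=1e-6)  # NonRepeat -> r1
        assert t[0, 7] == pytest.approx(0.02, abs=1e-6)  # NonRepeat -> Dr1
        # exits to NonRepeat from r3 / Ir3 / Dr2 / Dr3
        for state in (3, 6, 8, 9):
            assert t[state, 0] == pytest.approx(0.02)
        assert t[2, 0] < 1e-6  # r2 cannot exit

    def test_noise_free_limit_is_deterministic_chain(self):
        profile = ErrorProfile(
            ins_rate=0.0, del_rate=0.0, sub_rate=0.0, region_io=0.0, nonrepeat_self=1.0
        )
        t = build_transition_matrix(3, profile)
        assert t[0, 0] == pytest.approx(1.0)
        assert t[1, 2] == pytest.approx(1.0, abs=1e-6)  # r1 -> r2 certain
        assert t[3, 1] == pytest.approx(1.0, abs=1e-6)  # r3 -> r1 certain

    def test_insertion_probability_monotone_in_rate(self):
        lo = build_transition_matrix(3, ErrorProfile(ins_rate=0.05))
        hi = build_transition_matrix(3, ErrorProfile(ins_rate=0.25))
        assert hi[1, 4] > lo[1, 4]
        assert hi[4, 4] > lo[4, 4]

    def test_infeasible_profile_raises(self):
        # rates whose sum leaves no mass for the expected transition are
        # rejected at profile construction (SpecError is a ValueError)
        with pytest.raises(ValueError):
            ErrorProfile(ins_rate=0.8, del_rate=0.15, region_io=0.1)


class TestStartProbs:
    def test_mass_on_nonrepeat(self, default_profile):
        p = build_start_probs(3, default_profile)
        assert p[0] == pytest.approx(0.96, abs=1e-6)
        assert p[1] == pytest.approx(0.02)
        assert p[7] == pytest.approx(0.02)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_profile(self):
        p = build_start_probs(2, ErrorProfile(ins_rate=0, del_rate=0, sub_rate=0,
                                              region_io=0, nonrepeat_self=1.0))
        assert p[0] == pytest.approx(1.0)


class TestViterbi:
    def test_clean_repeats_between_separators(self, cag_model):
        path = viterbi("NNN" + "CAG" * 3 + "NNN", cag_model)
        assert list(path.states) == [0, 0, 0, 1, 2, 3, 1, 2, 3, 1, 2, 3, 0, 0, 0]
        assert repeat_count_from_path(path, 3) == 3

    def test_single_insertion_decoded_as_insertion_state(self, cag_model):
        path = viterbi("CAGCCAGCAG", cag_model)
        ins = [s for s in path.states if 4 <= s <= 6]
        assert len(ins) == 1
        assert repeat_count_from_path(path, 3) == 3

    def test_matches_exhaustive_enumeration_small(self, cag_model, rng):
        # CAG model (10 states) at L<=4; full enumeration is feasible there
        for _ in range(5):
            length = int(rng.integers(2, 5))
            obs = "".join(rng.choice(list("ACGTN"), size=length))
            got = viterbi(obs, cag_model).log_likelihood
            want = brute_force_viterbi(obs, cag_model)
            assert got == pytest.approx(want, abs=1e-9)

    def test_matches_exhaustive_enumeration_single_base_unit(self, rng):
        spec = RepeatSpec("G", "c", 1, 10, "A")
        model = build_model(spec, ErrorProfile())
        for _ in range(8):
            length = int(rng.integers(3, 8))
            obs = "".join(rng.choice(list("ACGTN"), size=length))
            got = viterbi(obs, model).log_likelihood
            want = brute_force_viterbi(obs, model)
            assert got == pytest.approx(want, abs=1e-9)

    # counts start at 2: entering the repeat states costs two region
    # crossings (~0.02 each), which a single unit cannot amortise — and the
    # histogram filter discards counts below 5 anyway
    @pytest.mark.parametrize("count", [2, 4, 25])
    def test_noise_free_parameter_recovery(self, cag_spec, errorfree_profile, count):
        model = build_model(cag_spec, errorfree_profile)
        path = viterbi("NNN" + "CAG" * count + "NNN", model)
        assert repeat_count_from_path(path, 3) == count

    def test_rejects_bad_symbols_and_empty(self, cag_model):
        with pytest.raises(ValueError):
            viterbi("CAGU", cag_model)
        with pytest.raises(ValueError):
            viterbi("", cag_model)


class TestRepeatCountRule:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ([1, 2, 3] * 3, 3),                    # nine match positions
            ([1, 2, 3, 1, 2, 3, 1] + [7], 3),      # 7 matches + 1 deletion = 9
            ([1, 2, 3] * 3 + [4, 5], 3),           # insertions contribute nothing
        ],
    )
    def test_reconstruction(self, states, expected):
        path = StatePath(states=np.array(states), log_likelihood=0.0)
        assert repeat_count_from_path(path, 3) == expected

    def test_half_up_rounding(self):
        # 7 matches + 1 deletion and 1 insertion: length 9 -> 3; bare 7 -> 2.33 -> 2
        path = StatePath(states=np.array([1, 2, 3, 1, 2, 3, 1]), log_likelihood=0.0)
        assert repeat_count_from_path(path, 3) == 2
        path = StatePath(states=np.array([1, 2, 3, 1, 2, 3, 1, 2]), log_likelihood=0.0)
        assert repeat_count_from_path(path, 3) == 3  # 8/3 = 2.67 -> 3


class TestSerialization:
    def test_json_round_trip(self, cag_model, tmp_path):
        path = tmp_path / "model.json"
        cag_model.to_json(path)
        loaded = HmmModel.from_json(path)
        assert loaded.states == cag_model.states
        assert np.allclose(loaded.emission, cag_model.emission)
        assert np.allclose(loaded.transition, cag_model.transition)
        assert np.allclose(loaded.start, cag_model.start)
        assert loaded.profile == cag_model.profile
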