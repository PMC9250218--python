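import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm as scipy_expm

from stageflow.ingest import FindingVocabulary
from stageflow.model import (
    AnchorSet,
    ConnectivityMask,
    ProgressionModel,
    count_free_parameters,
    count_parameters,
    default_anchor_set,
    make_connectivity_mask,
    noisy_or_prob,
    noisy_or_probs,
    observation_log_likelihood,
    onset_prob,
    stage_transition_matrix,
    validate_model,
)
from stageflow.simulate import make_fixture_model


class TestCountParameters:
    @pytest.mark.parametrize("K,W,N,C,expected", [
        (5, 10, 1000, 0, 10125),   # the headline three-layer count
        (5, 12, 88, 0, 1201),      # the diabetes study dimensions
        (2, 3, 5, 4, 23),          # toy pruning: 4 anchored codes drop 8
    ])
    def test_counts(self, K, W, N, C, expected):
        assert count_parameters(K, W, N, C) == expected

    def test_anchoring_removes_w_minus_1_per_code(self):
        for C in range(6):
            assert (count_parameters(4, 3, 5, C)
                    == count_parameters(4, 3, 5, 0) - C * 2)

    def test_free_count_drops_constrained_q_entries(self):
        # forward-only Q has K(K-1)/2 free entries instead of K^2
        assert count_free_parameters(5, 10, 1000) == 10125 - 25 + 10

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            count_parameters(-1, 2, 3)
        with pytest.raises(ValueError):
            count_parameters(2, 2, 3, anchored_codes=4)


class TestConnectivityMask:
    def test_pruning_toy(self):
        """Three complications, five findings, four anchored codes -> 7 links."""
        vocab = FindingVocabulary(["F1", "F2", "F3", "F4", "F5"])
        anchors = AnchorSet({0: ["F2"], 1: ["F1", "F5"], 2: ["F3"]})
        mask = make_connectivity_mask(anchors, vocab, W=3)
        assert list(mask.allowed.sum(axis=0)) == [1, 1, 1, 3, 1]
        assert mask.n_links == 7
        # the unanchored finding stays fully connected
        assert mask.allowed[:, 3].all()
        # each anchored column keeps exactly its anchor parent
        assert mask.allowed[1, 0] and mask.allowed[0, 1] and mask.allowed[2, 2]

    def test_no_anchors_fully_connected(self):
        vocab = FindingVocabulary(["a", "b"])
        mask = make_connectivity_mask(AnchorSet({}), vocab, W=4)
        assert mask.allowed.all() and mask.n_links == 8

    def test_every_finding_anchored_gives_n_links(self):
        vocab = FindingVocabulary(["a", "b", "c"])
        anchors = AnchorSet({0: ["a"], 1: ["b", "c"]})
        mask = make_connectivity_mask(anchors, vocab, W=2)
        assert mask.n_links == 3

    def test_out_of_range_complication_is_error(self):
        vocab = FindingVocabulary(["a"])
        with pytest.raises(ValueError, match="W="):
            make_connectivity_mask(AnchorSet({5: ["a"]}), vocab, W=2)

    def test_unbound_code_ignored(self):
        vocab = FindingVocabulary(["a"])
        mask = make_connectivity_mask(AnchorSet({0: ["zzz"]}), vocab, W=2)
        assert mask.allowed.all()

    def test_duplicate_anchor_code_rejected(self):
        with pytest.raises(ValueError, match="anchored to both"):
            AnchorSet({0: ["a"], 1: ["a"]})


class TestDefaultAnchors:
    def test_twelve_categories_and_code_count(self):
        anchors = default_anchor_set()
        assert anchors.n_complications_anchored == 12
        assert anchors.n_codes == 28
        assert anchors.names[0] == "Diabetes"
        assert "E11.9" in anchors.anchors[0]
        assert "E11.2" in anchors.anchors[3]  # renal codes under nephropathy

    def test_yaml_round_trip(self, tmp_path):
        anchors = default_anchor_set()
        path = tmp_path / "anchors.yaml"
        anchors.to_yaml(path)
        back = AnchorSet.from_yaml(path)
        assert back.anchors == anchors.anchors
        assert back.names == anchors.names


class TestNoisyOr:
    def test_no_active_parent_gives_leak(self, fixture_model):
        p = noisy_or_probs(np.zeros(2, dtype=bool), fixture_model)
        assert np.allclose(p, fixture_model.leak)

    def test_single_parent_closed_form(self, fixture_model):
        m = fixture_model.copy()
        m.leak[:] = 0.1
        m.A[0, 2] = 0.5
        p = noisy_or_prob(np.array([True, False]), 2, m)
        assert p == pytest.approx(1 - 0.9 * 0.5)

    def test_certain_activation(self, fixture_model):
        m = fixture_model.copy()
        m.A[0, 2] = 1.0
        assert noisy_or_prob(np.array([True, False]), 2, m) == 1.0

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_active_set_and_weights(self, data):
        """Adding parents or raising any A[w, n] never lowers p_n."""
        m = make_fixture_model(seed=data.draw(st.integers(0, 10**6)))
        act = np.array([data.draw(st.booleans()), data.draw(st.booleans())])
        bigger = act.copy()
        bigger[data.draw(st.integers(0, 1))] = True
        p_small = noisy_or_probs(act, m)
        p_big = noisy_or_probs(bigger, m)
        assert np.all(p_big >= p_small - 1e-12)
        m2 = m.copy()
        w, n = data.draw(st.integers(0, 1)), data.draw(st.integers(0, 5))
        if m2.mask.allowed[w, n]:
            m2.A[w, n] = min(1.0, m2.A[w, n] + 0.1)
        assert np.all(noisy_or_probs(bigger, m2) >= p_big - 1e-12)


class TestObservationLogLikelihood:
    def test_vacuous_observation(self, fixture_model):
        m = fixture_model.copy()
        m.leak[:] = 0.0
        m.A[:, 2:] = 0.0
        ll = observation_log_likelihood(frozenset(), np.zeros(2, bool), m)
        assert ll == pytest.approx(0.0)

    def test_impossible_positive_is_minus_inf(self, fixture_model):
        m = fixture_model.copy()
        m.leak[:] = 0.0
        ll = observation_log_likelihood(frozenset({2}), np.zeros(2, bool), m)
        assert ll == -np.inf

    def test_matches_direct_product(self, fixture_model):
        active = np.array([True, False])
        p = noisy_or_probs(active, fixture_model)
        findings = frozenset({0, 3})
        expected = sum(math.log(p[n]) if n in findings else math.log(1 - p[n])
                       for n in range(6))
        got = observation_log_likelihood(findings, active, fixture_model)
        assert got == pytest.approx(expected)


class TestStageTransitionMatrix:
    def test_zero_generator_is_identity(self):
        assert np.allclose(stage_transition_matrix(np.zeros((3, 3)), 2.0),
                           np.eye(3))

    def test_two_state_closed_form(self):
        Q = np.array([[-math.log(2), math.log(2)], [0.0, 0.0]])
        P = stage_transition_matrix(Q, 1.0)
        assert P[0, 1] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("seed,dt", [(0, 0.5), (1, 1.0), (2, 3.0), (3, 17.0)])
    def test_matches_dense_expm(self, seed, dt):
        m = make_fixture_model(K=4, W=2, N=6, seed=seed)
        P = stage_transition_matrix(m.Q, dt)
        assert np.allclose(P, scipy_expm(m.Q * dt), atol=1e-9)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(np.tril(P, -1) == 0.0)

    @given(seed=st.integers(0, 10**6), dt1=st.floats(0.1, 5.0), dt2=st.floats(0.1, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_chapman_kolmogorov(self, seed, dt1, dt2):
        m = make_fixture_model(K=4, W=2, N=6, seed=seed)
        lhs = stage_transition_matrix(m.Q, dt1 + dt2)
        rhs = stage_transition_matrix(m.Q, dt1) @ stage_transition_matrix(m.Q, dt2)
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_nonpositive_dt_is_error(self):
        with pytest.raises(ValueError):
            stage_transition_matrix(np.zeros((2, 2)), 0.0)


class TestOnsetProb:
    def test_closed_forms(self, fixture_model):
        m = fixture_model.copy()
        m.h_onset[1, 0] = 0.0
        assert onset_prob(0, 1, 5.0, m) == 0.0
        m.h_onset[1, 0] = 1.0
        assert onset_prob(0, 1, 1.0, m) == 1.0
        m.h_onset[1, 0] = 0.19
        assert onset_prob(0, 1, 2.0, m) == pytest.approx(1 - 0.81**2)


class TestValidateModel:
    def test_valid_fixture(self, fixture_model):
        assert validate_model(fixture_model) == []

    def test_negative_intensity_flagged(self, fixture_model):
        m = fixture_model.copy()
        m.Q[0, 1] = -0.2
        m.Q[0, 0] = 0.2
        assert any("Q" in v for v in validate_model(m))

    def test_backward_transition_flagged(self, fixture_model):
        m = fixture_model.copy()
        m.Q[-1, :] = 0.0
        m.Q[1, 0] = 0.1
        m.Q[1, 1] -= 0.1
        assert any("forward" in v for v in validate_model(m))

    def test_masked_link_with_weight_flagged(self, fixture_model):
        m = fixture_model.copy()
        m.A[1, 0] = 0.3  # column 0 is anchored to complication 0
        assert any("A[1,0]" in v for v in validate_model(m))


class TestSerialization:
    def test_json_round_trip_is_exact(self, tmp_path, fixture_model):
        path = tmp_path / "model.json"
        fixture_model.save(path)
        back = ProgressionModel.load(path)
        for name in ("Q", "pi_onset", "h_onset", "A", "leak"):
            assert np.array_equal(getattr(back, name), getattr(fixture_model, name))
        assert np.array_equal(back.mask.allowed, fixture_model.mask.allowed)
        assert back.codes == fixture_model.codes
        assert back.anchor_set.anchors == fixture_model.anchor_set.anchors
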