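import numpy as np
import pytest

from stageflow.ingest import FindingVocabulary
from stageflow.learning import (
    FitConfig,
    SufficientStats,
    ZeroProbabilityEvidenceError,
    activity_matrix,
    fit,
    init_model,
    m_step,
    sample_attributions,
    sample_complications,
    sample_stages,
)
from stageflow.model import AnchorSet, default_anchor_set
from stageflow.simulate import make_fixture_model

from .conftest import make_history


@pytest.fixture(scope="module")
def diabetes_vocab():
    """An 88-code vocabulary containing all 28 anchored codes."""
    anchored = sorted(default_anchor_set().complication_of())
    filler = [f"X{i:02d}" for i in range(88 - len(anchored))]
    return FindingVocabulary(sorted(anchored + filler))


class TestInitModel:
    def test_same_seed_identical(self, diabetes_vocab):
        anchors = default_anchor_set()
        m1 = init_model(5, 12, diabetes_vocab, anchors, seed=3)
        m2 = init_model(5, 12, diabetes_vocab, anchors, seed=3)
        for name in ("Q", "pi_onset", "h_onset", "A", "leak"):
            assert np.array_equal(getattr(m1, name), getattr(m2, name))
        assert m1.validate() == []

    def test_study_mask_column_counts(self, diabetes_vocab):
        """Anchored codes keep one parent; the rest stay fully connected."""
        m = init_model(5, 12, diabetes_vocab, default_anchor_set(), seed=0)
        col = m.mask.allowed.sum(axis=0)
        anchored = set(default_anchor_set().complication_of())
        for n, code in enumerate(diabetes_vocab.codes):
            assert col[n] == (1 if code in anchored else 12)
        assert (col == 1).sum() == 28

    def test_single_complication_no_anchors(self):
        vocab = FindingVocabulary(["a", "b", "c"])
        m = init_model(3, 1, vocab, AnchorSet({}), seed=0)
        assert m.mask.allowed.all() and m.mask.shape == (1, 3)


class TestSampleStages:
    def test_deterministic_emission_forces_stage(self, fixture_model, rng):
        """An onset only possible in stage 3 pins the final stage there."""
        m = fixture_model.copy()
        m.h_onset[:, 0] = [0.0, 0.0, 0.9]
        m.pi_onset[:, 0] = 0.0
        h = make_history("p", [(0, set()), (1, set())])
        tau = np.array([1, 2])  # complication 0 activates at slice 1
        for _ in range(25):
            stages = sample_stages(h, tau, m, rng)
            assert stages[1] == 2

    def test_sequences_nondecreasing(self, fixture_model, rng):
        h = make_history("p", [(0, set()), (1, set()), (3, set()), (6, set())])
        for _ in range(50):
            stages = sample_stages(h, np.array([4, 4]), fixture_model, rng)
            assert np.all(np.diff(stages) >= 0)

    def test_impossible_evidence_identifies_slice(self, fixture_model, rng):
        m = fixture_model.copy()
        m.pi_onset[:, :] = 0.0  # activity at slice 0 has probability zero
        h = make_history("p", [(0, set()), (1, set())])
        with pytest.raises(ZeroProbabilityEvidenceError, match="slice 0"):
            sample_stages(h, np.array([0, 2]), m, rng)


class TestSampleComplications:
    def test_no_evidence_follows_prior(self, fixture_model, rng):
        """With zero activations and leaks driving all findings, onsets follow
        the prior onset chain."""
        m = fixture_model.copy()
        m.A[:] = 0.0  # no complication can fire any finding
        m.leak[:] = 0.2
        m.pi_onset[:] = 0.3
        m.h_onset[:] = 0.4
        h = make_history("p", [(0, set()), (1, set())])
        stages = np.array([0, 0])
        counts = np.zeros(3)
        n = 4000
        tau = None
        for _ in range(n):
            tau = sample_complications(h, stages, m, rng, onset_slices=tau)
            counts[tau[1]] += 1
        # prior: P(tau=0)=0.3, P(tau=1)=0.7*0.4, P(never)=0.7*0.6
        expect = np.array([0.3, 0.28, 0.42])
        assert np.allclose(counts / n, expect, atol=0.03)

    def test_anchored_code_with_zero_leak_forces_onset(self, fixture_model, rng):
        m = fixture_model.copy()
        m.leak[:] = 0.0
        h = make_history("p", [(0, set()), (1, {0})])  # code 0 anchored to comp 0
        stages = np.array([0, 1])
        tau = sample_complications(h, stages, m, rng)
        assert tau[0] <= 1  # active at slice 1 with probability 1

    def test_activity_is_monotone(self, fixture_model, rng):
        h = make_history("p", [(0, {0}), (1, set()), (2, {1, 3})])
        stages = np.array([0, 1, 2])
        for _ in range(50):
            tau = sample_complications(h, stages, m := fixture_model, rng)
            act = activity_matrix(tau, 3)
            assert np.all(act[1:] >= act[:-1])


class TestSampleAttributions:
    def test_leak_only_explanation(self, fixture_model, rng):
        m = fixture_model.copy()
        tau = np.array([2, 2])  # nothing active
        h = make_history("p", [(0, {2}), (1, set())])
        att = sample_attributions(h, tau, m, rng)
        assert att[0][2] == -1

    def test_equal_parents_split_evenly(self, fixture_model, rng):
        m = fixture_model.copy()
        m.A[0, 2] = m.A[1, 2] = 0.4
        m.leak[2] = 0.0
        h = make_history("p", [(0, {2}), (1, set())])
        tau = np.array([0, 0])
        counts = {0: 0, 1: 0}
        n = 4000
        for _ in range(n):
            counts[sample_attributions(h, tau, m, rng)[0][2]] += 1
        assert counts[0] / n == pytest.approx(0.5, abs=0.03)

    def test_zero_probability_positive_is_error(self, fixture_model, rng):
        m = fixture_model.copy()
        m.leak[:] = 0.0
        h = make_history("p", [(0, {3}), (1, set())])
        with pytest.raises(ZeroProbabilityEvidenceError):
            sample_attributions(h, np.array([2, 2]), m, rng)


class TestMStep:
    def _stats(self, K, W, N):
        return SufficientStats(K, W, N)

    def test_plug_in_counts_reproduce_parameters(self, fixture_model):
        """Counts matching a model's expectations return those parameters up
        to the Beta/Gamma smoothing bias."""
        m = fixture_model
        cfg = FitConfig()
        stats = self._stats(3, 2, 6)
        n = 10_000.0
        stats.pi_trials[:] = n
        stats.pi_succ[:] = n * m.pi_onset
        stats.h_succ[:] = n * m.h_onset
        stats.h_fail[:] = n * (1 - m.h_onset)
        stats.A_succ[:] = n * m.A
        stats.A_fail[:] = np.where(m.mask.allowed, n * (1 - m.A), 0.0)
        stats.leak_succ[:] = n * m.leak
        stats.leak_fail[:] = n * (1 - m.leak)
        stats.q_exposure[:] = n
        stats.q_jumps[:] = n * np.triu(m.Q, 1)
        new = m_step(stats, cfg, m)
        assert np.allclose(new.A, m.A, atol=1e-3)
        assert np.allclose(new.leak, m.leak, atol=1e-3)
        assert np.allclose(new.h_onset, m.h_onset, atol=1e-3)
        assert np.allclose(np.triu(new.Q, 1), np.triu(m.Q, 1), atol=1e-3)

    def test_no_data_returns_prior_mean(self, fixture_model):
        new = m_step(self._stats(3, 2, 6), FitConfig(beta_prior=(1.0, 1.0)),
                     fixture_model)
        assert np.allclose(new.pi_onset, 0.5)
        assert np.allclose(new.leak, 0.5)
        assert np.all(new.A[~fixture_model.mask.allowed] == 0.0)

    def test_unvisited_transitions_shrink_to_prior(self, fixture_model):
        stats = self._stats(3, 2, 6)
        stats.q_exposure[:] = [1000.0, 0.0, 0.0]  # everyone stays in stage 1
        new = m_step(stats, FitConfig(gamma_prior=(1.0, 1.0)), fixture_model)
        assert new.Q[0, 1] == pytest.approx(1.0 / 1001.0)
        assert new.Q[1, 2] == pytest.approx(1.0)  # pure prior mean


class TestFit:
    def test_single_patient_runs_and_is_valid(self, fixture_model):
        vocab = FindingVocabulary(fixture_model.codes)
        cfg = FitConfig(n_em_iterations=3, n_gibbs_sweeps=3, burn_in=1,
                        random_seed=0)
        h = make_history("p", [(0, {0}), (1, {0, 2})])
        model, diag = fit([h], cfg, fixture_model.anchor_set, vocab, K=3, W=2)
        assert model.validate() == []
        assert len(diag["loglik"]) == diag["n_iterations"]

    def test_identical_seed_bit_identical_diagnostics(self, fixture_model):
        vocab = FindingVocabulary(fixture_model.codes)
        cfg = FitConfig(n_em_iterations=4, n_gibbs_sweeps=3, burn_in=1,
                        random_seed=7)
        hs = [make_history("a", [(0, {0}), (1, {0, 2}), (2, {1})]),
              make_history("b", [(0, set()), (2, {3})])]
        _, d1 = fit(hs, cfg, fixture_model.anchor_set, vocab, K=3, W=2)
        _, d2 = fit(hs, cfg, fixture_model.anchor_set, vocab, K=3, W=2)
        assert d1["loglik"] == d2["loglik"]

    def test_empty_data_is_error(self, fixture_model):
        vocab = FindingVocabulary(fixture_model.codes)
        with pytest.raises(ValueError, match="at least one"):
            fit([], FitConfig(), fixture_model.anchor_set, vocab)

    def test_freeze_anchors_pins_anchored_links(self, fixture_model):
        vocab = FindingVocabulary(fixture_model.codes)
        cfg = FitConfig(n_em_iterations=2, n_gibbs_sweeps=2, burn_in=0,
                        random_seed=0, freeze_anchors=True, anchor_init=0.8)
        hs = [make_history("a", [(0, {0}), (1, {0, 1})])]
        model, _ = fit(hs, cfg, fixture_model.anchor_set, vocab, K=3, W=2)
        assert model.A[0, 0] == 0.8 and model.A[1, 1] == 0.8

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(burn_in=5, n_gibbs_sweeps=5).validate()
        with pytest.raises(ValueError):
            FitConfig(initial_stage="last").validate()
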