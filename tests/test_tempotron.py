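import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stn

from spiketempo.data import SpikeTrain, Trial
from spiketempo.lif import LIFParams, max_voltage, psp_kernel
from spiketempo import tempotron as tp
from spiketempo.tempotron import (
    TrainConfig,
    predict,
    tempotron_delta,
    train,
    vr_delta,
    vr_factor,
)
from .conftest import random_trial


@pytest.fixture
def lif():
    return LIFParams(tau=0.1, tau_s=0.025)


class TestTempotronDelta:
    def test_single_spike_at_peak_lag_gives_lambda(self, lif):
        lam, t_max = 0.01, 1.0
        trial = Trial(
            trains=(SpikeTrain(0, np.array([t_max - lif.t_peak])),), duration=2.0
        )
        delta = tempotron_delta(trial, t_max, lif, lam)
        assert delta[0] == pytest.approx(lam, abs=1e-12)

    def test_spikes_at_or_after_tmax_contribute_nothing(self, lif):
        trial = Trial(
            trains=(SpikeTrain(0, np.array([0.5, 0.7, 0.9])),), duration=2.0
        )
        assert tempotron_delta(trial, 0.5, lif, 0.01)[0] == 0.0

    def test_matches_manual_kernel_sum(self, lif):
        times = np.array([0.1, 0.25, 0.4])
        lam, t_max = 0.02, 0.5
        trial = Trial(trains=(SpikeTrain(0, times),), duration=1.0)
        expected = lam * sum(psp_kernel(t_max - ti, lif) for ti in times)
        assert tempotron_delta(trial, t_max, lif, lam)[0] == pytest.approx(
            expected, rel=1e-12
        )


class TestVRFactor:
    @settings(derandomize=True, max_examples=50)
    @given(
        seed=stn.integers(0, 100_000),
        n_groups=stn.integers(2, 6),
    )
    def test_target_positive_others_negative(self, seed, n_groups):
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 3, n_groups)
        target = int(rng.integers(n_groups))
        f = vr_factor(v, target)
        assert f[target] > 0
        others = np.delete(f, target)
        assert np.all(others < 0)

    def test_equal_voltages_closed_form(self):
        # all groups at V: target factor = f'(V) * (C-1) / (C * f(V));
        # C=2, V=0: f(0)=ln2, f'(0)=1/2 -> 1/(4 ln2)
        f = vr_factor([0.0, 0.0], target_group=0)
        assert f[0] == pytest.approx(1.0 / (4 * math.log(2)), rel=1e-12)
        for C in (3, 5):
            v = 0.7
            f = vr_factor([v] * C, target_group=1)
            sp = math.log(math.exp(v) + 1)
            sig = 1 / (1 + math.exp(-v))
            assert f[1] == pytest.approx(sig * (C - 1) / (C * sp), rel=1e-12)

    def test_factors_well_defined_for_very_negative_voltages(self):
        f = vr_factor([-50.0, -60.0, -40.0], target_group=0)
        assert np.all(np.isfinite(f))

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            vr_factor([1.0], target_group=0)


class TestVRDelta:
    def test_zero_factor_gives_zero_update(self, small_trial, lif):
        assert np.all(vr_delta(small_trial, 0.5, lif, 0.01, 0.0) == 0.0)

    def test_unit_factor_equals_tempotron_delta(self, small_trial, lif):
        np.testing.assert_allclose(
            vr_delta(small_trial, 0.5, lif, 0.01, 1.0),
            tempotron_delta(small_trial, 0.5, lif, 0.01),
        )

    @settings(derandomize=True, max_examples=25)
    @given(seed=stn.integers(0, 10_000), fp=stn.floats(-2.0, 2.0))
    def test_decomposes_as_delta_times_factor(self, seed, fp):
        rng = np.random.default_rng(seed)
        trial = random_trial(rng)
        lif = LIFParams(tau=0.1, tau_s=0.025)
        t_max = float(rng.uniform(0.1, 1.0))
        np.testing.assert_allclose(
            vr_delta(trial, t_max, lif, 0.01, fp),
            tempotron_delta(trial, t_max, lif, 0.01) * fp,
            rtol=1e-12,
        )


class TestVote:
    def test_majority_wins(self):
        # firing counts per group (3, 1, 0) with theta=1
        v = np.array([1.5, 1.2, 1.1, 1.3, 0.2, 0.1, 0.5, 0.4, 0.3])
        assert tp._vote(v, theta=1.0, C=3, G=3) == 0

    def test_all_silent_falls_back_to_summed_voltage(self):
        v = np.array([0.1, 0.2, 0.8, 0.3])  # sums (0.3, 1.1)
        assert tp._vote(v, theta=1.0, C=2, G=2) == 1

    def test_count_tie_broken_by_summed_voltage(self):
        # counts (1, 1); sums (1.4, 1.9) -> group 1
        v = np.array([1.1, 0.3, 1.2, 0.7])
        assert tp._vote(v, theta=1.0, C=2, G=2) == 1

    def test_full_tie_prefers_lowest_class_index(self):
        v = np.array([1.1, 0.3, 1.1, 0.3])
        assert tp._vote(v, theta=1.0, C=2, G=2) == 0


def _two_pattern_setup(lif):
    """Two 2-channel single-spike patterns and weights classifying them."""
    a = Trial(
        trains=(SpikeTrain(0, np.array([0.2])), SpikeTrain(1, np.array([]))),
        duration=1.0, label="a",
    )
    b = Trial(
        trains=(SpikeTrain(0, np.array([])), SpikeTrain(1, np.array([0.2]))),
        duration=1.0, label="b",
    )
    W = np.array([[2.0, -2.0], [-2.0, 2.0]])  # group 0 detects a, group 1 b
    return a, b, W


class TestTraining:
    def test_error_free_epoch_changes_no_weights(self, lif):
        """Classic updates are error-gated: a clean epoch is a no-op."""
        a, b, W = _two_pattern_setup(lif)
        cfg = TrainConfig(group_size=1, use_vr=False)
        compiled = tp._compile([a, b], lif, ("a", "b"))
        before = W.copy()
        n_err = tp.train_epoch(compiled, W, lif, cfg, order=[0, 1])
        assert n_err == 0
        np.testing.assert_array_equal(W, before)

    def test_erroneous_epoch_does_change_weights(self, lif):
        a, b, W = _two_pattern_setup(lif)
        W = -W  # now every neuron misbehaves
        cfg = TrainConfig(group_size=1, use_vr=False)
        compiled = tp._compile([a, b], lif, ("a", "b"))
        before = W.copy()
        n_err = tp.train_epoch(compiled, W, lif, cfg, order=[0, 1])
        assert n_err > 0
        assert not np.array_equal(W, before)

    def test_vr_sign_law_moves_voltages_the_right_way(self, lif, rng):
        """One VR step raises the target group's v_max, lowers the others'."""
        trial = random_trial(rng, n_channels=5, duration=1.0, label="a")
        C = 3
        W = rng.normal(0, 0.2, size=(C, 5))
        target = 0
        before = [max_voltage(trial, w, lif, refine=False) for w in W]
        factors = vr_factor([vs.v_max for vs in before], target)
        after = []
        for m in range(C):
            Wm = W[m] + vr_delta(trial, before[m].t_max, lif, 0.05, factors[m])
            after.append(max_voltage(trial, Wm, lif, refine=False))
        assert after[target].v_max >= before[target].v_max - 1e-12
        for m in range(1, C):
            assert after[m].v_max <= before[m].v_max + 1e-12

    def test_identical_seeds_identical_models(self, two_class_clean):
        cfg = TrainConfig(max_epochs=5, shuffle_seed=42)
        lif = LIFParams()
        m1 = train(two_class_clean, cfg, lif)
        m2 = train(two_class_clean, cfg, lif)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_different_shuffle_seeds_differ(self, two_class_clean):
        lif = LIFParams()
        m1 = train(two_class_clean, TrainConfig(max_epochs=5, shuffle_seed=1), lif)
        m2 = train(two_class_clean, TrainConfig(max_epochs=5, shuffle_seed=2), lif)
        assert not np.array_equal(m1.weights, m2.weights)

    def test_single_class_rejected(self, two_class_clean):
        only_a = [t for t in two_class_clean.trials if t.label == "odor-1"]
        with pytest.raises(ValueError, match="2 classes"):
            train(only_a, TrainConfig(), LIFParams())

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig(), LIFParams())

    def test_learns_clean_two_class_problem(self, two_class_clean):
        model = train(
            two_class_clean, TrainConfig(max_epochs=50, shuffle_seed=0), LIFParams()
        )
        assert model.history[-1]["train_accuracy"] == 1.0
        hits = sum(
            predict(model, t) == t.label for t in two_class_clean.trials
        )
        assert hits == len(two_class_clean)


class TestPredict:
    def test_channel_mismatch_rejected(self, two_class_clean, rng):
        model = train(
            two_class_clean, TrainConfig(max_epochs=2), LIFParams()
        )
        bad = random_trial(rng, n_channels=3)
        with pytest.raises(ValueError, match="channels"):
            predict(model, bad)


def test_model_roundtrip(tmp_path, two_class_clean):
    model = train(two_class_clean, TrainConfig(max_epochs=3), LIFParams())
    path = tmp_path / "model.json"
    tp.save_model(model, path)
    loaded = tp.load_model(path)
    np.testing.assert_array_equal(loaded.weights, model.weights)
    assert loaded.class_labels == model.class_labels
    assert loaded.params.tau == model.params.tau
    assert predict(loaded, two_class_clean.trials[0]) == predict(
        model, two_class_clean.trials[0]
    )
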