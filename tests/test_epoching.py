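import numpy as np
import pandas as pd
import pytest

from spnlab.epoching import (
    AlignmentError,
    average_conditions,
    baseline_correct,
    filter_correct,
    rereference_average,
    screen_epochs,
)
from tests.conftest import make_epochs


class TestBaselineCorrect:
    def test_constant_epoch_becomes_zero(self):
        ep = baseline_correct(make_epochs(np.full((1, 2, 3, 256), 5.0)))
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-6)

    def test_step_epoch_keeps_poststimulus_jump(self):
        data = np.zeros((1, 1, 1, 256))
        ep0 = make_epochs(data)
        data[..., ep0.times_ms > 0] = 7.0
        data[..., ep0.times_ms <= 0] = 2.0
        ep = baseline_correct(make_epochs(data))
        assert ep.data[..., ep.times_ms > 50].mean() == pytest.approx(5.0, abs=1e-5)
        mask = ep.window_mask((-200.0, 0.0))
        np.testing.assert_allclose(ep.data[..., mask].mean(axis=-1), 0.0, atol=1e-6)

    def test_idempotent(self, small_dataset):
        _, epochs = small_dataset
        once = baseline_correct(epochs)
        twice = baseline_correct(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-5)

    def test_empty_window_rejected(self, small_dataset):
        _, epochs = small_dataset
        with pytest.raises(ValueError):
            baseline_correct(epochs, (-199.9, -199.8))


class TestRereference:
    def test_balanced_channels_unchanged(self):
        data = np.stack(
            [np.ones((1, 2, 256)), -np.ones((1, 2, 256))], axis=2
        )
        ep = rereference_average(make_epochs(data))
        np.testing.assert_allclose(ep.data, data, atol=1e-6)

    def test_common_signal_removed(self):
        ep = rereference_average(make_epochs(np.full((1, 2, 4, 64), 3.3)))
        np.testing.assert_allclose(ep.data, 0.0, atol=1e-6)

    def test_idempotent_and_commutes_with_baseline(self, small_dataset):
        _, epochs = small_dataset
        a = rereference_average(baseline_correct(epochs))
        b = baseline_correct(rereference_average(epochs))
        np.testing.assert_allclose(a.data, b.data, atol=1e-4)
        np.testing.assert_allclose(
            rereference_average(a).data, a.data, atol=1e-5
        )


class TestScreenEpochs:
    def test_clean_epochs_all_retained(self):
        ep, report = screen_epochs(make_epochs(np.zeros((2, 10, 3, 128))))
        assert report.n_removed == 0
        assert ep.retained.all()

    def test_amplitude_flag_inside_window_only(self):
        data = np.zeros((1, 3, 1, 385))
        ref = make_epochs(data, t0_ms=-500.0)
        inside = np.argmin(np.abs(ref.times_ms - 300))
        outside = np.argmin(np.abs(ref.times_ms - 700))
        data[0, 1, 0, inside] = 130.0  # above 120 uV, within -200..600 ms
        data[0, 2, 0, outside] = 130.0  # outside the screened window
        ep, report = screen_epochs(make_epochs(data, t0_ms=-500.0))
        flags = report.flags.set_index("trial")
        assert flags.loc[1, "removed"] and flags.loc[1, "amplitude"]
        assert not flags.loc[2, "removed"]
        assert not flags.loc[0, "removed"]

    def test_trend_flag_threshold_on_fitted_change(self):
        # noise-free ramps: R^2 = 1, so the fitted-change criterion decides
        S = 385
        ramp = np.linspace(-0.5, 0.5, S)
        data = np.zeros((1, 2, 1, S))
        data[0, 0, 0] = 100.0 * ramp  # 100 uV rise across the epoch
        data[0, 1, 0] = 50.0 * ramp  # 50 uV rise: retained
        ep, report = screen_epochs(make_epochs(data, t0_ms=-500.0))
        flags = report.flags.set_index("trial")
        assert flags.loc[0, "trend"] and flags.loc[0, "removed"]
        assert not flags.loc[1, "removed"]

    def test_kurtosis_outlier_flagged(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((1, 80, 1, 385))
        data[0, 5, 0, 100] = 30.0  # single heavy-tailed epoch
        ep, report = screen_epochs(make_epochs(data, t0_ms=-500.0))
        flags = report.flags.set_index("trial")
        assert flags.loc[5, "kurtosis_local"]

    def test_bookkeeping_and_monotonicity(self, small_dataset):
        _, epochs = small_dataset
        ep1, r1 = screen_epochs(epochs, amp_limit_uv=30.0)
        ep2, r2 = screen_epochs(epochs, amp_limit_uv=120.0)
        assert r1.n_removed + r1.n_retained == r1.n_input
        removed1 = set(map(tuple, r1.flags.loc[r1.flags["removed"], ["participant", "trial"]].values))
        removed2 = set(map(tuple, r2.flags.loc[r2.flags["removed"], ["participant", "trial"]].values))
        amp1 = set(map(tuple, r1.flags.loc[r1.flags["amplitude"], ["participant", "trial"]].values))
        amp2 = set(map(tuple, r2.flags.loc[r2.flags["amplitude"], ["participant", "trial"]].values))
        assert amp2 <= amp1
        assert removed2 <= removed1

    def test_filter_then_screen_differs_from_screen_then_filter(self):
        """The kurtosis z-scores are relative to the screened epoch set, so
        removing incorrect trials first can expose an outlier that a larger,
        more contaminated set would mask."""
        rng = np.random.default_rng(1)
        data = rng.standard_normal((1, 80, 1, 385))
        t0 = -500.0
        times = t0 + np.arange(385) * 1000.0 / 256.0
        late = np.argmin(np.abs(times - 700))  # outside the amplitude window
        data[0, 0, 0, late] = 110.0  # extreme kurtosis, on the incorrect trial
        data[0, 1, 0, late] = 20.0  # moderate outlier
        correct = np.ones((1, 80), dtype=bool)
        correct[0, 0] = False
        ep = make_epochs(data, t0_ms=t0, correct=correct)
        behavior = pd.DataFrame(
            {
                "participant": 0,
                "trial": np.arange(80),
                "condition": ep.conditions[0],
                "response": np.where(correct[0], ep.conditions[0], "X"),
                "correct": correct[0],
            }
        )
        # paper order: correctness filter first, then quality screen
        a, _ = screen_epochs(filter_correct(ep, behavior))
        # swapped order
        b = filter_correct(screen_epochs(ep)[0], behavior)
        assert not a.retained[0, 1]  # outlier exposed
        assert b.retained[0, 1]  # outlier masked by the extreme trial
        assert a.retained.sum() != b.retained.sum()


class TestFilterCorrect:
    def make_behavior(self, ep, correct):
        return pd.DataFrame(
            {
                "participant": np.repeat(ep.participants, ep.shape[1]),
                "trial": np.tile(np.arange(ep.shape[1]), ep.shape[0]),
                "condition": ep.conditions.ravel(),
                "response": np.where(correct.ravel(), ep.conditions.ravel(), "X"),
                "correct": correct.ravel(),
            }
        )

    def test_all_correct_is_identity(self):
        ep = make_epochs(np.zeros((2, 6, 2, 64)))
        beh = self.make_behavior(ep, np.ones((2, 6), dtype=bool))
        assert filter_correct(ep, beh).retained.all()

    def test_all_incorrect_warns_and_empties(self):
        ep = make_epochs(np.zeros((1, 4, 2, 64)))
        beh = self.make_behavior(ep, np.zeros((1, 4), dtype=bool))
        with pytest.warns(UserWarning, match="no correct trials"):
            out = filter_correct(ep, beh)
        assert not out.retained.any()

    def test_misaligned_trials_rejected(self):
        ep = make_epochs(np.zeros((1, 4, 2, 64)))
        beh = self.make_behavior(ep, np.ones((1, 4), dtype=bool)).iloc[:-1]
        with pytest.raises(AlignmentError):
            filter_correct(ep, beh)

    def test_retained_count_arithmetic(self):
        # 120 trials, 24 incorrect, screening removes 2 more -> 94 retained
        rng = np.random.default_rng(3)
        data = rng.standard_normal((1, 120, 2, 385)) * 5.0
        ep = make_epochs(data, t0_ms=-500.0)
        correct = np.ones((1, 120), dtype=bool)
        correct[0, :24] = False
        inside = np.argmin(np.abs(ep.times_ms - 400))
        data[0, 30, 0, inside] = 200.0
        data[0, 31, 0, inside] = -200.0
        ep = make_epochs(data, t0_ms=-500.0, correct=correct)
        beh = TestFilterCorrect().make_behavior(ep, correct)
        screened, report = screen_epochs(filter_correct(ep, beh))
        assert report.n_input == 96
        assert report.n_removed == 2
        assert screened.retained.sum() == 94


class TestAverageConditions:
    def test_single_trial_average_is_identity(self):
        data = np.zeros((1, 2, 2, 64))
        data[0, 0] = 1.5  # the only S trial
        data[0, 1] = -2.0  # the only A trial
        erps = average_conditions(make_epochs(data))
        np.testing.assert_allclose(erps.erp[0, 0], 1.5, atol=1e-6)
        np.testing.assert_allclose(erps.erp[0, 1], -2.0, atol=1e-6)
        assert erps.counts.tolist() == [[1, 1]]

    def test_opposite_trials_cancel(self):
        data = np.zeros((1, 4, 1, 32))
        data[0, 0] = 1.0
        data[0, 2] = -1.0  # trials 0 and 2 are both "S"
        erps = average_conditions(make_epochs(data))
        np.testing.assert_allclose(erps.erp[0, 0], 0.0, atol=1e-7)

    def test_linearity(self, small_dataset):
        _, epochs = small_dataset
        a = epochs.copy()
        b = epochs.copy()
        b.data = (b.data * 2.0).astype(b.data.dtype)
        s = epochs.copy()
        s.data = (a.data + b.data).astype(a.data.dtype)
        np.testing.assert_allclose(
            average_conditions(s).erp,
            average_conditions(a).erp + average_conditions(b).erp,
            atol=1e-3,
        )

    def test_empty_condition_excludes_participant(self):
        data = np.zeros((2, 4, 1, 32))
        conditions = np.array([["S", "A", "S", "A"], ["S", "S", "S", "S"]])
        ep = make_epochs(data, conditions=conditions)
        with pytest.warns(UserWarning, match="excluded"):
            erps = average_conditions(ep)
        assert erps.participants == (0,)
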