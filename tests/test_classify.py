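"""Response calls, latencies, learning modulation, and proportions."""

import numpy as np
import pytest

import ceatopo as ct
from ceatopo import InsufficientDataError, SchemaError


def _peri(values, frame_rate=6.0, pre=10.0, post=10.0):
    """Wrap (neuron, event, frame) values into a tensor."""
    values = np.asarray(values, float)
    if values.ndim == 2:
        values = values[:, None, :]
    return ct.PeriEventTensor(values=values, frame_rate=frame_rate, window=(pre, post))


def _step_tensor(base_val, resp_val, n_neurons=1, noise=None, rng=None):
    """121-frame snippet: frames < 0 at base_val, frames >= 0 at resp_val."""
    snip = np.concatenate([np.full(60, float(base_val)), np.full(61, float(resp_val))])
    vals = np.tile(snip, (n_neurons, 1))
    if noise:
        vals = vals + rng.normal(0.0, noise, size=vals.shape)
    return _peri(vals)


class TestClassifyResponse:
    def test_null_response_called_none_by_signed_rank(self, rng):
        # the AUC sub-criterion is ill-posed on zero-mean noise (its
        # threshold ~ |2 x baseline AUC| collapses), so calibration is a
        # signed-rank property; the OR-criterion rate is checked for
        # stability elsewhere
        peri = _peri(rng.normal(0.0, 1.0, size=(50, 121)))
        out = ct.classify_response(
            peri, (-10.0, 0.0), (0.0, 10.0), alpha=0.001, criterion="signed_rank"
        )
        assert (out["call"] == "none").mean() > 0.9

    def test_auc_ratio_criterion_fires_above_factor(self):
        # constant segments: baseline per-second AUC a, response 2.5a
        peri = _step_tensor(1.0, 2.5)
        out = ct.classify_response(
            peri, (-10.0, -1.0), (1.0, 10.0), criterion="auc_ratio"
        )
        assert out.loc[0, "call"] == "excited"
        assert out.loc[0, "auc_ratio"] == pytest.approx(2.5, abs=1e-9)
        # 1.5a does not clear the 2x factor
        out2 = ct.classify_response(
            _step_tensor(1.0, 1.5), (-10.0, -1.0), (1.0, 10.0), criterion="auc_ratio"
        )
        assert out2.loc[0, "call"] == "none"

    def test_reflected_response_called_inhibited(self, rng):
        peri = _step_tensor(0.5, -0.5, n_neurons=5, noise=0.05, rng=rng)
        out = ct.classify_response(peri, (-10.0, -1.0), (1.0, 10.0))
        assert (out["call"] == "inhibited").all()

    def test_negation_swaps_excited_and_inhibited_exactly(self, rng):
        vals = rng.normal(0.0, 1.0, size=(60, 121))
        vals[:20, 65:] += 1.5  # planted excitation in a third of neurons
        a = ct.classify_response(_peri(vals), (-10.0, 0.0), (0.0, 10.0))
        b = ct.classify_response(_peri(-vals), (-10.0, 0.0), (0.0, 10.0))
        assert (a["call"] == "excited").sum() == (b["call"] == "inhibited").sum()
        assert (a["call"] == "inhibited").sum() == (b["call"] == "excited").sum()
        assert list(a["call"].map({"excited": "inhibited", "inhibited": "excited", "none": "none"})) == list(b["call"])

    def test_degenerate_all_tied_flags_none(self):
        peri = _peri(np.zeros((2, 121)))
        out = ct.classify_response(peri, (-10.0, 0.0), (0.0, 10.0))
        assert (out["call"] == "none").all()
        assert out["degenerate"].all()


class TestClassifyBlockwise:
    def _block(self, level, n_neurons=6, n_frames=120, noise=0.2, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.full((n_neurons, 1, n_frames), float(level)) + rng.normal(
            0.0, noise, size=(n_neurons, 1, n_frames)
        )
        return ct.PeriEventTensor(
            values=vals, frame_rate=6.0, window=(0.0, (n_frames - 1) / 6.0)
        )

    def test_single_elevated_block_detected(self):
        baseline = self._block(0.0, seed=1)
        blocks = [self._block(0.0, seed=2), self._block(1.0, seed=3), self._block(0.0, seed=4)]
        per_block, summary = ct.classify_blockwise(blocks, baseline, alpha=1e-4)
        assert summary["any_block_excited"].all()
        excited_blocks = per_block[per_block["call"] == "excited"]["block"].unique()
        assert list(excited_blocks) == [1]

    def test_all_blocks_identical_not_excited(self):
        baseline = self._block(0.0, seed=5)
        blocks = [self._block(0.0, seed=5), self._block(0.0, seed=5)]
        _, summary = ct.classify_blockwise(blocks, baseline)
        assert not summary["any_block_excited"].any()

    def test_block_order_is_a_relabeling(self):
        baseline = self._block(0.0, seed=6)
        blocks = [self._block(0.3, seed=7), self._block(1.0, seed=8)]
        a, _ = ct.classify_blockwise(blocks, baseline)
        b, _ = ct.classify_blockwise(blocks[::-1], baseline)
        a0 = a[a["block"] == 0].reset_index(drop=True).drop(columns="block")
        b1 = b[b["block"] == 1].reset_index(drop=True).drop(columns="block")
        assert a0.equals(b1)

    def test_mismatched_neuron_sets_rejected(self):
        with pytest.raises(SchemaError):
            ct.classify_blockwise([self._block(0.0, n_neurons=4)], self._block(0.0, n_neurons=6))


class TestMonotonicIncrease:
    def _norm(self, values):
        return ct.NormalizedTrace(
            values=np.atleast_2d(np.asarray(values, float)), frame_rate=6.0, mode="dff"
        )

    def test_noiseless_ramp_flagged_with_exact_slope(self):
        t = np.arange(0, 70, 1 / 6)
        out = ct.detect_monotonic_increase(self._norm(0.01 * t), window=(0.0, 60.0))
        assert bool(out.loc[0, "increasing"])
        assert out.loc[0, "slope"] == pytest.approx(0.01, abs=1e-12)

    def test_constant_and_decreasing_not_flagged(self):
        t = np.arange(0, 70, 1 / 6)
        flat = ct.detect_monotonic_increase(self._norm(np.ones_like(t)))
        down = ct.detect_monotonic_increase(self._norm(-0.01 * t))
        assert not flat.loc[0, "increasing"] and flat.loc[0, "slope"] == 0.0
        assert not down.loc[0, "increasing"]


class TestLearningModulation:
    def test_monotone_trials_increasing(self):
        out = ct.detect_learning_modulation(np.array([[0.0, 1.0, 2.0, 3.0, 4.0]]))
        assert out.loc[0, "call"] == "increasing"
        assert out.loc[0, "method"] == "slope"

    def test_constant_trials_stable(self):
        out = ct.detect_learning_modulation(np.ones((3, 5)))
        assert (out["call"] == "stable").all()

    def test_first_vs_last_frames_drive_call(self):
        first = np.zeros((1, 120))
        last = np.ones((1, 120))
        responses = np.array([[0.0, 1.0]])  # two trials: slope p undefined
        out = ct.detect_learning_modulation(responses, first, last)
        assert out.loc[0, "call"] == "increasing"
        assert out.loc[0, "method"] == "first_vs_last"

    def test_single_trial_rejected(self):
        with pytest.raises(InsufficientDataError):
            ct.detect_learning_modulation(np.ones((2, 1)))


class TestTrialCrossCorrelation:
    def test_identity_negation_and_hand_oracle(self):
        vals = np.zeros((3, 2, 3))
        vals[0] = [[0, 1, 2], [0, 1, 2]]
        vals[1] = [[0, 1, 2], [0, -1, -2]]
        vals[2] = [[0, 1, 2], [0, 2, 2]]
        peri = ct.PeriEventTensor(values=vals, frame_rate=6.0, window=(0.0, 2 / 6))
        out = ct.trial_cross_correlation(peri, 0, 1)
        assert out.loc[0, "r"] == pytest.approx(1.0, abs=1e-12)
        assert out.loc[1, "r"] == pytest.approx(-1.0, abs=1e-12)
        assert out.loc[2, "r"] == pytest.approx(np.sqrt(3) / 2, abs=1e-9)

    def test_zero_variance_snippet_flagged(self):
        vals = np.zeros((1, 2, 5))
        vals[0, 0] = np.arange(5)
        peri = ct.PeriEventTensor(values=vals, frame_rate=6.0, window=(0.0, 4 / 6))
        out = ct.trial_cross_correlation(peri, 0, 1)
        assert not out.loc[0, "defined"]
        assert np.isnan(out.loc[0, "r"])


class TestResponseLatency:
    def _peri_step(self, step_at_s, amp=5.0):
        snip = np.zeros(121)
        t = (np.arange(121) - 60) / 6.0
        snip[t >= step_at_s] = amp
        return _peri(snip[None, :])

    def test_step_at_onset_has_zero_latency(self):
        out = ct.response_latency(self._peri_step(0.0), threshold_sd=2.0)
        assert out.loc[0, "latency_s"] == 0.0

    def test_step_two_seconds_in(self):
        out = ct.response_latency(self._peri_step(2.0), threshold_sd=2.0)
        assert out.loc[0, "latency_s"] == pytest.approx(2.0, abs=1e-9)

    def test_subthreshold_is_undefined(self):
        out = ct.response_latency(self._peri_step(0.0, amp=1.0), threshold_sd=2.0)
        assert not out.loc[0, "defined"]

    def test_sorting_reproduces_planted_order(self):
        tensors = [self._peri_step(s) for s in (3.0, 0.5, 1.5)]
        vals = np.concatenate([t.values for t in tensors], axis=0)
        peri = _peri(vals[:, 0, :])
        out = ct.response_latency(peri)
        assert list(np.argsort(out["latency_s"])) == [1, 2, 0]


class TestPopulationProportions:
    def test_all_excited_degenerate(self):
        import pandas as pd

        labels = pd.DataFrame({"call": ["excited"] * 10})
        est = ct.population_proportions(labels, n_boot=100, seed=0)
        assert est.p_hat == 1.0 and est.boot_sd == 0.0

    def test_seed_reproducibility(self):
        import pandas as pd

        labels = pd.DataFrame({"call": ["excited", "none"] * 25})
        a = ct.population_proportions(labels, n_boot=500, seed=42)
        b = ct.population_proportions(labels, n_boot=500, seed=42)
        assert (a.boot_mean, a.boot_sd) == (b.boot_mean, b.boot_sd)

    def test_binomial_closed_form_sd(self):
        import pandas as pd

        labels = pd.DataFrame({"call": ["excited"] * 50 + ["none"] * 50})
        est = ct.population_proportions(labels, n_boot=10_000, seed=0)
        assert est.boot_sd == pytest.approx(0.05, rel=0.1)
        assert est.boot_mean == pytest.approx(est.p_hat, abs=3 * est.boot_sd / np.sqrt(est.n_boot) + 1e-3)


class TestCompareEventConditions:
    def test_identical_pairs_no_difference(self):
        stat, p, direction = ct.compare_event_conditions(np.ones(10), np.ones(10))
        assert p == 1.0 and direction == "none"

    def test_uniform_shift_rejected(self, rng):
        base = rng.normal(0.0, 1.0, 30)
        _, p, direction = ct.compare_event_conditions(base + 1.0, base)
        assert p < 0.05 and direction == "higher"

    def test_single_pair_rejected(self):
        with pytest.raises(InsufficientDataError):
            ct.compare_event_conditions([1.0], [2.0])
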