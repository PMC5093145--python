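"""Recognition metrics, activity histograms and the system report."""

import numpy as np
import pytest

from snn_spikesort.encoder import SignalTrace
from snn_spikesort.evaluation import (
    EvaluationConfig,
    activity_histogram,
    assign_neurons,
    data_reduction,
    recognition_rate,
    system_report,
)
from snn_spikesort.network import SpikeTrain
from snn_spikesort.oxram import EnergyModel, EventLedger
from snn_spikesort.synth import GroundTruth


def _train(times, ids, n=5):
    order = np.argsort(times, kind="stable")
    return SpikeTrain(np.asarray(times, float)[order],
                      np.asarray(ids, int)[order], "output", n)


def _brute_force_rate(truth_times, spike_times, window):
    """Independent O(n^2) oracle for the matched fraction."""
    hits = 0
    for t in truth_times:
        if any(t < s <= t + window for s in spike_times):
            hits += 1
    return hits / len(truth_times) if len(truth_times) else float("nan")


class TestAssignment:
    def test_single_unit_single_responder(self):
        truth = GroundTruth({"A": np.array([1.0, 2.0, 3.0, 4.0, 5.0])})
        out = _train([1.005, 2.005, 3.005, 4.005, 5.005], [2] * 5)
        assert assign_neurons(out, truth) == {"A": 2}

    def test_two_units_disjoint_neurons(self):
        truth = GroundTruth({"A": np.array([1.0, 2.0]), "B": np.array([10.0, 11.0])})
        out = _train([1.01, 2.01, 10.01, 11.01], [3, 3, 0, 0])
        assert assign_neurons(out, truth) == {"A": 3, "B": 0}

    def test_acausal_spikes_do_not_match(self):
        """A neuron spiking only before events is never assigned."""
        truth = GroundTruth({"A": np.array([1.0, 2.0, 3.0])})
        out = _train([0.99, 1.99, 2.99], [1, 1, 1])
        assert assign_neurons(out, truth) == {}

    def test_spike_exactly_at_event_time_is_not_causal(self):
        truth = GroundTruth({"A": np.array([1.0])})
        out = _train([1.0], [0])
        assert assign_neurons(out, truth) == {}

    def test_empty_output_warns_and_returns_empty(self):
        truth = GroundTruth({"A": np.array([1.0])})
        out = _train([], [])
        with pytest.warns(UserWarning):
            assert assign_neurons(out, truth) == {}

    def test_assignment_is_injective(self):
        # one neuron matches both units; the weaker unit gets the next best
        truth = GroundTruth({"A": np.array([1.0, 2.0, 3.0]), "B": np.array([1.0, 2.0])})
        out = _train([1.005, 2.005, 3.005, 1.01, 2.01], [0, 0, 0, 1, 1])
        assignment = assign_neurons(out, truth)
        assert assignment["A"] == 0 and assignment["B"] == 1


class TestRecognitionRate:
    def test_four_of_five_is_point_eight(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = _train([1.01, 2.01, 3.01, 4.01], [0] * 4)
        rep = recognition_rate(out, truth, 0, EvaluationConfig())
        assert rep.mean == pytest.approx(0.8)

    def test_silent_neuron_scores_zero(self):
        truth = np.array([1.0, 2.0])
        out = _train([1.5], [3], n=5)
        rep = recognition_rate(out, truth, 0, EvaluationConfig())
        assert rep.mean == 0.0

    def test_all_events_recognized(self):
        truth = np.array([1.0, 2.0, 3.0])
        out = _train([1.01, 2.01, 3.01], [0] * 3)
        rep = recognition_rate(out, truth, 0, EvaluationConfig())
        assert rep.mean == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = np.sort(rng.uniform(0, 9.9, size=40))
        spikes = np.sort(rng.uniform(0, 10, size=60))
        out = _train(spikes, np.zeros(60, int))
        cfg = EvaluationConfig(match_window_s=0.05, bin_s=100.0)  # single bin
        rep = recognition_rate(out, truth, 0, cfg)
        assert rep.mean == pytest.approx(_brute_force_rate(truth, spikes, 0.05))

    def test_mean_skips_empty_bins(self):
        """Bins before the unit's first event carry no weight in the mean."""
        truth = np.array([25.0, 26.0])  # only in bin [20, 30)
        out = _train([25.01, 26.01], [0, 0])
        rep = recognition_rate(out, truth, 0, EvaluationConfig(), duration_s=40.0)
        assert np.isnan(rep.per_bin[0]) and np.isnan(rep.per_bin[1])
        assert rep.per_bin[2] == pytest.approx(1.0)
        assert rep.mean == pytest.approx(1.0)

    def test_invariant_to_spikes_outside_all_windows(self):
        truth = np.array([1.0, 2.0])
        base = _train([1.01, 2.01], [0, 0])
        noisy = _train([0.5, 1.01, 1.5, 2.01, 9.0], [0] * 5)
        cfg = EvaluationConfig()
        assert recognition_rate(base, truth, 0, cfg).mean == pytest.approx(
            recognition_rate(noisy, truth, 0, cfg).mean
        )


class TestActivityHistogram:
    def test_empty_train_all_zeros(self):
        hist = activity_histogram(_train([], []), 10.0, duration_s=30.0)
        assert hist.shape == (5, 3)
        assert hist.sum() == 0

    def test_counts_land_in_their_bin(self):
        out = _train([11.0 + 0.1 * k for k in range(7)], [2] * 7)
        hist = activity_histogram(out, 10.0, duration_s=30.0)
        assert hist[2, 1] == 7
        assert hist.sum() == 7

    def test_total_conservation_on_random_trains(self, rng):
        times = np.sort(rng.uniform(0, 100, size=500))
        ids = rng.integers(0, 5, size=500)
        hist = activity_histogram(_train(times, ids), 10.0, duration_s=100.0)
        assert hist.sum() == 500
        np.testing.assert_array_equal(hist.sum(axis=1), np.bincount(ids, minlength=5))


class TestSystemReport:
    def test_reference_counts_give_11_microjoules(self):
        """Feeding the reference run's event counts and per-event energies
        through the report reproduces the ~11 uJ total."""
        model = EnergyModel()
        ledger = EventLedger(
            n_read=16_200_000, n_set=27_500, n_reset=58_600,
            e_read_j=16_200_000 * 0.39e-12,
            e_set_j=27_500 * model.e_set_j,
            e_reset_j=58_600 * model.e_reset_j,
        )
        rep = system_report(ledger, model, duration_s=681.0, n_devices=1600,
                            n_synapses=160)
        assert rep.e_total_j == pytest.approx(11e-6, rel=0.05)
        assert round(rep.sets_per_device) == 17
        assert round(rep.resets_per_device) == 37
        assert rep.sets_per_device_10y == pytest.approx(8e6, rel=0.01)
        assert rep.resets_per_device_10y == pytest.approx(1.7e7, rel=0.01)
        assert rep.power_w == pytest.approx(rep.e_total_j / 681.0)

    def test_neuron_energy_term(self):
        rep = system_report(EventLedger(), EnergyModel(), 10.0, 1600,
                            neuron_spike_count=330_000)
        assert rep.e_neurons_j == pytest.approx(0.66e-6)

    def test_zero_events_zero_energy(self):
        rep = system_report(EventLedger(), EnergyModel(), 5.0, 100)
        assert rep.e_total_j == 0.0 and rep.power_w == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            system_report(EventLedger(), EnergyModel(), 0.0, 100)


class TestDataReduction:
    def test_sample_to_event_ratio(self):
        trace = SignalTrace(np.zeros(20000), 20000.0)
        out = _train(np.linspace(0.1, 0.9, 10), np.zeros(10, int))
        assert data_reduction(trace, out) == pytest.approx(2000.0)

    def test_no_output_is_unbounded(self):
        trace = SignalTrace(np.zeros(100), 20000.0)
        assert data_reduction(trace, _train([], [])) == np.inf

    def test_doubling_events_halves_ratio(self):
        trace = SignalTrace(np.zeros(20000), 20000.0)
        r10 = data_reduction(trace, _train(np.linspace(0.1, 0.9, 10), np.zeros(10, int)))
        r20 = data_reduction(trace, _train(np.linspace(0.1, 0.9, 20), np.zeros(20, int)))
        assert r20 == pytest.approx(r10 / 2)
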