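"""Network loop: STDP branches, winner-take-all, topology, determinism."""

import dataclasses

import numpy as np
import pytest

from snn_spikesort.encoder import SignalTrace
from snn_spikesort.errors import InvalidInputError
from snn_spikesort.network import (
    NetworkConfig,
    STDPParams,
    SpikeTrain,
    apply_stdp,
    build_synapses,
    run_network,
    weight_matrix,
    winner_take_all,
)
from snn_spikesort.oxram import (
    CompoundSynapse,
    DeviceState,
    EnergyModel,
    EventLedger,
    OxRAMDevice,
    ResistanceDistribution,
    SynapseConfig,
    synapse_weight,
)

ZERO_SPREAD = ResistanceDistribution(
    median_lrs_ohm=25e3, sigma_log_lrs=0.0, median_hrs_ohm=250e3, sigma_log_hrs=0.0
)


def _all_hrs_synapse(n=10):
    return CompoundSynapse(
        [OxRAMDevice(DeviceState.HRS, 1.0 / 250e3) for _ in range(n)], ZERO_SPREAD
    )


def _all_lrs_synapse(n=10):
    return CompoundSynapse(
        [OxRAMDevice(DeviceState.LRS, 1.0 / 25e3) for _ in range(n)], ZERO_SPREAD
    )


class TestApplyStdp:
    def test_certain_potentiation_saturates_weight(self, rng):
        syn = _all_hrs_synapse()
        params = STDPParams(p_set=1.0, p_reset=0.0, t_ltp_s=0.010)
        apply_stdp(0, 1.0, np.array([0.995]), params, [syn], rng,
                   EventLedger(), EnergyModel())
        assert synapse_weight(syn) == pytest.approx(1.0)

    def test_zero_probabilities_freeze_everything(self, rng):
        syn = _all_lrs_synapse()
        ledger = EventLedger()
        params = STDPParams(p_set=0.0, p_reset=0.0, t_ltp_s=0.010)
        apply_stdp(0, 1.0, np.array([0.999]), params, [syn], rng, ledger, EnergyModel())
        assert synapse_weight(syn) == pytest.approx(1.0)
        assert ledger.n_set == ledger.n_reset == 0

    def test_silent_input_takes_depression_branch(self, rng):
        """An input that never spiked (last pre-time -inf) is depressed."""
        syn = _all_lrs_synapse()
        params = STDPParams(p_set=1.0, p_reset=1.0, t_ltp_s=0.010)
        apply_stdp(0, 1.0, np.array([-np.inf]), params, [syn], rng,
                   EventLedger(), EnergyModel())
        assert synapse_weight(syn) == pytest.approx(0.0)

    def test_gradual_ltp_matches_bernoulli_closed_form(self, rng):
        """After k LTP rounds from all-HRS the expected LRS fraction is
        1 - (1 - p_set)^k; a 500-synapse Monte-Carlo must sit within
        3 standard errors (small-scale version of the acceptance check)."""
        p_set, k, n_syn, n_dev = 0.2, 4, 500, 10
        params = STDPParams(p_set=p_set, p_reset=0.0, t_ltp_s=0.010)
        synapses = [_all_hrs_synapse(n_dev) for _ in range(n_syn)]
        for _ in range(k):
            apply_stdp(0, 1.0, np.zeros(n_syn) + 0.995, params, synapses, rng,
                       EventLedger(), EnergyModel())
        frac = np.mean([
            np.mean([d.state is DeviceState.LRS for d in syn.devices])
            for syn in synapses
        ])
        expected = 1.0 - (1.0 - p_set) ** k
        se = np.sqrt(expected * (1 - expected) / (n_syn * n_dev))
        assert abs(frac - expected) < 3 * se

    def test_pre_after_post_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            apply_stdp(0, 1.0, np.array([2.0]), STDPParams(), [_all_hrs_synapse()],
                       rng, EventLedger(), EnergyModel())


class TestWinnerTakeAll:
    def test_argmax_above_threshold(self):
        elig = np.ones(5, dtype=bool)
        assert winner_take_all(np.array([0.6, 0.59, 0, 0, 0]), elig, 0.58) == 0

    def test_all_subthreshold_is_none(self):
        assert winner_take_all(np.full(5, 0.5), np.ones(5, bool), 0.58) is None

    def test_tie_goes_to_lowest_id(self):
        assert winner_take_all(np.array([0.0, 0.6, 0.6, 0.0, 0.0]),
                               np.ones(5, bool), 0.58) == 1

    def test_ineligible_neurons_cannot_win(self):
        elig = np.array([False, True, False, False, False])
        assert winner_take_all(np.array([0.9, 0.6, 0.7, 0, 0]), elig, 0.58) == 1
        assert winner_take_all(np.array([0.9, 0.0, 0.7, 0, 0]), elig, 0.58) is None


def _channels(n=32, n_samp=2000, rate=20000.0):
    return [SignalTrace(np.zeros(n_samp), rate) for _ in range(n)]


class TestRunNetwork:
    def test_default_topology_160_synapses_1600_devices(self, rng):
        syns = build_synapses(32, 5, SynapseConfig(), rng)
        flat = [s for row in syns for s in row]
        assert len(flat) == 160
        assert sum(s.n for s in flat) == 1600

    def test_zero_input_is_silent_with_empty_ledger(self):
        run = run_network(_channels())
        assert len(run.input_spikes) == 0
        assert len(run.output_spikes) == 0
        assert run.ledger.n_read == run.ledger.n_set == run.ledger.n_reset == 0

    def test_channel_mismatch_rejected(self):
        chans = _channels()
        chans[3] = SignalTrace(np.zeros(1999), 20000.0)
        with pytest.raises(InvalidInputError):
            run_network(chans)
        with pytest.raises(InvalidInputError):
            run_network(_channels(n=31))

    def test_coincident_burst_drives_deterministic_output(self):
        """Learning off, all weights saturated: a strong coincident burst
        across several channels produces identical output spikes across
        reruns (the determinism contract)."""
        chans = _channels()
        burst = np.zeros(2000)
        burst[100:300] = 0.5
        for c in range(4, 12):
            chans[c] = SignalTrace(burst, 20000.0)
        results = []
        for _ in range(2):
            synapses = [[_all_lrs_synapse() for _ in range(5)] for _ in range(32)]
            run = run_network(chans, synapses=synapses, learning=False)
            results.append(run)
        assert len(results[0].output_spikes) > 0
        np.testing.assert_array_equal(results[0].output_spikes.times_s,
                                      results[1].output_spikes.times_s)
        np.testing.assert_array_equal(results[0].output_spikes.neuron_ids,
                                      results[1].output_spikes.neuron_ids)

    def test_learning_off_read_counts_follow_input_spikes(self):
        chans = _channels()
        burst = np.zeros(2000)
        burst[100:400] = 0.4
        chans[7] = SignalTrace(burst, 20000.0)
        run = run_network(chans, learning=False)
        assert run.ledger.n_set == 0 and run.ledger.n_reset == 0
        assert run.ledger.n_read == len(run.input_spikes) * 5 * 10


class TestRunInvariants:
    """Whole-run invariants on a short sorted recording (session fixture)."""

    def test_at_most_one_output_spike_per_step(self, small_sorted_run):
        _, _, _, run = small_sorted_run
        times = run.output_spikes.times_s
        assert len(run.output_spikes) > 0
        assert np.unique(times).size == times.size

    def test_weights_stay_in_unit_interval(self, small_sorted_run):
        _, _, _, run = small_sorted_run
        w = weight_matrix(run.synapses)
        assert np.all(w >= 0.0) and np.all(w <= 1.0)
        np.testing.assert_allclose(run.weights, w)

    def test_output_respects_refractory_period(self, small_sorted_run):
        cfg, _, _, run = small_sorted_run
        for j in range(cfg.network.n_output):
            isi = np.diff(run.output_spikes.for_neuron(j))
            if isi.size:
                assert isi.min() > cfg.layer2.t_refractory_s

    def test_ledger_energy_is_sum_of_modes(self, small_sorted_run):
        _, _, _, run = small_sorted_run
        ledger = run.ledger
        assert ledger.e_total_j == pytest.approx(
            ledger.e_read_j + ledger.e_set_j + ledger.e_reset_j
        )
        model = EnergyModel()
        assert ledger.e_set_j == pytest.approx(ledger.n_set * model.e_set_j)
        assert ledger.e_reset_j == pytest.approx(ledger.n_reset * model.e_reset_j)


class TestSpikeTrain:
    def test_rejects_unsorted_times(self):
        with pytest.raises(InvalidInputError):
            SpikeTrain(np.array([2.0, 1.0]), np.array([0, 1]), "output", 5)

    def test_rejects_out_of_range_ids(self):
        with pytest.raises(InvalidInputError):
            SpikeTrain(np.array([1.0]), np.array([7]), "output", 5)

    def test_counts_partition_spikes(self):
        train = SpikeTrain(np.array([0.1, 0.2, 0.3]), np.array([1, 1, 4]), "output", 5)
        assert train.counts().tolist() == [0, 2, 0, 0, 1]
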