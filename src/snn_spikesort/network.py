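"""The 32 -> 5 spiking network with probabilistic STDP and winner-take-all.

Rectified filter-bank channels drive 32 input LIF neurons one-to-one; the
input layer is fully connected to 5 output LIF neurons through 32 x 5
excitatory compound-RRAM synapses.  Every input spike delivers
``weight * synaptic_gain`` to each output integrator (costing one read
pulse per device of every synapse touched).  Lateral inhibition across the
output layer enforces a winner-take-all: within a clock step at most one
output neuron - the one with the largest integration - may fire; the
others are reset and held inhibited for a short interval.

Learning is a simplified probabilistic STDP evaluated at each post-synaptic
spike: inputs that were active within the LTP window are potentiated by
setting each of their HRS devices with probability ``p_set``; all other
inputs are depressed by resetting each LRS device with probability
``p_reset``.  Per-device Bernoulli programming is what turns the binary
devices into the gradual multi-level potentiation/depression curves the
compound synapse is designed for.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .lif import LIFParams, LAYER1_DEFAULTS, LAYER2_DEFAULTS, run_lif_channel, _T_EPS_S
from .oxram import (
    CompoundSynapse,
    DeviceState,
    EnergyModel,
    EventLedger,
    SynapseConfig,
    program_device,
    random_synapse,
    synapse_weight,
)
from .encoder import SignalTrace

__all__ = [
    "STDPParams",
    "NetworkConfig",
    "SpikeTrain",
    "NetworkRun",
    "apply_stdp",
    "winner_take_all",
    "build_synapses",
    "weight_matrix",
    "run_network",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class STDPParams:
    """Set/reset probabilities and the LTP coincidence window.

    The reference system optimized these with a genetic algorithm but never
    published the optimum; the defaults here are calibration constants for
    the desk-scale (0.1x time) synthetic protocol: ``p_set = 0.3`` lets a
    selective neuron saturate within roughly ten of its events - the same
    fraction of a unit's presence as in the full-scale reference dynamics -
    and the LTP window covers a 1-2 ms spike plus its filter transients.
    """

    p_set: float = 0.3
    p_reset: float = 0.05
    t_ltp_s: float = 10e-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_set <= 1.0 or not 0.0 <= self.p_reset <= 1.0:
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if not self.t_ltp_s > 0:
            raise ConfigurationError("t_ltp_s must be > 0")


@dataclass(frozen=True)
class NetworkConfig:
    """Topology, gains and inhibition of the two-layer network.

    ``input_gain`` converts a rectified channel amplitude into the drive
    increment ``gain * amplitude * dt`` of its input neuron (units 1/s, so
    the drive is an amplitude-time integral and invariant to the clock
    rate).  ``synaptic_gain`` scales the weight delivered to an output
    integrator per input spike.  Both were tuned once, like the reference
    system's manually tuned front end, so that the input layer mirrors
    band energy and an untrained (weight ~ 0.5) output layer is excitable.
    """

    n_input: int = 32
    n_output: int = 5
    inhibition_s: float = 35e-3
    seed: int = 0
    input_gain: float = 16000.0
    synaptic_gain: float = 0.15

    def __post_init__(self) -> None:
        if self.n_input < 1:
            raise ConfigurationError("n_input must be >= 1")
        if self.n_output < 2:
            raise ConfigurationError("winner-take-all needs n_output >= 2")
        if self.inhibition_s < 0:
            raise ConfigurationError("inhibition_s must be >= 0")
        if self.input_gain <= 0 or self.synaptic_gain <= 0:
            raise ConfigurationError("gains must be > 0")


@dataclass
class SpikeTrain:
    """Timestamped spike events of one layer."""

    times_s: np.ndarray
    neuron_ids: np.ndarray
    layer: str
    n_neurons: int

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        if self.times_s.shape != self.neuron_ids.shape:
            raise InvalidInputError("times and neuron ids must align")
        if self.times_s.size and np.any(np.diff(self.times_s) < 0):
            raise InvalidInputError("spike times must be non-decreasing")
        if self.neuron_ids.size and (
            self.neuron_ids.min() < 0 or self.neuron_ids.max() >= self.n_neurons
        ):
            raise InvalidInputError("neuron id out of range for layer")

    def __len__(self) -> int:
        return self.times_s.size

    def counts(self) -> np.ndarray:
        """Total spikes per neuron."""
        return np.bincount(self.neuron_ids, minlength=self.n_neurons)

    def for_neuron(self, neuron_id: int) -> np.ndarray:
        return self.times_s[self.neuron_ids == neuron_id]


@dataclass
class NetworkRun:
    """Everything produced by one pass of the simulation loop."""

    input_spikes: SpikeTrain
    output_spikes: SpikeTrain
    ledger: EventLedger
    synapses: list[list[CompoundSynapse]]
    weights: np.ndarray
    duration_s: float

    def __iter__(self):
        # Allows tuple-style unpacking (input, output, ledger).
        return iter((self.input_spikes, self.output_spikes, self.ledger))


def winner_take_all(
    integrations: np.ndarray, eligible: np.ndarray, threshold: float
) -> int | None:
    """Index of the winning output neuron, or None.

    Among eligible neurons whose integration reached the threshold the one
    with the largest integration wins; ties go to the lowest id.
    """
    integrations = np.asarray(integrations, dtype=float)
    eligible = np.asarray(eligible, dtype=bool)
    candidates = eligible & (integrations >= threshold)
    if not np.any(candidates):
        return None
    masked = np.where(candidates, integrations, -np.inf)
    return int(np.argmax(masked))


def apply_stdp(
    post_neuron: int,
    t_post_s: float,
    last_pre_times: np.ndarray,
    params: STDPParams,
    synapses: list[CompoundSynapse],
    rng: np.random.Generator,
    ledger: EventLedger,
    model: EnergyModel,
) -> list[CompoundSynapse]:
    """Update the winner's 32 afferent synapses after a post-synaptic spike.

    For input ``i`` with pre-post delay ``dt = t_post - last_pre[i]``: if
    ``dt < t_ltp`` each HRS device of synapse i is set independently with
    probability ``p_set`` (gradual LTP); otherwise - including inputs that
    never spiked (``dt = inf``) - each LRS device is reset independently
    with probability ``p_reset`` (gradual LTD).  Every applied pulse is
    booked in the ledger.
    """
    for i, syn in enumerate(synapses):
        dt = t_post_s - last_pre_times[i]
        if dt < 0:
            raise InvalidInputError("pre-spike time after the post-spike")
        if dt < params.t_ltp_s:
            target, prob, source = DeviceState.LRS, params.p_set, DeviceState.HRS
        else:
            target, prob, source = DeviceState.HRS, params.p_reset, DeviceState.LRS
        if prob == 0.0:
            continue
        for dev in syn.devices:
            if dev.state is source and rng.random() < prob:
                program_device(dev, target, syn.dist, ledger, model, rng)
    return synapses


def build_synapses(
    n_input: int,
    n_output: int,
    syn_cfg: SynapseConfig,
    rng: np.random.Generator,
) -> list[list[CompoundSynapse]]:
    """Fresh fully connected synapse grid ``[input][output]``."""
    return [
        [
            random_synapse(syn_cfg.n_devices, syn_cfg.distribution, rng, syn_cfg.p_init_lrs)
            for _ in range(n_output)
        ]
        for _ in range(n_input)
    ]


def weight_matrix(synapses: list[list[CompoundSynapse]]) -> np.ndarray:
    """Current normalized weights as an (n_input, n_output) array."""
    return np.array([[synapse_weight(s) for s in row] for row in synapses])


def _conductance_matrix(synapses: list[list[CompoundSynapse]]) -> np.ndarray:
    return np.array([[s.conductance_sum_s() for s in row] for row in synapses])


def run_network(
    channels: list[SignalTrace],
    config: NetworkConfig | None = None,
    lif1: LIFParams = LAYER1_DEFAULTS,
    lif2: LIFParams = LAYER2_DEFAULTS,
    stdp: STDPParams | None = None,
    synapses: list[list[CompoundSynapse]] | None = None,
    synapse_config: SynapseConfig | None = None,
    energy_model: EnergyModel | None = None,
    learning: bool = True,
) -> NetworkRun:
    """Clock-driven simulation of the full two-layer network.

    Per clock step (one input sample): (1) the input LIF neurons integrate
    the rectified drive; (2) every input spike delivers
    ``weight * synaptic_gain`` to all eligible output integrators and costs
    one read pulse per device of each of its ``n_output`` synapses;
    (3) the output integrators leak continuously; (4) if any eligible
    output reaches threshold, the winner-take-all fires exactly one neuron
    and resets/inhibits the rest; (5) with learning enabled, STDP updates
    the winner's afferents.  Steps without input spikes are skipped using
    the exact analytic leak, which leaves the dynamics bit-identical to
    the naive step-by-step loop because output integrations can only cross
    threshold when input arrives.
    """
    config = config or NetworkConfig()
    stdp = stdp or STDPParams()
    synapse_config = synapse_config or SynapseConfig()
    model = energy_model or synapse_config.energy

    if len(channels) != config.n_input:
        raise InvalidInputError(
            f"expected {config.n_input} channels, got {len(channels)}"
        )
    rate = channels[0].rate_hz
    n_samp = len(channels[0])
    t0 = channels[0].t0_s
    for ch in channels:
        if ch.rate_hz != rate or len(ch) != n_samp:
            raise InvalidInputError("all channels must share length and rate")
    dt = 1.0 / rate

    seq = np.random.SeedSequence(config.seed)
    init_ss, stdp_ss = seq.spawn(2)
    if synapses is None:
        synapses = build_synapses(
            config.n_input, config.n_output, synapse_config, np.random.default_rng(init_ss)
        )
    rng = np.random.default_rng(stdp_ss)
    ledger = EventLedger()
    n_out = config.n_output
    n_dev = synapses[0][0].n

    # ---- layer 1: compiled per-channel LIF over the whole trace ----
    in_steps: list[np.ndarray] = []
    for ch in channels:
        drive = config.input_gain * ch.samples * dt
        gap_times = run_lif_channel(drive, lif1, dt, t0_s=t0)
        in_steps.append(np.round((gap_times - t0) / dt).astype(np.int64) - 1)
    all_steps = np.concatenate(in_steps) if in_steps else np.empty(0, np.int64)
    all_chan = np.concatenate(
        [np.full(s.size, i, dtype=np.int64) for i, s in enumerate(in_steps)]
    ) if in_steps else np.empty(0, np.int64)
    order = np.lexsort((all_chan, all_steps))
    all_steps, all_chan = all_steps[order], all_chan[order]
    input_times = t0 + (all_steps + 1) * dt
    input_train = SpikeTrain(input_times, all_chan, "input", config.n_input)

    # ---- layer 2: event-driven over steps that carry input spikes ----
    W = weight_matrix(synapses)
    G = _conductance_matrix(synapses)
    integ = np.zeros(n_out)
    refrac_until = np.full(n_out, -np.inf)
    inhib_until = np.full(n_out, -np.inf)
    last_pre = np.full(config.n_input, -np.inf)
    decay2 = lambda delta: math.exp(-delta / lif2.t_leak_s)  # noqa: E731
    last_t = t0
    out_times: list[float] = []
    out_ids: list[int] = []

    group_bounds = np.flatnonzero(np.diff(all_steps, prepend=-1))
    for gi, start in enumerate(group_bounds):
        stop = group_bounds[gi + 1] if gi + 1 < group_bounds.size else all_steps.size
        t = t0 + (all_steps[start] + 1) * dt
        fired = all_chan[start:stop]
        last_pre[fired] = t

        # weight sensing: one read pulse per device of every synapse touched
        ledger.record_read(float(G[fired, :].sum()), fired.size * n_out * n_dev, model)

        integ *= decay2(t - last_t)
        last_t = t
        eligible = (t > refrac_until + _T_EPS_S) & (t > inhib_until + _T_EPS_S)
        contrib = config.synaptic_gain * W[fired, :].sum(axis=0)
        integ[eligible] += contrib[eligible]

        winner = winner_take_all(integ, eligible, lif2.i_thres)
        if winner is not None:
            out_times.append(t)
            out_ids.append(winner)
            refrac_until[winner] = t + lif2.t_refractory_s
            others = np.arange(n_out) != winner
            inhib_until[others] = np.maximum(inhib_until[others], t + config.inhibition_s)
            integ[:] = 0.0
            if learning:
                column = [synapses[i][winner] for i in range(config.n_input)]
                apply_stdp(winner, t, last_pre, stdp, column, rng, ledger, model)
                for i in range(config.n_input):
                    W[i, winner] = synapse_weight(synapses[i][winner])
                    G[i, winner] = synapses[i][winner].conductance_sum_s()

    output_train = SpikeTrain(
        np.array(out_times), np.array(out_ids, dtype=np.int64), "output", n_out
    )
    duration = n_samp * dt
    logger.info(
        "run_network: %d input spikes, %d output spikes over %.1f s",
        len(input_train), len(output_train), duration,
    )
    return NetworkRun(input_train, output_train, ledger, synapses, W, duration)
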