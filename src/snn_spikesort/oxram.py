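"""Behavioral model of compound binary-RRAM (OxRAM) synapses.

One synaptic weight is realized by ``n`` oxide-RRAM devices wired in
parallel.  Operated at a 30 uA set-current compliance each device switches
abruptly between exactly two non-volatile states, a low-resistance state
(LRS) and a high-resistance state (HRS), separated by about one decade in
median resistance.  Cycle-to-cycle variability is captured by re-sampling
the device resistance from a log-normal distribution of its new state at
every programming pulse.  Summing the parallel conductances yields a
synapse with approximately n + 1 distinct weight levels (exactly n + 1
when the distributions have zero spread).

Every physical pulse is accounted for: an :class:`EventLedger` counts
read/set/reset events and accumulates their energies E = V * I * t, which
is what makes the nanowatt-scale power and ten-year endurance projections
of the whole network computable from a simulation run.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "DeviceState",
    "ResistanceDistribution",
    "OxRAMDevice",
    "CompoundSynapse",
    "EnergyModel",
    "EventLedger",
    "program_device",
    "synapse_weight",
    "read_synapse",
    "extrapolate_endurance",
    "random_synapse",
    "SynapseConfig",
    "SECONDS_PER_10_YEARS",
]

SECONDS_PER_10_YEARS = 10 * 365 * 24 * 3600.0  # 3.1536e8 s


class DeviceState(enum.Enum):
    """The two non-volatile resistance states of a binary device."""

    LRS = "LRS"
    HRS = "HRS"


@dataclass(frozen=True)
class ResistanceDistribution:
    """Log-normal resistance statistics of the two device states.

    Defaults place the medians one decade apart (25 kOhm vs 250 kOhm) with
    a larger relative spread in the HRS, reflecting the empirical trend of
    resistance variability growing with the mean resistance.  These are
    calibration constants of the behavioral model, not universal device
    figures.
    """

    median_lrs_ohm: float = 25e3
    sigma_log_lrs: float = 0.3
    median_hrs_ohm: float = 250e3
    sigma_log_hrs: float = 0.5

    def __post_init__(self) -> None:
        if not self.median_hrs_ohm > self.median_lrs_ohm:
            raise ConfigurationError("median HRS resistance must exceed median LRS")
        if self.sigma_log_lrs < 0 or self.sigma_log_hrs < 0:
            raise ConfigurationError("log-normal spreads must be >= 0")
        if min(self.median_lrs_ohm, self.median_hrs_ohm) <= 0:
            raise ConfigurationError("median resistances must be > 0")

    def sample_resistance(self, state: DeviceState, rng: np.random.Generator) -> float:
        if state is DeviceState.LRS:
            med, sig = self.median_lrs_ohm, self.sigma_log_lrs
        else:
            med, sig = self.median_hrs_ohm, self.sigma_log_hrs
        if sig == 0.0:
            return med
        return med * math.exp(sig * rng.standard_normal())


@dataclass
class OxRAMDevice:
    """One binary device: its state and its currently sampled conductance."""

    state: DeviceState
    conductance_s: float

    def __post_init__(self) -> None:
        if not self.conductance_s > 0:
            raise ConfigurationError("conductance must be > 0")


@dataclass(frozen=True)
class EnergyModel:
    """Per-pulse electrical conditions for set, reset and read.

    Defaults are the 30 uA-compliance pulse conditions of the behavioral
    model: 2.5 V / 30 uA / 1 us set (75 pJ), 1.5 V magnitude / 30 uA /
    1 us reset (45 pJ), and 0.1 V / 1 us reads whose current is set by the
    device resistance.
    """

    v_set_v: float = 2.5
    i_set_a: float = 30e-6
    t_set_s: float = 1e-6
    v_reset_v: float = 1.5
    i_reset_a: float = 30e-6
    t_reset_s: float = 1e-6
    v_read_v: float = 0.1
    t_read_s: float = 1e-6

    def __post_init__(self) -> None:
        for name in (
            "v_set_v", "i_set_a", "t_set_s",
            "v_reset_v", "i_reset_a", "t_reset_s",
            "v_read_v", "t_read_s",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be a positive magnitude")

    @property
    def e_set_j(self) -> float:
        """Energy of one set pulse, V_set * I_set * t_set."""
        return self.v_set_v * self.i_set_a * self.t_set_s

    @property
    def e_reset_j(self) -> float:
        """Energy of one reset pulse, |V_reset| * I_reset * t_reset."""
        return self.v_reset_v * self.i_reset_a * self.t_reset_s

    def e_read_j(self, conductance_s: float) -> float:
        """Energy of one read pulse at a given device conductance.

        The read current is determined by the device resistance,
        I = V_read / R, so E = V_read^2 * G * t_read.
        """
        return self.v_read_v**2 * conductance_s * self.t_read_s


@dataclass
class EventLedger:
    """Monotone counters of programming/read events and their energies."""

    n_read: int = 0
    n_set: int = 0
    n_reset: int = 0
    e_read_j: float = 0.0
    e_set_j: float = 0.0
    e_reset_j: float = 0.0

    def record_set(self, model: EnergyModel, count: int = 1) -> None:
        self.n_set += count
        self.e_set_j += count * model.e_set_j

    def record_reset(self, model: EnergyModel, count: int = 1) -> None:
        self.n_reset += count
        self.e_reset_j += count * model.e_reset_j

    def record_read(
        self, conductance_sum_s: float, n_device_events: int, model: EnergyModel
    ) -> None:
        """Record read pulses across devices whose conductances sum as given."""
        self.n_read += n_device_events
        self.e_read_j += model.e_read_j(conductance_sum_s)

    @property
    def e_total_j(self) -> float:
        """Total synaptic energy, the sum over modes of E_mode * N_mode."""
        return self.e_read_j + self.e_set_j + self.e_reset_j


@dataclass
class CompoundSynapse:
    """``n`` parallel binary devices forming one multi-level weight."""

    devices: list[OxRAMDevice]
    dist: ResistanceDistribution

    def __post_init__(self) -> None:
        if len(self.devices) < 1:
            raise ConfigurationError("a synapse needs at least one device")

    @property
    def n(self) -> int:
        return len(self.devices)

    def conductance_sum_s(self) -> float:
        return sum(d.conductance_s for d in self.devices)

    @property
    def g_min_s(self) -> float:
        """Expected all-HRS parallel conductance (distribution medians)."""
        return self.n / self.dist.median_hrs_ohm

    @property
    def g_max_s(self) -> float:
        """Expected all-LRS parallel conductance (distribution medians)."""
        return self.n / self.dist.median_lrs_ohm


def program_device(
    device: OxRAMDevice,
    target: DeviceState,
    dist: ResistanceDistribution,
    ledger: EventLedger,
    model: EnergyModel,
    rng: np.random.Generator,
) -> OxRAMDevice:
    """Apply one set or reset pulse to a device.

    The device assumes the target state and its conductance is re-sampled
    from that state's distribution (cycle-to-cycle variability).  The pulse
    is booked in the ledger even when the device was already in the target
    state: a physical pulse is a physical pulse.
    """
    device.state = target
    device.conductance_s = 1.0 / dist.sample_resistance(target, rng)
    if target is DeviceState.LRS:
        ledger.record_set(model)
    else:
        ledger.record_reset(model)
    return device


def synapse_weight(syn: CompoundSynapse) -> float:
    """Normalized weight in [0, 1] from the summed parallel conductance.

    ``(G_total - G_min) / (G_max - G_min)`` with G_min/G_max the expected
    all-HRS / all-LRS sums at the distribution medians, clipped to [0, 1].
    With zero spread and k of n devices in LRS this is exactly k/n.
    """
    g_min, g_max = syn.g_min_s, syn.g_max_s
    if g_max <= g_min:
        raise ConfigurationError("degenerate resistance window (G_max <= G_min)")
    w = (syn.conductance_sum_s() - g_min) / (g_max - g_min)
    return min(1.0, max(0.0, w))


def read_synapse(
    syn: CompoundSynapse, model: EnergyModel, ledger: EventLedger
) -> float:
    """Sense one synapse: one read pulse per device, returning the weight."""
    ledger.record_read(syn.conductance_sum_s(), syn.n, model)
    return synapse_weight(syn)


def random_synapse(
    n_devices: int,
    dist: ResistanceDistribution,
    rng: np.random.Generator,
    p_lrs: float = 0.5,
) -> CompoundSynapse:
    """A fresh synapse with each device independently LRS with ``p_lrs``.

    The half/half default gives random initial weights with mean ~0.5, so
    an untrained network responds (and therefore explores) before any
    learning has taken place.
    """
    devices = []
    for _ in range(n_devices):
        state = DeviceState.LRS if rng.random() < p_lrs else DeviceState.HRS
        devices.append(
            OxRAMDevice(state, 1.0 / dist.sample_resistance(state, rng))
        )
    return CompoundSynapse(devices, dist)


def extrapolate_endurance(
    ledger: EventLedger, n_devices: int, duration_s: float, horizon_s: float
) -> tuple[float, float]:
    """Mean per-device set/reset counts scaled to a longer horizon.

    Returns ``(sets_per_device, resets_per_device)`` after scaling the
    observed per-device means by ``horizon_s / duration_s``; with the
    horizon equal to the observed duration this is the identity.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if n_devices <= 0:
        raise ValueError("n_devices must be > 0")
    scale = horizon_s / duration_s
    return (
        ledger.n_set / n_devices * scale,
        ledger.n_reset / n_devices * scale,
    )


@dataclass(frozen=True)
class SynapseConfig:
    """Bundled synapse settings: array size, statistics, pulse energetics."""

    n_devices: int = 10
    p_init_lrs: float = 0.5
    distribution: ResistanceDistribution = field(default_factory=ResistanceDistribution)
    energy: EnergyModel = field(default_factory=EnergyModel)

    def __post_init__(self) -> None:
        if self.n_devices < 1:
            raise ConfigurationError("n_devices must be >= 1")
        if not 0.0 <= self.p_init_lrs <= 1.0:
            raise ConfigurationError("p_init_lrs must be in [0, 1]")
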