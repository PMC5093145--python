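"""Spike-sorting performance metrics and system statistics.

A ground-truth event counts as recognized when the output neuron assigned
to that unit spikes within the causal match window (t, t + 20 ms] after
the event.  The recognition rate is reported per 10 s interval as the
fraction of that interval's truth events recognized, and averaged over the
intervals that contain events - so the mean effectively starts at a unit's
first occurrence.  Unit-to-neuron assignment is done post hoc, as with a
real intracellular reference: greedily, injectively, maximizing matched
events.

``system_report`` turns the event ledger of a run into the hardware-facing
summary: per-event energies E = V * I * t, the total synaptic energy
``sum_mode E_mode * N_mode``, the mean power E/t, per-device programming
counts, and their extrapolation to a ten-year implant lifetime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoder import SignalTrace
from .errors import InvalidInputError
from .network import SpikeTrain
from .oxram import EnergyModel, EventLedger, SECONDS_PER_10_YEARS, extrapolate_endurance
from .synth import GroundTruth

__all__ = [
    "EvaluationConfig",
    "RecognitionReport",
    "SystemReport",
    "match_counts",
    "assign_neurons",
    "recognition_rate",
    "activity_histogram",
    "system_report",
    "data_reduction",
]

E_NEURON_SPIKE_J = 2e-12  # analog CMOS neuron, energy per emitted spike


@dataclass(frozen=True)
class EvaluationConfig:
    """Match window after a truth event and the activity reporting bin."""

    match_window_s: float = 0.020
    bin_s: float = 10.0

    def __post_init__(self) -> None:
        if self.match_window_s <= 0 or self.bin_s <= 0:
            raise InvalidInputError("match_window_s and bin_s must be > 0")


def _matched_mask(
    truth_times: np.ndarray, spike_times: np.ndarray, window_s: float
) -> np.ndarray:
    """For each truth event, is there a spike in (t, t + window]?"""
    truth_times = np.asarray(truth_times, dtype=float)
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    idx = np.searchsorted(spike_times, truth_times, side="right")
    ok = idx < spike_times.size
    mask = np.zeros(truth_times.size, dtype=bool)
    mask[ok] = spike_times[idx[ok]] <= truth_times[ok] + window_s
    return mask


def match_counts(
    output: SpikeTrain, truth: GroundTruth, config: EvaluationConfig
) -> pd.DataFrame:
    """Matched-event counts for every (unit, neuron) pair."""
    rows = {}
    for unit, times in truth.events.items():
        rows[unit] = [
            int(_matched_mask(times, output.for_neuron(j), config.match_window_s).sum())
            for j in range(output.n_neurons)
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(output.n_neurons))


def assign_neurons(
    output: SpikeTrain, truth: GroundTruth, config: EvaluationConfig | None = None
) -> dict[str, int]:
    """Greedy injective unit -> output-neuron assignment.

    Pairs are taken in decreasing order of matched-event count (ties to the
    lower neuron id, then unit order); a pair is accepted only if both its
    unit and its neuron are still free and the count is positive.  With no
    output spikes at all an empty assignment is returned with a warning.
    """
    config = config or EvaluationConfig()
    if len(output) == 0:
        warnings.warn("no output spikes: returning an empty assignment", stacklevel=2)
        return {}
    counts = match_counts(output, truth, config)
    pairs = [
        (int(counts.loc[unit, j]), ui, j, unit)
        for ui, unit in enumerate(counts.index)
        for j in counts.columns
    ]
    pairs.sort(key=lambda p: (-p[0], p[2], p[1]))
    assignment: dict[str, int] = {}
    used: set[int] = set()
    for count, _ui, j, unit in pairs:
        if count > 0 and unit not in assignment and j not in used:
            assignment[unit] = j
            used.add(j)
    return assignment


@dataclass
class RecognitionReport:
    """Per-bin and mean recognition of one unit by its assigned neuron."""

    unit: str
    neuron: int
    bin_edges_s: np.ndarray
    per_bin: np.ndarray  # NaN for bins without truth events
    mean: float


def recognition_rate(
    output: SpikeTrain,
    truth_times: np.ndarray,
    neuron_id: int,
    config: EvaluationConfig | None = None,
    duration_s: float | None = None,
    unit: str = "",
) -> RecognitionReport:
    """Recognition of one unit's events by one neuron, binned in time.

    Each bin's rate is (truth events followed by an assigned-neuron spike
    within the window) / (truth events in the bin); bins without truth
    events carry NaN and are excluded from the unweighted mean, so the
    mean runs from the unit's first occurrence.
    """
    config = config or EvaluationConfig()
    truth_times = np.asarray(truth_times, dtype=float)
    spikes = output.for_neuron(neuron_id)
    end = duration_s
    if end is None:
        candidates = [config.bin_s]
        if truth_times.size:
            candidates.append(float(truth_times.max()) + config.match_window_s)
        if spikes.size:
            candidates.append(float(spikes.max()))
        end = max(candidates)
    edges = np.arange(0.0, end + config.bin_s, config.bin_s)
    if edges[-1] < end:
        edges = np.append(edges, edges[-1] + config.bin_s)
    matched = _matched_mask(truth_times, spikes, config.match_window_s)
    which = np.digitize(truth_times, edges) - 1
    n_bins = edges.size - 1
    per_bin = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if np.any(sel):
            per_bin[b] = matched[sel].mean()
    mean = float(np.nanmean(per_bin)) if np.any(~np.isnan(per_bin)) else float("nan")
    return RecognitionReport(unit, neuron_id, edges, per_bin, mean)


def activity_histogram(
    train: SpikeTrain, bin_s: float = 10.0, duration_s: float | None = None
) -> np.ndarray:
    """Spike counts per neuron per time bin, shape (n_neurons, n_bins)."""
    if bin_s <= 0:
        raise InvalidInputError("bin_s must be > 0")
    end = duration_s
    if end is None:
        end = float(train.times_s.max()) + bin_s if len(train) else bin_s
    n_bins = max(1, int(np.ceil(end / bin_s)))
    hist = np.zeros((train.n_neurons, n_bins), dtype=np.int64)
    if len(train):
        b = np.minimum((train.times_s / bin_s).astype(np.int64), n_bins - 1)
        np.add.at(hist, (train.neuron_ids, b), 1)
    return hist


@dataclass
class SystemReport:
    """Event statistics and energetics of one run, table-style."""

    duration_s: float
    n_synapses: int | None
    n_devices: int
    n_read: int
    n_set: int
    n_reset: int
    e_set_event_j: float
    e_reset_event_j: float
    e_read_event_j: float  # mean over actual reads; 0 when there were none
    e_total_j: float
    power_w: float
    sets_per_device: float
    resets_per_device: float
    sets_per_device_10y: float
    resets_per_device_10y: float
    neuron_spike_count: int | None = None
    e_neurons_j: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Input signal duration (s)", self.duration_s),
            ("Read events", self.n_read),
            ("Set events", self.n_set),
            ("Reset events", self.n_reset),
            ("Set event energy (J)", self.e_set_event_j),
            ("Reset event energy (J)", self.e_reset_event_j),
            ("Mean read event energy (J)", self.e_read_event_j),
            ("Synaptic energy dissipation (J)", self.e_total_j),
            ("Synaptic power, E/t (W)", self.power_w),
            ("Mean Set events per device", self.sets_per_device),
            ("Mean Reset events per device", self.resets_per_device),
            ("Set events per device over 10 y", self.sets_per_device_10y),
            ("Reset events per device over 10 y", self.resets_per_device_10y),
        ]
        if self.n_synapses is not None:
            rows.insert(1, ("Number of synapses", self.n_synapses))
        if self.e_neurons_j is not None:
            rows.append(("Output neuron spikes", self.neuron_spike_count))
            rows.append(("Neuron energy (J)", self.e_neurons_j))
        return pd.DataFrame(rows, columns=["quantity", "value"])


def system_report(
    ledger: EventLedger,
    model: EnergyModel,
    duration_s: float,
    n_devices: int,
    n_synapses: int | None = None,
    neuron_spike_count: int | None = None,
    e_neuron_spike_j: float = E_NEURON_SPIKE_J,
) -> SystemReport:
    """Summarize a run's ledger into energies, power and endurance.

    The total synaptic energy is the ledger's accumulated
    ``sum_mode E_mode * N_mode``; the power is that total divided by the
    signal duration.  The optional neuron term adds
    ``spike count x energy-per-spike`` for an analog neuron implementation
    (2 pJ/spike by default) without folding it into the synaptic totals.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    sets_pd, resets_pd = extrapolate_endurance(ledger, n_devices, duration_s, duration_s)
    sets_10y, resets_10y = extrapolate_endurance(
        ledger, n_devices, duration_s, SECONDS_PER_10_YEARS
    )
    return SystemReport(
        duration_s=duration_s,
        n_synapses=n_synapses,
        n_devices=n_devices,
        n_read=ledger.n_read,
        n_set=ledger.n_set,
        n_reset=ledger.n_reset,
        e_set_event_j=model.e_set_j,
        e_reset_event_j=model.e_reset_j,
        e_read_event_j=ledger.e_read_j / ledger.n_read if ledger.n_read else 0.0,
        e_total_j=ledger.e_total_j,
        power_w=ledger.e_total_j / duration_s,
        sets_per_device=sets_pd,
        resets_per_device=resets_pd,
        sets_per_device_10y=sets_10y,
        resets_per_device_10y=resets_10y,
        neuron_spike_count=neuron_spike_count,
        e_neurons_j=(
            neuron_spike_count * e_neuron_spike_j
            if neuron_spike_count is not None
            else None
        ),
    )


def data_reduction(trace: SignalTrace, output: SpikeTrain) -> float:
    """Input samples per output event; ``inf`` when no output fired.

    Orders of magnitude around 1000 are typical: a 20 kHz recording reduced
    to a few output events per second.
    """
    if len(output) == 0:
        return float("inf")
    return len(trace) / len(output)
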