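"""End-to-end composition: trace -> encoder -> network -> evaluation.

These helpers wire the modules together exactly the way the command-line
interface and the tests use them, so a full experiment is:

>>> cfg = RunConfig()
>>> trace, truth = generate(cfg.synth.to_synth_config())
>>> run = sort_trace(trace, cfg)
>>> summary = evaluate_run(run, truth, cfg)
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .encoder import SignalTrace, encode, normalize_trace
from .evaluation import (
    RecognitionReport,
    activity_histogram,
    assign_neurons,
    data_reduction,
    recognition_rate,
    system_report,
    SystemReport,
)
from .lif import LIFParams
from .network import NetworkRun, STDPParams, run_network
from .synth import GroundTruth, generate

__all__ = ["sort_trace", "evaluate_run", "EvaluationSummary", "make_fitness"]

logger = logging.getLogger(__name__)


def sort_trace(trace: SignalTrace, cfg: RunConfig, learning: bool = True) -> NetworkRun:
    """Normalize, encode and run the spiking network on one trace."""
    norm = normalize_trace(trace)
    channels = encode(norm, cfg.filterbank)
    run = run_network(
        channels,
        config=cfg.network,
        lif1=cfg.layer1,
        lif2=cfg.layer2,
        stdp=cfg.stdp,
        synapse_config=cfg.synapse,
        learning=learning,
    )
    hist = activity_histogram(run.output_spikes, cfg.evaluation.bin_s, run.duration_s)
    for b in range(hist.shape[1]):
        logger.info(
            "activity %5.0f-%5.0f s: %s",
            b * cfg.evaluation.bin_s,
            (b + 1) * cfg.evaluation.bin_s,
            hist[:, b].tolist(),
        )
    return run


@dataclass
class EvaluationSummary:
    """Assignment, recognition and system statistics of one run."""

    assignment: dict[str, int]
    recognition: dict[str, RecognitionReport]
    mean_recognition: dict[str, float]
    output_counts: np.ndarray
    system: SystemReport
    data_reduction: float


def evaluate_run(
    run: NetworkRun,
    truth: GroundTruth,
    cfg: RunConfig,
    trace: SignalTrace | None = None,
) -> EvaluationSummary:
    """Assign output neurons to units and score the run."""
    assignment = assign_neurons(run.output_spikes, truth, cfg.evaluation)
    recognition = {
        unit: recognition_rate(
            run.output_spikes,
            truth[unit],
            neuron,
            cfg.evaluation,
            duration_s=run.duration_s,
            unit=unit,
        )
        for unit, neuron in assignment.items()
    }
    n_synapses = cfg.network.n_input * cfg.network.n_output
    report = system_report(
        run.ledger,
        cfg.synapse.energy,
        run.duration_s,
        n_devices=n_synapses * cfg.synapse.n_devices,
        n_synapses=n_synapses,
        neuron_spike_count=len(run.output_spikes) + len(run.input_spikes),
    )
    reduction = data_reduction(trace, run.output_spikes) if trace is not None else float("nan")
    return EvaluationSummary(
        assignment=assignment,
        recognition=recognition,
        mean_recognition={u: r.mean for u, r in recognition.items()},
        output_counts=run.output_spikes.counts(),
        system=report,
        data_reduction=reduction,
    )


def make_fitness(cfg: RunConfig, scale: float | None = None):
    """Fitness for the genetic optimizer: mean recognition on fixed data.

    The synthetic dataset is generated once (fixed seed from the config) so
    the returned callable is deterministic in its parameters.  The flat
    parameter names are the output-layer LIF fields (``i_thres``,
    ``t_leak_s``, ``t_refractory_s``) and the STDP fields (``p_set``,
    ``p_reset``, ``t_ltp_s``); probabilities are clipped into [0, 1].
    """
    synth_cfg = cfg.synth.to_synth_config()
    if scale is not None:
        section = dataclasses.replace(cfg.synth, scale=scale)
        synth_cfg = section.to_synth_config()
    trace, truth = generate(synth_cfg)

    def fitness(params: dict[str, float]) -> float:
        layer2 = LIFParams(
            i_thres=params.get("i_thres", cfg.layer2.i_thres),
            t_leak_s=params.get("t_leak_s", cfg.layer2.t_leak_s),
            t_refractory_s=params.get("t_refractory_s", cfg.layer2.t_refractory_s),
        )
        stdp = STDPParams(
            p_set=min(1.0, params.get("p_set", cfg.stdp.p_set)),
            p_reset=min(1.0, params.get("p_reset", cfg.stdp.p_reset)),
            t_ltp_s=params.get("t_ltp_s", cfg.stdp.t_ltp_s),
        )
        trial = dataclasses.replace(cfg, layer2=layer2, stdp=stdp)
        run = sort_trace(trace, trial)
        summary = evaluate_run(run, truth, trial)
        if not summary.mean_recognition:
            return 0.0
        return float(np.mean(list(summary.mean_recognition.values())))

    return fitness
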