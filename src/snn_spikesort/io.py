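"""Plain-text and WAV readers/writers for traces and event lists.

Trace text format: comment header lines ``# key=value`` carrying
``rate_hz`` (required) and ``t0_s`` (optional), then one sample per line.
Event files are tab-separated ``time_s<TAB>id`` rows sorted by time, with
a single header line.  WAV files carry the sampling rate in their header;
integer PCM is rescaled to [-1, 1] on read.
"""

from __future__ import annotations

import os

import numpy as np
from scipy.io import wavfile

from .encoder import SignalTrace
from .errors import InvalidInputError

__all__ = ["read_trace", "write_trace", "read_events", "write_events"]


def _format_of(path: str, format: str | None) -> str:
    if format is not None:
        return format
    ext = os.path.splitext(path)[1].lower()
    return "wav" if ext == ".wav" else "txt"


def write_trace(trace: SignalTrace, path: str, format: str | None = None) -> None:
    fmt = _format_of(path, format)
    if fmt == "wav":
        wavfile.write(path, int(round(trace.rate_hz)), trace.samples.astype(np.float32))
        return
    if fmt == "txt":
        with open(path, "w") as fh:
            fh.write(f"# rate_hz={trace.rate_hz!r}\n")
            fh.write(f"# t0_s={trace.t0_s!r}\n")
            for x in trace.samples:
                fh.write(f"{float(x)!r}\n")
        return
    raise InvalidInputError(f"unknown trace format {fmt!r}")


def read_trace(path: str, format: str | None = None) -> SignalTrace:
    fmt = _format_of(path, format)
    if fmt == "wav":
        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim > 1:
            raise InvalidInputError("multi-channel WAV traces are not supported")
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
        return SignalTrace(data.astype(np.float64), float(rate))
    if fmt != "txt":
        raise InvalidInputError(f"unknown trace format {fmt!r}")
    meta: dict[str, float] = {}
    samples: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    try:
                        meta[key.strip()] = float(value)
                    except ValueError as exc:
                        raise InvalidInputError(
                            f"{path}:{lineno}: bad header value {value!r}"
                        ) from exc
                continue
            try:
                samples.append(float(line))
            except ValueError as exc:
                raise InvalidInputError(
                    f"{path}:{lineno}: malformed sample {line!r}"
                ) from exc
    if "rate_hz" not in meta:
        raise InvalidInputError(f"{path}: missing '# rate_hz=' header")
    return SignalTrace(np.asarray(samples), meta["rate_hz"], meta.get("t0_s", 0.0))


def write_events(times_s: np.ndarray, ids, path: str, id_column: str = "neuron_id") -> None:
    times_s = np.asarray(times_s, dtype=float)
    ids = list(ids)
    if len(ids) != times_s.size:
        raise InvalidInputError("times and ids must align")
    with open(path, "w") as fh:
        fh.write(f"time_s\t{id_column}\n")
        for t, i in zip(times_s, ids):
            fh.write(f"{float(t)!r}\t{i}\n")


def read_events(path: str) -> tuple[np.ndarray, list[str]]:
    """Read an event file; returns (times, ids) with ids kept as strings."""
    times: list[float] = []
    ids: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if lineno == 1 and line.lower().startswith("time_s"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InvalidInputError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                t = float(parts[0])
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: malformed time {parts[0]!r}") from exc
            if times and t < times[-1]:
                raise InvalidInputError(f"{path}:{lineno}: event times must be sorted")
            times.append(t)
            ids.append(parts[1])
    return np.asarray(times), ids
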