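"""Delimited-text output for traces and weight matrices.

Traces are comma-separated with a header row (``time`` followed by
``cell/compartment/variable`` identifiers) and one row per recorded step.
Numbers are written with Python's shortest round-trippable ``repr``, so a
read-back equals the in-memory trace exactly.
"""

from __future__ import annotations

import numpy as np

from .model import EhhError
from .simulate import Trace

__all__ = ["write_trace", "read_trace", "write_weights", "read_weights"]


def write_trace(trace: Trace, destination) -> None:
    """Write a trace as delimited text (header + one row per record)."""
    if trace.times.size == 0:
        raise EhhError("refusing to write an empty trace")

    def _write(fh):
        fh.write(",".join(["time"] + list(trace.names)) + "\n")
        for t, row in zip(trace.times, trace.values):
            fh.write(",".join(repr(float(x)) for x in [t, *row]) + "\n")

    if hasattr(destination, "write"):
        _write(destination)
    else:
        with open(destination, "w") as fh:
            _write(fh)


def read_trace(source) -> Trace:
    """Read a trace previously written by :func:`write_trace`."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    header = lines[0].split(",")
    rows = [[float(x) for x in line.split(",")] for line in lines[1:] if line]
    data = np.array(rows)
    return Trace(times=data[:, 0], names=header[1:], values=data[:, 1:])


def write_weights(weights, destination) -> None:
    """Write a weight matrix as tab-delimited text, one row per line."""
    w = np.asarray(weights, dtype=float)
    with open(destination, "w") as fh:
        for row in w:
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_weights(source) -> np.ndarray:
    """Read a tab- or whitespace-delimited weight matrix."""
    with open(source) as fh:
        rows = [[float(x) for x in line.split()] for line in fh if line.strip()]
    return np.array(rows)
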