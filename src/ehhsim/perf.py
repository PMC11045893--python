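"""Analytical performance model of the dataflow-hardware implementation.

The hardware maps the cell-dynamics loop and the gap-junction loop onto
statically scheduled, deeply pipelined kernels.  Their behaviour is
deterministic, so required DRAM/ring throughputs, on-chip memory-block
counts, tick (clock-cycle) counts and execution-time bottlenecks can be
predicted in closed form.

Conventions: frequencies in Hz (except the explicit MHz helpers),
bandwidths in bytes/s, data sizes in bytes, tick counts are integral —
ceilings are applied wherever a count is divided, so exact-division inputs
reproduce the plain formula values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .model import InvalidParameterError

__all__ = [
    "PerfConfig",
    "hhmc_dram_throughput",
    "gap_dram_throughput",
    "min_freq_exceeding_dram",
    "mem_blocks",
    "stage_ticks",
    "maxring_throughput",
    "hhmcg_ticks",
    "cell_ticks",
    "gap_ticks_monolithic",
    "exec_time",
]


@dataclass(frozen=True)
class PerfConfig:
    """Hardware-model parameters.

    Defaults follow the modelled accelerator platform: 15 GB/s on-board
    DRAM per DIMM, 5 GB/s ring interconnect, 4-byte (single-precision)
    values.  The gap-kernel pipeline depth ``d_gap`` and the cell-kernel
    inner-loop buffer ``size_buffer`` are design placeholders exposed here.
    """

    uf_cell: int = 1
    uf_gap: int = 16
    f: float = 170e6
    bw_dram: float = 15e9
    bw_maxring: float = 5e9
    d_gap: int = 90
    size_buffer: int = 16
    bytes_per_value: int = 4
    n_dfes: int = 1
    n_gapkernels_per_dfe: int = 1
    mem_width: int = 36
    mem_depth: int = 1024
    mem_ports: int = 2

    def __post_init__(self):
        for name in ("uf_cell", "uf_gap", "d_gap", "bytes_per_value",
                     "n_dfes", "n_gapkernels_per_dfe", "mem_width",
                     "mem_depth", "mem_ports"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be a positive integer")
        if self.size_buffer < 0:
            raise InvalidParameterError("size_buffer must be >= 0")
        if self.bw_dram <= 0 or self.bw_maxring <= 0:
            raise InvalidParameterError("bandwidths must be > 0")

    @property
    def n_gap_kernels(self) -> int:
        return self.n_dfes * self.n_gapkernels_per_dfe


def hhmc_dram_throughput(cfg: PerfConfig, n_comps_cell: int, n_gates_comp: int) -> float:
    """Required DRAM throughput (bytes/s) of the cell kernel without gaps.

    Expanded per-stream form: a 100-byte stream accessed every tick per
    unrolled lane, a 44-byte stream accessed once per gate-loop pass, and a
    4-byte stream accessed once per compartment per gate-loop pass.
    """
    if n_comps_cell < 1 or n_gates_comp < 1:
        raise InvalidParameterError("compartment and gate counts must be >= 1")
    passes = math.ceil(n_gates_comp / cfg.uf_cell)
    return (
        (96 + 4) * cfg.uf_cell * cfg.f
        + (32 + 4 + 4 + 4) * cfg.f / passes
        + 4 * cfg.f / (passes * n_comps_cell)
    )


def gap_dram_throughput(cfg: PerfConfig) -> float:
    """Required DRAM throughput of the gap kernel: the 4-byte weight stream
    consumed by every unrolled lane on every tick, ``4 uf_gap f``."""
    return 4.0 * cfg.uf_gap * cfg.f


def min_freq_exceeding_dram(cfg: PerfConfig) -> int:
    """Smallest integer frequency (MHz) whose required gap-kernel weight
    throughput exceeds the per-DIMM DRAM bandwidth."""
    mhz = int(cfg.bw_dram / (4.0 * cfg.uf_gap * 1e6))
    while not gap_dram_throughput(replace(cfg, f=mhz * 1e6)) > cfg.bw_dram:
        mhz += 1
    return mhz


def mem_blocks(w_req: int, d_req: int, p_req: int, geometry=None, cfg: PerfConfig | None = None) -> int:
    """On-chip memory blocks needed for a (width, depth, ports) requirement.

    ``ceil(w/w_hw) * ceil(d/d_hw) * ceil(p/p_hw)`` — storing values in
    vectors trades depth and write ports against width, which is why
    vectorized storage usually needs fewer blocks.
    """
    if min(w_req, d_req, p_req) < 1:
        raise InvalidParameterError("memory requirements must be >= 1")
    if geometry is None:
        cfg = cfg or PerfConfig()
        geometry = (cfg.mem_width, cfg.mem_depth, cfg.mem_ports)
    w_hw, d_hw, p_hw = geometry
    return math.ceil(w_req / w_hw) * math.ceil(d_req / d_hw) * math.ceil(p_req / p_hw)


def stage_ticks(cfg: PerfConfig, n_cells_gap: int) -> int:
    """Ticks per ring stage of one gap kernel holding ``n_cells_gap`` cells.

    Each cell's accumulation occupies ``max(d_gap, ceil(N/uf_gap))`` ticks:
    the pipeline's rotating partial accumulators must complete a full
    ``d_gap``-tick rotation even when there are fewer addend groups than
    pipeline slots (depth-bound regime); with enough data the issue count
    ``ceil(N/uf_gap)`` dominates (saturated regime, ``N^2/uf`` per stage).
    """
    if n_cells_gap < 1:
        raise InvalidParameterError("n_cells_gap must be >= 1")
    iterations = math.ceil(n_cells_gap / cfg.uf_gap)
    return n_cells_gap * max(cfg.d_gap, iterations)


def maxring_throughput(cfg: PerfConfig, n_cells_gap: int) -> float:
    """Required ring-interconnect throughput (bytes/s).

    One block of ``n_cells_gap`` voltages is transferred per stage, and a
    whole stage is available for the transfer.
    """
    return cfg.bytes_per_value * n_cells_gap * cfg.f / stage_ticks(cfg, n_cells_gap)


def hhmcg_ticks(cfg: PerfConfig, n_cells_total: int, n_steps: int) -> int:
    """Total ticks of the gap-coupled simulation over all ring stages.

    ``n_steps * K * stage_ticks(N/K)`` with ``K = n_dfes *
    n_gapkernels_per_dfe``; non-divisible cell counts use the padded
    (phantom-cell) block size.  Linear in N while depth-bound, quadratic
    once every kernel's pipeline is saturated
    (``N/K * uf_gap >= d_gap``).
    """
    if n_cells_total < 1 or n_steps < 0:
        raise InvalidParameterError("need n_cells_total >= 1 and n_steps >= 0")
    K = cfg.n_gap_kernels
    block = math.ceil(n_cells_total / K)
    return n_steps * K * stage_ticks(cfg, block)


def cell_ticks(cfg: PerfConfig, gates_per_compartment, n_steps: int) -> int:
    """Ticks of the cell kernel: ``n_steps * sum_i ceil(N_gates[i]/uf_cell)``
    plus the variable-inner-loop buffer (added once)."""
    gates = list(gates_per_compartment)
    if not gates:
        raise InvalidParameterError("gates_per_compartment must be non-empty")
    return n_steps * sum(math.ceil(g / cfg.uf_cell) for g in gates) + cfg.size_buffer


def gap_ticks_monolithic(cfg: PerfConfig, n_cells: int, n_steps: int) -> int:
    """Ticks of a single un-partitioned gap kernel:
    ``n_steps * N * ceil(N/uf_gap)`` (``N^2/uf`` when divisible)."""
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    return n_steps * n_cells * math.ceil(n_cells / cfg.uf_gap)


def exec_time(cfg: PerfConfig, ticks: int, bytes_per_tick: float) -> tuple:
    """Predicted execution time and its bottleneck.

    ``T_comp = ticks / f``; ``T_DRAM = bytes_per_tick * ticks / bw_dram``;
    the execution time is the larger of the two, labelled ``"compute"`` or
    ``"memory"``.  The ring interconnect is omitted: its required
    throughput sits orders of magnitude below its bandwidth.
    """
    if ticks < 0:
        raise InvalidParameterError("ticks must be >= 0")
    t_comp = ticks / cfg.f
    t_dram = bytes_per_tick * ticks / cfg.bw_dram
    if t_comp >= t_dram:
        return t_comp, "compute"
    return t_dram, "memory"
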