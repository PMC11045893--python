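"""Ring-partitioned computation of gap-junction currents.

The all-to-all gap-current sum is split across ``K`` identical kernels
arranged in a one-dimensional systolic ring.  Cells are assigned to ``K``
equal, contiguous blocks (padding with phantom zero-weight cells when ``K``
does not divide the cell count).  Each simulation step runs ``K`` stages:

* **start** — every kernel accumulates partial currents from its own block
  of voltages and forwards that block to its ring neighbour;
* **middle** — each kernel accumulates from the block it just received and
  forwards it onward (repeated for ``K - 2`` stages);
* **end** — each kernel consumes the final block; the voltages are then
  fully updated.

Kernel ``k`` forwards to kernel ``(k + 1) mod K``, so at stage ``s`` it
holds block ``(k - s) mod K``; after ``K`` stages every kernel has consumed
every block exactly once.  Concurrency is emulated sequentially with
double-buffered block exchange: a stage only consumes data produced before
it.

Per-cell currents are exactly rounded sums (``math.fsum``) of the same pair
terms the dense path uses, so the result is bit-identical to
:func:`ehhsim.model.gap_current_dense` for every ``K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import InvalidParameterError, NetworkModel

__all__ = ["PartitionPlan", "make_partition", "ring_schedule", "compute_gap_partitioned"]


@dataclass(frozen=True)
class PartitionPlan:
    """Assignment of cells to ``K`` ring-ordered gap kernels."""

    n_cells: int
    K: int
    block_size: int
    n_phantom: int

    @property
    def padded_size(self) -> int:
        return self.n_cells + self.n_phantom

    @property
    def blocks(self) -> list:
        """Contiguous cell-index ranges, one per kernel, over padded cells."""
        b = self.block_size
        return [range(k * b, (k + 1) * b) for k in range(self.K)]


def make_partition(n_cells: int, K: int) -> PartitionPlan:
    """Split ``n_cells`` into ``K`` equal contiguous blocks.

    When ``K`` does not divide ``n_cells`` the tail is padded with phantom
    cells carrying zero weights; their currents are discarded on output.
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    if K < 1:
        raise InvalidParameterError("K must be >= 1")
    block = -(-n_cells // K)  # ceil division
    return PartitionPlan(n_cells=n_cells, K=K, block_size=block, n_phantom=block * K - n_cells)


def ring_schedule(plan: PartitionPlan) -> list:
    """Ordered ``(phase, kernel, source_block)`` triples, stage-major.

    ``K`` stages per step; stage 0 is ``"start"`` (local block, forwarded),
    stages ``1 .. K-2`` are ``"middle"`` (received block, forwarded), stage
    ``K-1`` is ``"end"`` (final received block, voltages updated).  ``K=1``
    collapses to a single local stage and ``K=2`` to start + end.
    """
    K = plan.K
    out = []
    for s in range(K):
        if s == 0:
            phase = "start"
        elif s == K - 1:
            phase = "end"
        else:
            phase = "middle"
        for k in range(K):
            out.append((phase, k, (k - s) % K))
    return out


def compute_gap_partitioned(
    model: NetworkModel,
    v_gap,
    plan: PartitionPlan,
    record_transfers: bool = False,
):
    """Gap currents for every real cell via the ring schedule.

    Returns the per-cell current array, or ``(currents, transfers)`` when
    ``record_transfers`` is set; ``transfers`` lists one
    ``(stage, kernel, block, n_values)`` record per block handed around the
    ring (each kernel transmits exactly one block of ``block_size`` voltage
    values per non-final stage).
    """
    v = np.asarray(v_gap, dtype=float)
    if v.shape != (model.n_cells,):
        raise InvalidParameterError(
            f"expected {model.n_cells} gap voltages, got shape {v.shape}"
        )
    if plan.n_cells != model.n_cells:
        raise InvalidParameterError(
            f"partition plan is for {plan.n_cells} cells, model has {model.n_cells}"
        )
    K, bs, npad = plan.K, plan.block_size, plan.padded_size

    # phantom cells: zero weights, zero voltage
    vp = np.zeros(npad)
    vp[: model.n_cells] = v
    wp = np.zeros((npad, npad))
    wp[: model.n_cells, : model.n_cells] = model.weights

    blocks = plan.blocks
    # per-kernel double buffer: block index + voltage copy currently held
    held = [(k, vp[blocks[k]].copy()) for k in range(K)]
    # per-cell pair terms collected stage by stage (schedule order)
    terms = [[] for _ in range(npad)]
    transfers = []

    for s in range(K):
        # compute phase: every kernel consumes the block it currently holds
        for k in range(K):
            b, v_other = held[k]
            rows = blocks[k]
            d = vp[rows][:, None] - v_other[None, :]
            cond = model.c0 * np.exp(model.c1 * d * d) + model.c2
            part = wp[rows][:, blocks[b]] * cond * d
            if b == k:
                np.fill_diagonal(part, 0.0)
            for local, cell in enumerate(rows):
                terms[cell].append(part[local])
        # transfer phase: forward the held block to the next kernel in the
        # ring (double-buffered: consumed only at the next stage)
        if s < K - 1:
            nxt = []
            for k in range(K):
                b, vb = held[k]
                transfers.append((s, k, b, bs))
                nxt.append((b, vb))
            held = [nxt[(k - 1) % K] for k in range(K)]

    currents = np.array(
        [math.fsum(np.concatenate(terms[i])) for i in range(model.n_cells)]
    )
    if record_transfers:
        return currents, transfers
    return currents
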