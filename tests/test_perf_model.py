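"""Analytical hardware performance model: throughputs, ticks, bottlenecks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ehhsim as e
from ehhsim.perf import PerfConfig


def emulate_stage_ticks(n_cells_block, uf, depth):
    """Brute-force discrete-event emulation of one ring stage.

    Models the accumulation pipeline tick by tick: cells are served one at
    a time; each cell issues ceil(N/uf) addend groups, one per tick, into a
    rotating bank of `depth` partial accumulators; the rotation must
    complete a full pass before the next cell's partials can be installed.
    """
    t = 0
    need = math.ceil(n_cells_block / uf)
    for _ in range(n_cells_block):
        issued = 0
        rotation = 0
        while True:
            if issued < need:
                issued += 1
            rotation += 1
            t += 1
            if issued >= need and rotation >= depth:
                break
    return t


def emulate_hhmcg_ticks(n_cells_total, K, uf, depth, n_steps):
    """Step/stage-level emulation of the full ring schedule."""
    block = math.ceil(n_cells_total / K)
    t = 0
    for _ in range(n_steps):
        # kernels run concurrently, so each of the K stages costs one
        # stage-emulation worth of ticks
        for _stage in range(K):
            t += emulate_stage_ticks(block, uf, depth)
    return t


class TestDramThroughput:
    def test_expanded_first_line_values(self):
        cfg = PerfConfig(uf_cell=1, f=1.0)
        assert e.hhmc_dram_throughput(cfg, 3, 3) == pytest.approx(100 + 44 / 3 + 4 / 9)
        cfg3 = PerfConfig(uf_cell=3, f=1.0)
        assert e.hhmc_dram_throughput(cfg3, 3, 3) == pytest.approx(300 + 44 + 4 / 3)

    def test_monotone_in_frequency(self):
        lo = e.hhmc_dram_throughput(PerfConfig(uf_cell=2, f=100e6), 3, 4)
        hi = e.hhmc_dram_throughput(PerfConfig(uf_cell=2, f=150e6), 3, 4)
        assert hi > lo

    def test_gap_weight_stream(self):
        assert e.gap_dram_throughput(PerfConfig(uf_gap=32, f=118e6)) == pytest.approx(1.5104e10)
        assert e.gap_dram_throughput(PerfConfig(uf_gap=32, f=117e6)) == pytest.approx(1.4976e10)
        assert e.gap_dram_throughput(PerfConfig(uf_gap=8, f=1.0)) == 32.0

    def test_threshold_frequencies(self):
        assert e.min_freq_exceeding_dram(PerfConfig(uf_gap=32)) == 118
        assert e.min_freq_exceeding_dram(PerfConfig(uf_gap=16)) == 235

    def test_doubling_unroll_roughly_halves_threshold(self):
        f16 = e.min_freq_exceeding_dram(PerfConfig(uf_gap=16))
        f32 = e.min_freq_exceeding_dram(PerfConfig(uf_gap=32))
        assert abs(f16 - 2 * f32) <= 2  # integer rounding slack


class TestMemBlocks:
    def test_exact_fit(self):
        assert e.mem_blocks(36, 1024, 1, (36, 1024, 1)) == 1

    def test_ceiling_product(self):
        assert e.mem_blocks(64, 2048, 2, (36, 1024, 1)) == 8

    def test_vectorizing_never_worse_when_vector_fits_word(self):
        """Packing 8 values per word (8x width, depth/8) does not increase
        the block count when the packed vector still fits one hardware word
        and the depth spans at least 8 hardware pages."""
        geom = (36, 1024, 1)
        for w in (2, 3, 4):  # 8 * w <= 36 bits
            for d in range(8 * 1024, 64 * 1024, 3 * 1024 + 7):
                plain = e.mem_blocks(w, d, 1, geom)
                packed = e.mem_blocks(w * 8, math.ceil(d / 8), 1, geom)
                assert packed <= plain

    def test_vectorizing_relieves_port_pressure(self):
        """With multiple write ports required, vectorized storage needs
        fewer blocks: the port and depth reductions outweigh the width."""
        geom = (36, 1024, 1)
        plain = e.mem_blocks(4, 16 * 1024, 8, geom)
        packed = e.mem_blocks(32, 2 * 1024, 1, geom)
        assert packed < plain


class TestStageTicks:
    def test_depth_bound_branch(self):
        cfg = PerfConfig(uf_gap=16, d_gap=90)
        assert e.stage_ticks(cfg, 100) == 9000

    def test_saturated_branch(self):
        cfg = PerfConfig(uf_gap=16, d_gap=90)
        assert e.stage_ticks(cfg, 3200) == 640_000  # N^2 / uf

    def test_branches_agree_at_boundary(self):
        cfg = PerfConfig(uf_gap=16, d_gap=90)
        n = 90 * 16
        assert e.stage_ticks(cfg, n) == n * 90

    @settings(derandomize=True, max_examples=120, deadline=None)
    @given(
        n=st.integers(1, 64),
        uf=st.sampled_from([1, 2, 4, 8]),
        d=st.integers(1, 16),
    )
    def test_matches_pipeline_emulator(self, n, uf, d):
        cfg = PerfConfig(uf_gap=uf, d_gap=d)
        assert e.stage_ticks(cfg, n) == emulate_stage_ticks(n, uf, d)


class TestRingThroughput:
    def test_far_below_ring_bandwidth(self):
        cfg = PerfConfig(uf_gap=16, d_gap=90, f=250e6)
        req = e.maxring_throughput(cfg, 3200)
        assert req == pytest.approx(5e6)
        assert req < cfg.bw_maxring / 100

    def test_saturated_closed_form_decreases_in_n(self):
        # saturated: 4 N f / (N^2/uf) = 4 f uf / N, decreasing in N
        cfg = PerfConfig(uf_gap=16, d_gap=90, f=250e6)
        for n in (3200, 6400):
            assert e.maxring_throughput(cfg, n) == pytest.approx(
                4 * cfg.f * cfg.uf_gap / n
            )
        assert e.maxring_throughput(cfg, 6400) < e.maxring_throughput(cfg, 3200)

    def test_zero_frequency(self):
        assert e.maxring_throughput(PerfConfig(uf_gap=16, d_gap=90, f=0.0), 100) == 0.0


class TestHhmcgTicks:
    def test_single_kernel_single_step_is_one_stage(self):
        cfg = PerfConfig(uf_gap=16, d_gap=90)
        assert e.hhmcg_ticks(cfg, 128, 1) == e.stage_ticks(cfg, 128)

    def test_saturated_example(self):
        cfg = PerfConfig(uf_gap=16, d_gap=90, n_dfes=4)
        assert e.hhmcg_ticks(cfg, 6400, 1) == 640_000

    def test_depth_bound_example_linear_in_n(self):
        cfg = PerfConfig(uf_gap=16, d_gap=90, n_dfes=4)
        assert e.hhmcg_ticks(cfg, 64, 1) == 5760
        assert e.hhmcg_ticks(cfg, 128, 1) == 2 * e.hhmcg_ticks(cfg, 64, 1)

    def test_quadratic_when_saturated(self):
        cfg = PerfConfig(uf_gap=16, d_gap=90, n_dfes=4)
        assert e.hhmcg_ticks(cfg, 12800, 1) == 4 * e.hhmcg_ticks(cfg, 6400, 1)

    def test_regime_switch_at_saturation_condition(self):
        """The linear/quadratic switch happens exactly where each kernel's
        block times the unroll factor reaches the pipeline depth."""
        cfg = PerfConfig(uf_gap=4, d_gap=12, n_dfes=2)
        n_sat = cfg.d_gap * cfg.uf_gap * cfg.n_gap_kernels  # N/K * uf = d
        below = e.hhmcg_ticks(cfg, n_sat // 2, 1)
        at = e.hhmcg_ticks(cfg, n_sat, 1)
        above = e.hhmcg_ticks(cfg, n_sat * 2, 1)
        assert at == 2 * below       # still linear up to saturation
        assert above == 4 * at       # quadratic beyond

    def test_perfect_scaling_when_saturated(self):
        """Perfect multi-kernel scaling in the saturated regime: K kernels
        cut the per-step tick count by exactly K (ticks * K is constant),
        the basis of the near-linear multi-device speedup."""
        work = {
            k: e.hhmcg_ticks(PerfConfig(uf_gap=16, d_gap=90, n_dfes=k), 25600, 3) * k
            for k in (1, 2, 4, 8)
        }
        assert len(set(work.values())) == 1

    def test_no_scaling_benefit_when_depth_bound(self):
        """Below saturation the pipelines idle: adding kernels does not
        reduce the total tick count at all."""
        ticks = {
            k: e.hhmcg_ticks(PerfConfig(uf_gap=16, d_gap=90, n_dfes=k), 64, 3)
            for k in (1, 2, 4)
        }
        assert len(set(ticks.values())) == 1

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        n=st.integers(1, 48),
        k=st.integers(1, 4),
        uf=st.sampled_from([1, 2, 4]),
        d=st.integers(1, 12),
        steps=st.integers(1, 3),
    )
    def test_matches_schedule_emulator(self, n, k, uf, d, steps):
        cfg = PerfConfig(uf_gap=uf, d_gap=d, n_dfes=k)
        assert e.hhmcg_ticks(cfg, n, steps) == emulate_hhmcg_ticks(n, k, uf, d, steps)


class TestCellTicks:
    def test_worked_example(self):
        cfg = PerfConfig(uf_cell=2, size_buffer=16)
        assert e.cell_ticks(cfg, [4, 5, 4], 10) == 86

    def test_large_unroll_saturates_at_compartment_count(self):
        cfg = PerfConfig(uf_cell=8, size_buffer=5)
        assert e.cell_ticks(cfg, [4, 6, 3], 7) == 7 * 3 + 5

    def test_minimal(self):
        cfg = PerfConfig(uf_cell=1, size_buffer=0)
        assert e.cell_ticks(cfg, [1], 1) == 1


class TestGapTicksMonolithic:
    def test_values(self):
        cfg = PerfConfig(uf_gap=16)
        assert e.gap_ticks_monolithic(cfg, 64, 2) == 512
        assert e.gap_ticks_monolithic(PerfConfig(uf_gap=1), 10, 1) == 100
        assert e.gap_ticks_monolithic(PerfConfig(uf_gap=16), 1, 5) == 5


class TestExecTime:
    def test_compute_bound(self):
        cfg = PerfConfig(f=200e6)
        t, label = e.exec_time(cfg, ticks=1000, bytes_per_tick=0.0)
        assert t == 1000 / 200e6 and label == "compute"

    def test_memory_bound(self):
        cfg = PerfConfig(f=200e6, bw_dram=15e9)
        bpt = 2 * cfg.bw_dram / cfg.f  # twice the crossover volume
        t, label = e.exec_time(cfg, ticks=500, bytes_per_tick=bpt)
        assert label == "memory"
        assert t == pytest.approx(bpt * 500 / cfg.bw_dram)

    def test_zero_ticks(self):
        assert e.exec_time(PerfConfig(), 0, 100.0) == (0.0, "compute")

    def test_crossover_matches_closed_form(self):
        """For the gap kernel the compute/memory crossover sits exactly at
        bw_dram = 4 uf_gap f."""
        cfg = PerfConfig(uf_gap=16, f=170e6)
        crossover = 4 * cfg.uf_gap * cfg.f
        bpt = e.gap_dram_throughput(cfg) / cfg.f
        for bw, expect in ((crossover * 1.001, "compute"), (crossover * 0.999, "memory")):
            c = PerfConfig(uf_gap=16, f=170e6, bw_dram=bw)
            assert e.exec_time(c, 1000, bpt)[1] == expect

    def test_non_increasing_in_bandwidth(self):
        bpt = 100.0
        times = [
            e.exec_time(PerfConfig(bw_dram=bw), 10_000, bpt)[0]
            for bw in (1e9, 5e9, 15e9, 60e9)
        ]
        assert all(a >= b for a, b in zip(times, times[1:]))
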