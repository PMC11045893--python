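"""Predict hardware throughput requirements and tick counts.

Evaluates the analytical performance model: where the gap kernel's weight
stream outgrows the on-board DRAM bandwidth, how stage tick counts switch
from the depth-bound (linear) to the saturated (quadratic) regime, and
which resource bounds the predicted execution time.
"""

import ehhsim as e
from ehhsim.perf import PerfConfig

# DRAM threshold: the 4-byte weight stream per unrolled lane per tick
for uf in (16, 32):
    mhz = e.min_freq_exceeding_dram(PerfConfig(uf_gap=uf, bw_dram=15e9))
    print(f"uf_gap={uf}: weight stream exceeds 15 GB/s above {mhz - 1} MHz")

# stage ticks: linear while the pipeline is under-filled, quadratic after
cfg = PerfConfig(uf_gap=16, d_gap=90)
print("\n cells/kernel   ticks/stage   regime")
for n in (50, 100, 1440, 3200, 6400):
    ticks = e.stage_ticks(cfg, n)
    regime = "depth-bound" if n < cfg.d_gap * cfg.uf_gap else "saturated"
    print(f"{n:12d} {ticks:13d}   {regime}")

# ring transfers stay far below the interconnect bandwidth
ring = e.maxring_throughput(PerfConfig(uf_gap=16, d_gap=90, f=250e6), 3200)
print(f"\nring transfer requirement at 3200 cells/kernel: {ring/1e6:.1f} MB/s "
      f"(bandwidth: 5000 MB/s)")

# execution-time bottleneck of the monolithic gap kernel
cfg = PerfConfig(uf_gap=16, f=170e6)
ticks = e.gap_ticks_monolithic(cfg, 7680, n_steps=1)
bytes_per_tick = e.gap_dram_throughput(cfg) / cfg.f
t, label = e.exec_time(cfg, ticks, bytes_per_tick)
print(f"7680 cells, one step: {ticks} ticks, {t*1e6:.1f} us, {label}-bound")
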