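# ehhsim

Simulation of extended Hodgkin–Huxley (eHH) neural networks — complex ion
gates, multi-compartment cells, and gap-junction coupling — together with a
faithful software emulation of how such networks are scheduled on
ring-connected dataflow accelerators, and the analytical performance model
that predicts their hardware behaviour.

It is written for computational neuroscientists who want a desk-scale,
fully inspectable reference for this simulation method: the same equations,
the same ring-partitioned gap-junction schedule, the same counter-based
connectivity generation, and the same throughput/tick accounting, all in
plain Python.

## The model

A cell is a serial chain of electrical compartments. Compartment voltage
obeys

    C dV_i/dt = I_app,i − I_channels,i − I_leak,i − I_mc,i − I_gap,i

with ohmic channel currents `I = g_c (V − V_c) · Π_k y_k^{p_k}`, leak
`g_l (V − V_l)`, inter-compartment coupling
`g_int Σ_j (V_i − V_j)/p_ij` over chain neighbours, and gap junctions
between the designated compartments of different cells:

    I_gap,i = Σ_j w_ij (c0 · exp(c1 · V_ij²) + c2) · V_ij ,   V_ij = V_i − V_j .

Gate variables follow `dy/dt = (1−y)α − yβ` or `dy/dt = (inf − y)/τ`, where
every rate is an instance of a single three-branch generalized function

    f(f_t, V, k0, k1, k2) = k0(k1−V)/(e^{(k1−V)k2} − 1) | k0·e^{(k1−V)k2} | k0/(e^{(k1−V)k2} + 1)

so a network is pure data: no re-coding to change a channel. The state
advances by synchronous forward Euler, `u ← u + Δt f(u)`.

Two presets are built in: the original squid-axon cell (its six rate
equations expressed as generalized records) and a three-compartment
inferior-olive cell (dendrite/soma/axon, 13 gate-state variables including
a calcium concentration, dendro-dendritic gap junctions).

The gap-junction sum — the quadratic, communication-heavy part — can be
computed on an emulated ring of K kernels: cells are split into equal
blocks, and voltages travel kernel-to-kernel through a start/middle/end
systolic schedule. Pair terms are summed exactly rounded, so the result is
**bit-identical** for every K and for the dense reference. Connectivity
weights come from the stateless counter-based Squares generator (uniform,
or gaussian via the probit transform), so any matrix entry can be
regenerated from its (i, j) address without storing the matrix.

The `perf` module predicts the hardware's behaviour in closed form:
required DRAM/ring throughputs, on-chip memory-block counts, per-stage and
total tick counts with their depth-bound (linear) vs saturated (quadratic)
regimes, and compute-vs-memory execution-time bottlenecks.

## A worked example

```python
import numpy as np
import ehhsim as e

net = e.build_io_network(12, {"dist": "gaussian", "key_seed": 5,
                              "mu": 0.5, "sigma": 0.15, "symmetric": True})
config = e.SimulationConfig(dt=0.05, n_steps=400, v_init=-60.0)
dense = e.run(net, config)
ring = e.run(net, config, partition=4)       # 4 emulated gap kernels
print(np.array_equal(ring.values, dense.values))
```

prints `True`: splitting the gap-junction workload across four emulated
kernels changes nothing, to the last bit. Running
`python examples/olive_network_ring.py` prints

```
K=3 ring trace identical to dense: True
K=4 ring trace identical to dense: True
partition: 4 kernels x 3 cells, 0 phantoms
kernel 2 consumes blocks in order: [2, 1, 0, 3]
sum of gap currents (symmetric weights): 1.388e-17 of total magnitude 0.898 — conservation
```

The block order shows the ring forwarding (each kernel first uses its own
block, then its neighbours' in ring order); the last line checks that
symmetric electrical coupling moves charge between cells without creating
any — the summed gap current is zero to rounding.

The performance model is just as direct:

```python
from ehhsim.perf import PerfConfig
e.min_freq_exceeding_dram(PerfConfig(uf_gap=32, bw_dram=15e9))  # -> 118
```

the smallest clock (MHz) at which a 32-lane gap kernel's 4-byte weight
stream outgrows a 15 GB/s DRAM DIMM. `examples/performance_model.py`
tabulates the linear-to-quadratic tick regimes and the ring-transfer
requirement (5.0 MB/s at 3200 cells/kernel — three orders below the
interconnect's bandwidth).

Other example scripts: `simulate_squid_axon.py` (action potential:
105.54 mV excursion at t = 2.15 ms under a −10 µA/cm² step),
`generate_connectivity.py` (address-regenerable weights),
`import_neuroml_gate.py` (NeuroML HH-gate import, exact to rounding).

A thin CLI wraps the same functions:

```
ehhsim simulate --config net.json --out trace.csv --dfes-emulated 4
ehhsim gen-net --cells 100 --dist gaussian --key-seed 7 --out w.tsv
ehhsim convert --neuroml channels.xml --out gates.json
ehhsim perf --kernel gap --sweep-f 100:300:10 --uf 16,32 --out sweep.tsv
```

## Scope

Forward Euler is the only production solver (higher-accuracy integrators
appear only as test oracles); compartment chains are serial (no branching
dendritic trees); synapses are electrical (no chemical synapses); the
hardware itself is modelled and emulated, never synthesized. See
`docs/methods.md` for the full model description, numerical choices and
limitations.
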