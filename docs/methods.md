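# Methods

This note documents the model equations, the numerical and design choices
behind `ehhsim`, what the built-in presets emulate, and the limits of what
the test suite demonstrates.

## Model equations

**Membrane dynamics.** Each compartment `i` integrates

    C dV_i/dt = I_app,i − I_channels,i − I_leak,i − I_mc,i − I_gap,i

- `I_channels,i = Σ_j g_c,j (V_i − V_c,j) · yProd_j`, with
  `yProd_j = Π_k y_k^{p_k}` the product of the channel's gate variables
  raised to non-negative integer exponents (an empty product is 1, giving a
  purely ohmic channel).
- `I_leak,i = g_l (V_i − V_l)`. The source formulation names the leak term
  without defining it; the standard ohmic leak with per-compartment
  constants is used.
- `I_mc,i = g_int Σ_j (V_i − V_j)/p_ij` over the (at most two) serial-chain
  neighbours. Each compartment after the first stores one surface ratio
  `p_up ∈ (0,1)`: the current towards the previous neighbour divides by
  `p_up`, the current from the previous towards this compartment divides by
  `1 − p_up`. This reproduces the asymmetric surface-ratio coupling of the
  olive literature (soma→dendrite /0.25, dendrite→soma /0.75, etc.) with a
  single stored number per junction.
- `I_gap,i = Σ_j w_ij (c0 e^{c1 V_ij²} + c2) V_ij`, `V_ij = V_i − V_j`.
  `w[i][j]` weights the current *into* cell `i` contributed by cell `j`;
  the diagonal is ignored (zeroed on construction). The conductance factor
  is even in `V_ij`, so for symmetric `w` the pair terms are exactly
  antisymmetric and total current is conserved.

**Gate kinetics.** `dy/dt = (1−y)α − yβ` (`alpha_beta`) or
`dy/dt = (inf − y)/τ` (`inf_tau`). A gate's driver is its compartment
voltage by default, or a named auxiliary state (`driver="aux:k"`) for
concentration-gated channels.

**Generalized rates.** Every rate is `a·f(f_t, v, k0, k1, k2) + b` with the
three-branch kernel

    branch 0:  k0 (k1 − v) / (e^{(k1−v)k2} − 1)
    branch 1:  k0 e^{(k1−v)k2}
    branch 2:  k0 / (e^{(k1−v)k2} + 1)

The affine wrap `(a, b)` is this library's extension: it covers constant
offsets in time constants (e.g. `5 + 47 e^{(V+50)/900}`) and uniform rate
scalings (e.g. the olive r-gate's 1/5 kinetic factor) that the bare kernel
cannot express. Three olive rate laws fall outside even the wrapped family
(a product of an exponential and a sigmoid, a sum of two exponentials in a
denominator, and a clipped linear function of calcium); these are provided
as *named built-in rates*, referenced by name in serialized documents so
round-tripping stays exact. Anything further is out of scope.

**Auxiliary states.** First-order linear in one channel current:
`ds/dt = c_I · I_channel + c_S · s`. This matches the olive calcium
equation (`dCa/dt = −3.0 I_CaH − 0.075 Ca`) while staying generic.

**Numerical guard.** Branch 0 has a removable singularity at
`(k1−v)k2 = 0`; within `|x| < ε = 1e-7` the evaluator returns the
l'Hôpital limit `k0/k2`. The guard's worst-case relative error at the band
edge is ~`ε/2`, far below any dynamics of interest, and the evaluator is
exact at the singular point itself. `expm1` is used outside the band.
Overflowing scalar exponentials saturate to `inf` (matching the array
path) so runaway trajectories surface as a diagnosable instability error —
naming the offending state variable and step — rather than an exception
from deep inside libm.

## Solver

Synchronous forward Euler: all derivatives are evaluated on the same
pre-step snapshot, then `u ← u + Δt f(u)`. This is mathematically the same
update the split cell-kernel/gap-kernel hardware performs; the split is
therefore not emulated separately. Properties the suite verifies: exact
agreement with a hand-written scalar transcription for one step; global
first-order convergence (log-log slope 1.0 ± 0.15 against a Δt/64
reference); gate boundedness in [0,1] whenever `Δt(α+β) ≤ 1` along the
trajectory; rest-state stability; bitwise determinism.

Initialization is either explicit (a full state vector) or `steady_state`:
voltage-driven gates at `α/(α+β)` or `inf`, auxiliary states at their own
fixed point `s* = −c_I I/c_S` (with channel currents from the
voltage-driven gates), then concentration-driven gates at the driver value
`s*`. `resting_voltage()` locates the uniform voltage where the summed
steady-state membrane current vanishes, by bisection.

Stimuli are constant, pulse (half-open `[on, off)`, so step counts are
unambiguous), or sampled series with zero-order hold (time before the
first sample yields 0 with a logged warning).

## Presets

**Squid axon.** Original sign convention (rest ≈ 0, spike negative,
`V_Na = −115`, `V_K = +12`, `V_l = −10.613` mV; `g_Na = 120`, `g_K = 36`,
`g_l = 0.3` mS/cm²; C = 1 µF/cm²). The six rate laws are stored as
generalized records and verified against direct transcriptions to 1e-12
relative on a dense voltage grid. Conductances and reversals come from the
original publication, which defines the cell the rate equations belong to.
Default Δt = 0.01 ms (comfortable margin under the fastest rate at spike
voltages).

**Inferior olive.** Three compartments in a serial chain —
dendrite (gap-junction terminal), soma, axon — transcribed from the
published olive network model this simulation method benchmarks:

| compartment | channels (gate^exponent) | gate states |
|---|---|---|
| dendrite | CaH (r²), KCa (s, Ca-driven), H (q) + calcium aux | 4 |
| soma | CaL (k³l), Na (m³h), Kdr (n⁴), Ks (x_s⁴) | 6 |
| axon | Na (m_a³h_a), K (x_a⁴) | 3 |

13 gate-state variables per cell; the calcium concentration is counted
among them because the state bookkeeping (like the hardware's gate memory)
stores it in the same bank. Constants: `g_int = 0.13`, surface ratios
0.25 (soma–dendrite) and 0.15 (axon–soma), leak 0.016 / +10 mV everywhere,
`V_Na = 55`, `V_K = −75`, `V_Ca = 120`, `V_h = −43` mV. Gap conductance
`0.8 e^{−0.01 V²} + 0.2`; weights in [0,1] carry the per-pair coupling
strength. The sodium activation gates are instantaneous in the source
model; they are kept as state variables with τ = 0.05 ms — equal to the
preset's Δt, so one Euler step lands them exactly on their target, which
reproduces the instantaneous update at the default step while remaining a
well-defined ODE for smaller steps. Default Δt = 0.05 ms, the step the
olive-model literature integrates this cell with.

The generated-connectivity defaults (gaussian, μ = 0.5, σ = 0.15, clipped
to [0,1]) keep the clipped mass at ~0.09% (3.33σ tails); clipping policy is
this library's choice since only the admissible weight range is prescribed.

**What the presets do not emulate.** Real olive tissue has heterogeneous
conductances, sparse local connectivity and noisy drive; the presets are
deliberately homogeneous and all-to-all (the hardest case for the
partitioned gap computation, and the configuration the hardware model
assumes). Passing tests therefore demonstrate correctness of the
numerics and the scheduling, not biological realism of any particular
trace.

## Ring-partitioned gap computation

`make_partition(n, K)` splits cells into K equal contiguous blocks,
padding with phantom cells (zero weights, zero voltage — they contribute
exact zeros) when K ∤ n. The schedule runs K stages per step: *start*
(each kernel consumes its own block and forwards it), K−2 *middle* stages
(consume the received block, forward it), *end* (consume the final block,
update voltages). Kernel k forwards to (k+1) mod K, so at stage s it holds
block (k−s) mod K; each kernel sees every block exactly once. Any order in
which ring forwarding delivers every block once is admissible; this
descending-mod order is the one a unidirectional ring produces, and it is
asserted in the tests. Concurrency is emulated sequentially with
double-buffered block exchange — a stage consumes only data produced
before it — and each kernel transmits exactly one block of voltages per
non-final stage, the data volume the ring-throughput model charges.

**Exact summation.** Per-pair current terms are computed identically in
the dense and partitioned paths, and each cell's current is their *exactly
rounded* sum (`math.fsum`). Since exact rounding is order-independent, the
partitioned result is bit-identical to the dense reference for every K —
a stronger and simpler guarantee than fixing a summation order, which
cannot be partition-invariant under float non-associativity. The price is
a constant-factor cost on the N² terms, irrelevant at desk scale.

## Connectivity generation

The Squares generator (four middle-square rounds over a 64-bit
counter × key product) supplies stateless uniforms: entry (i, j) uses
counter `i·n + j` (the upper-triangle address when symmetric), so matrices
never need storing and any entry is regenerable in O(1) — the property
that lets hardware generate weights in-stream. Keys follow the published
construction (16 non-zero hex digits, distinct within each half, lowest
digit odd) from a user seed. Uniform weights are `x/2³²` ∈ [0,1);
gaussian weights are `μ + σ·probit(u)` with `u = (x+0.5)/2³²` (strictly
interior, so the probit is always finite) clipped to [0,1]. The probit is
the inverse normal CDF (`scipy.special.ndtri`), verified against a
root-finding oracle to 1e-9.

## Performance model

All quantities are closed-form functions of a `PerfConfig` (unroll
factors, clock, bandwidths, pipeline depth, memory geometry; defaults:
15 GB/s DRAM per DIMM, 5 GB/s ring, 4-byte values, 170 MHz).

- **Cell-kernel DRAM throughput** uses the expanded per-stream form
  `100·uf·f + 44·f/⌈N_g/uf⌉ + 4·f/(⌈N_g/uf⌉·N_c)`. (The one-line
  simplification sometimes quoted for it is inconsistent with the
  expanded form and is not used.)
- **Gap-kernel DRAM throughput** is the weight stream `4·uf_gap·f`; its
  smallest integer MHz exceeding a 15 GB/s DIMM is 118 at uf = 32 and 235
  at uf = 16.
- **Stage ticks** are `N · max(d_gap, ⌈N/uf_gap⌉)`: each cell's
  accumulation occupies the larger of the pipeline's rotation depth and
  its issue count. The unified `max` form covers both the depth-bound
  (linear in N) and saturated (N²/uf) regimes and switches exactly at the
  saturation condition `N·uf ≥ d`. A brute-force discrete-event emulator —
  one cell at a time, one addend group per tick into a rotating bank of d
  partial accumulators, full rotation required before handoff — reproduces
  the closed form for every small (N, uf, d).
- **Execution time** is `max(ticks/f, bytes_per_tick·ticks/bw_dram)` with
  the bottleneck labelled; the transferred volume is `bytes_per_tick ·
  ticks` (a data volume, not a rate — an extra clock factor sometimes seen
  in this expression is dimensionally wrong). Ring transfer time is
  omitted: its requirement sits orders of magnitude below the ring
  bandwidth (5 MB/s vs 5 GB/s in the saturated example).
- **Memory blocks**: `⌈w/w_hw⌉·⌈d/d_hw⌉·⌈p/p_hw⌉`. Vectorized storage
  reduces the count when the packed vector fits a hardware word or when it
  relieves write-port pressure; packing that overflows the word width can
  cost blocks, so it is a trade, not a law.
- Ceilings are applied wherever counts are divided (ticks are integral);
  exact divisions reproduce the plain formulas. `d_gap = 90` and
  `size_buffer = 16` are exposed placeholders: the modelled platform does
  not publish them. The inner-loop buffer is added once, outside the step
  product, following the literal reading of its defining expression.

## Tunable parameters that matter

| parameter | default | meaning |
|---|---|---|
| `dt` | 0.01 ms (squid), 0.05 ms (olive) | Euler step; stability requires `dt·(α+β) ≤ 1` on the visited range |
| `c0, c1, c2` | 0.8, −0.01 mV⁻², 0.2 | gap conductance vs voltage difference |
| `uf_cell, uf_gap` | 1, 16 | hardware lanes per loop |
| `d_gap` | 90 ticks | gap-pipeline depth; sets the linear/quadratic switch |
| `bw_dram, bw_maxring` | 15, 5 GB/s | per-DIMM and ring bandwidths |
| `μ, σ` (gaussian weights) | 0.5, 0.15 | keeps [0,1] clipping ≈ 0.09% |

## Problem sizes used in the checks

Partition invariance and conservation use 12–48-cell networks (60–400
steps); convergence uses a 4 ms stimulated squid-axon trajectory at
Δt ∈ {0.04, 0.02, 0.01} against a Δt/64 reference; the tick-model sweep
covers all (N ≤ 64, uf ∈ {1,2,4,8}, d ≤ 16); RNG statistics use 10⁵ draws
and a 200-cell weight matrix. These sizes exercise every code path while
keeping the whole suite under a minute on one core.

## Known limitations

- Forward Euler only; stiff channel sets need small steps. No adaptive or
  implicit solvers, by design.
- Serial compartment chains only (no branching trees), electrical synapses
  only — the same functional envelope as the modelled hardware library.
- The all-N² gap computation is performed even for sparse weight matrices;
  sparsity optimization is explicitly out of scope.
- Units are a contract, not a check: presets use mV/ms/mS·cm⁻²/µA·cm⁻²,
  but nothing stops inconsistent user input.
- The performance model predicts requirement/capacity crossovers and tick
  counts, not wall-clock times of any physical device; effective DRAM
  bandwidths below the theoretical figure shift the thresholds
  accordingly.
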