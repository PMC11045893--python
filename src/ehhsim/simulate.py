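"""Forward-Euler time stepping over the whole network state.

The full state (membrane voltages, gate activations, auxiliary
concentrations) advances synchronously: every derivative is evaluated on the
same pre-step snapshot, then ``u <- u + dt * f(u)``.  Gap currents are
computed per step either from the dense all-to-all sum or through the
ring-partitioned schedule; both produce bit-identical currents, so traces do
not depend on the emulated kernel count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    EhhError,
    InvalidParameterError,
    NetworkModel,
    NumericalInstabilityError,
    aux_derivative,
    channel_current,
    eval_rate,
    gap_current_dense,
    gate_derivative,
    gate_product,
    leak_current,
    mc_current,
)
from .ring import compute_gap_partitioned, make_partition

__all__ = [
    "StimulusSpec",
    "SimulationConfig",
    "StateVector",
    "Trace",
    "DegenerateGateError",
    "eval_stimulus",
    "steady_state_gates",
    "initial_state",
    "euler_step",
    "run",
]

log = logging.getLogger("ehhsim")


class DegenerateGateError(EhhError):
    """Steady state is undefined because alpha + beta = 0."""


@dataclass(frozen=True)
class StimulusSpec:
    """Applied-current waveform for one compartment.

    ``kind`` is ``"constant"`` (always ``amplitude``), ``"pulse"``
    (``amplitude`` on the half-open interval ``[t_on, t_off)``) or
    ``"series"`` (zero-order hold over sampled ``times``/``values``).
    """

    kind: str
    amplitude: float = 0.0
    t_on: float = 0.0
    t_off: float = 0.0
    times: tuple = ()
    values: tuple = ()

    def __post_init__(self):
        if self.kind not in ("constant", "pulse", "series"):
            raise InvalidParameterError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "pulse" and not self.t_on < self.t_off:
            raise InvalidParameterError("pulse requires t_on < t_off")
        if self.kind == "series":
            object.__setattr__(self, "times", tuple(self.times))
            object.__setattr__(self, "values", tuple(self.values))
            if len(self.times) != len(self.values) or not self.times:
                raise InvalidParameterError("series needs equal-length, non-empty samples")
            if any(b <= a for a, b in zip(self.times, self.times[1:])):
                raise InvalidParameterError("series times must be strictly increasing")


def eval_stimulus(spec: StimulusSpec | None, t: float) -> float:
    """Applied current at time ``t`` (0 for a missing stimulus)."""
    if spec is None:
        return 0.0
    if spec.kind == "constant":
        return spec.amplitude
    if spec.kind == "pulse":
        return spec.amplitude if spec.t_on <= t < spec.t_off else 0.0
    if t < spec.times[0]:
        log.warning("stimulus evaluated at t=%g before first sample t=%g", t, spec.times[0])
        return 0.0
    idx = int(np.searchsorted(spec.times, t, side="right")) - 1
    return spec.values[idx]


@dataclass(frozen=True)
class SimulationConfig:
    """Time-stepping parameters.

    ``stimuli`` maps ``(cell_index, compartment_index)`` to a
    :class:`StimulusSpec`.  ``init`` is ``"steady_state"`` (gates and
    auxiliary states at their fixed point for ``v_init``) or ``"explicit"``
    (a full :class:`StateVector` supplied to :func:`run`).
    """

    dt: float
    n_steps: int
    stimuli: dict = field(default_factory=dict)
    record_stride: int = 1
    init: str = "steady_state"
    v_init: float = 0.0
    record_gates: bool = False
    precision: str = "double"

    def __post_init__(self):
        if not self.dt >= 0:
            raise InvalidParameterError("dt must be >= 0")
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.record_stride < 1:
            raise InvalidParameterError("record_stride must be >= 1")
        if self.init not in ("steady_state", "explicit"):
            raise InvalidParameterError("init must be 'steady_state' or 'explicit'")
        if self.precision not in ("double", "single"):
            raise InvalidParameterError("precision must be 'double' or 'single'")


@dataclass
class StateVector:
    """Flattened network state at one instant (cell-major layout)."""

    V: np.ndarray  # one entry per compartment
    y: np.ndarray  # one entry per gate
    s: np.ndarray  # one entry per auxiliary state
    t: float = 0.0

    def copy(self) -> "StateVector":
        return StateVector(self.V.copy(), self.y.copy(), self.s.copy(), self.t)


@dataclass
class Trace:
    """Recorded simulation output: times x named variables."""

    times: np.ndarray
    names: list
    values: np.ndarray  # shape (n_recorded, len(names))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


class _Layout:
    """Index bookkeeping mapping the model tree onto flat state arrays."""

    def __init__(self, model: NetworkModel):
        self.model = model
        self.v_index = {}  # (cell, comp) -> V slot
        self.y_index = {}  # (cell, comp, channel, gate) -> y slot
        self.s_index = {}  # (cell, comp, aux) -> s slot
        self.v_names, self.y_names, self.s_names = [], [], []
        self.gap_v_slots = []  # per cell, V slot of the gap compartment
        nv = ny = ns = 0
        for ci, cell in enumerate(model.cells):
            for pi, comp in enumerate(cell.compartments):
                self.v_index[ci, pi] = nv
                self.v_names.append(f"cell{ci}/{comp.name}/V")
                if comp.has_gap:
                    self.gap_v_slots.append(nv)
                nv += 1
                for chi, ch in enumerate(comp.channels):
                    for gi, gate in enumerate(ch.gates):
                        self.y_index[ci, pi, chi, gi] = ny
                        self.y_names.append(f"cell{ci}/{comp.name}/{gate.name}")
                        ny += 1
                for ai, aux in enumerate(comp.aux_states):
                    self.s_index[ci, pi, ai] = ns
                    self.s_names.append(f"cell{ci}/{comp.name}/{aux.name}")
                    ns += 1
        self.n_v, self.n_y, self.n_s = nv, ny, ns

    def empty_state(self) -> StateVector:
        return StateVector(np.zeros(self.n_v), np.zeros(self.n_y), np.zeros(self.n_s))


def _driver_value(gate, v, s_comp):
    """Driver value for a gate: the compartment voltage or an aux state."""
    k = gate.aux_index
    return v if k is None else s_comp[k]


def steady_state_gates(model: NetworkModel, v: float) -> np.ndarray:
    """Gate activations at their fixed point for uniform voltage ``v``.

    ``alpha_beta`` gates settle at ``alpha / (alpha + beta)``, ``inf_tau``
    gates at their target value.  Gates driven by an auxiliary state use
    that state's own fixed point (``s* = -c_I I / c_S`` with the channel
    current evaluated from the voltage-driven gates).
    """
    _, y, _ = _steady_state(model, v)
    return y


def _steady_state(model: NetworkModel, v: float):
    layout = _Layout(model)
    st = layout.empty_state()
    st.V[:] = v

    def fixed_point(gate, driver):
        r1 = eval_rate(gate.rate1, driver)
        r2 = eval_rate(gate.rate2, driver)
        if gate.formulation == "alpha_beta":
            if r1 + r2 == 0:
                raise DegenerateGateError(
                    f"gate {gate.name!r}: alpha + beta = 0 at driver {driver}"
                )
            return r1 / (r1 + r2)
        return r1

    for ci, cell in enumerate(model.cells):
        for pi, comp in enumerate(cell.compartments):
            # pass 1: voltage-driven gates
            for chi, ch in enumerate(comp.channels):
                for gi, gate in enumerate(ch.gates):
                    if gate.aux_index is None:
                        st.y[layout.y_index[ci, pi, chi, gi]] = fixed_point(gate, v)
            # pass 2: auxiliary states at their own fixed point
            for ai, aux in enumerate(comp.aux_states):
                ch = comp.channels[aux.channel]
                yprod = gate_product(
                    [
                        (st.y[layout.y_index[ci, pi, aux.channel, gi]], g.exponent)
                        for gi, g in enumerate(ch.gates)
                        if g.aux_index is None
                    ]
                )
                i_ch = channel_current(ch, v, yprod)
                if aux.c_self == 0:
                    raise DegenerateGateError(
                        f"aux state {aux.name!r}: fixed point undefined with c_self = 0"
                    )
                st.s[layout.s_index[ci, pi, ai]] = -aux.c_current * i_ch / aux.c_self
            # pass 3: aux-driven gates
            for chi, ch in enumerate(comp.channels):
                for gi, gate in enumerate(ch.gates):
                    k = gate.aux_index
                    if k is not None:
                        driver = st.s[layout.s_index[ci, pi, k]]
                        st.y[layout.y_index[ci, pi, chi, gi]] = fixed_point(gate, driver)
    return layout, st.y, st.s


def resting_voltage(model: NetworkModel, v_lo: float = -90.0, v_hi: float = 20.0) -> float:
    """Uniform voltage at which the summed membrane current vanishes.

    Gates and auxiliary states sit at their fixed points for the candidate
    voltage; the root of the total (all-compartment) voltage derivative is
    located by bisection.  Exact for single-compartment cells; for
    multi-compartment cells it is the balance point of the summed currents
    (inter-compartment terms cancel at uniform voltage).
    """
    from scipy.optimize import brentq

    layout = _Layout(model)

    def net(v):
        st = layout.empty_state()
        st.V[:] = v
        _, st.y[:], st.s[:] = _steady_state(model, v)
        dV, _, _ = _derivatives(model, layout, st, {}, None)
        return float(np.sum(dV))

    return float(brentq(net, v_lo, v_hi, xtol=1e-12))


def initial_state(model: NetworkModel, config: SimulationConfig, explicit=None) -> StateVector:
    """Initial :class:`StateVector` per the config's initialization policy."""
    if config.init == "explicit":
        if explicit is None:
            raise InvalidParameterError("explicit initialization requires a StateVector")
        st = explicit.copy()
    else:
        layout, y, s = _steady_state(model, config.v_init)
        st = layout.empty_state()
        st.V[:] = config.v_init
        st.y[:] = y
        st.s[:] = s
    if config.precision == "single":
        # state storage in single precision, mirroring hardware data widths;
        # per-step arithmetic rounds back into the float32 state
        st = StateVector(
            st.V.astype(np.float32), st.y.astype(np.float32),
            st.s.astype(np.float32), st.t,
        )
    return st


def _derivatives(model, layout, state, stim_values, gap_currents):
    """Synchronous derivative of the full state vector."""
    dV = np.zeros_like(state.V)
    dy = np.zeros_like(state.y)
    ds = np.zeros_like(state.s)
    for ci, cell in enumerate(model.cells):
        v_cell = [state.V[layout.v_index[ci, pi]] for pi in range(cell.n_comps)]
        for pi, comp in enumerate(cell.compartments):
            v = v_cell[pi]
            s_comp = [
                state.s[layout.s_index[ci, pi, ai]] for ai in range(len(comp.aux_states))
            ]
            i_channels = 0.0
            ch_currents = []
            for chi, ch in enumerate(comp.channels):
                yprod = gate_product(
                    [
                        (state.y[layout.y_index[ci, pi, chi, gi]], g.exponent)
                        for gi, g in enumerate(ch.gates)
                    ]
                )
                i_ch = channel_current(ch, v, yprod)
                ch_currents.append(i_ch)
                i_channels += i_ch
                for gi, gate in enumerate(ch.gates):
                    slot = layout.y_index[ci, pi, chi, gi]
                    dy[slot] = gate_derivative(
                        gate, state.y[slot], _driver_value(gate, v, s_comp)
                    )
            for ai, aux in enumerate(comp.aux_states):
                slot = layout.s_index[ci, pi, ai]
                ds[slot] = aux_derivative(aux, state.s[slot], ch_currents[aux.channel])
            i_mc = mc_current(cell, pi, v_cell) if cell.n_comps > 1 else 0.0
            i_gap = gap_currents[ci] if (comp.has_gap and gap_currents is not None) else 0.0
            i_app = stim_values.get((ci, pi), 0.0)
            slot = layout.v_index[ci, pi]
            dV[slot] = (i_app - i_channels - leak_current(comp, v) - i_mc - i_gap) / comp.C
    return dV, dy, ds


def _check_finite(layout, dV, dy, ds):
    for arr, names in ((dV, layout.v_names), (dy, layout.y_names), (ds, layout.s_names)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise NumericalInstabilityError(
                f"non-finite derivative for {names[bad[0]]}"
            )


def euler_step(
    model: NetworkModel,
    state: StateVector,
    stimuli: dict | None = None,
    dt: float = 0.0,
    *,
    partition=None,
    layout: _Layout | None = None,
) -> StateVector:
    """One synchronous forward-Euler step; the input state is unmodified.

    ``partition`` selects the gap-current path: ``None`` for the dense sum,
    an integer ``K`` or a :class:`~ehhsim.ring.PartitionPlan` for the
    ring-partitioned schedule (both yield bit-identical currents).
    """
    layout = layout or _Layout(model)
    stim_values = {
        key: eval_stimulus(spec, state.t) for key, spec in (stimuli or {}).items()
    }
    gap_currents = _gap_currents(model, layout, state, partition)
    dV, dy, ds = _derivatives(model, layout, state, stim_values, gap_currents)
    _check_finite(layout, dV, dy, ds)
    return StateVector(
        V=state.V + dt * dV, y=state.y + dt * dy, s=state.s + dt * ds, t=state.t + dt
    )


def _gap_currents(model, layout, state, partition):
    if not model.has_gap or not np.any(model.weights):
        return None
    v_gap = state.V[layout.gap_v_slots]
    if partition is None:
        return gap_current_dense(model, v_gap)
    plan = partition if not isinstance(partition, int) else make_partition(model.n_cells, partition)
    return compute_gap_partitioned(model, v_gap, plan)


def run(
    model: NetworkModel,
    config: SimulationConfig,
    *,
    initial: StateVector | None = None,
    partition=None,
) -> Trace:
    """Integrate ``config.n_steps`` forward-Euler steps and record a trace.

    Every ``record_stride``-th state is recorded, starting with the initial
    state at ``t = 0``.  The result is deterministic given the model,
    config and weights.
    """
    layout = _Layout(model)
    state = initial_state(model, config, explicit=initial)
    names = list(layout.v_names)
    if config.record_gates:
        names += layout.y_names + layout.s_names
    plan = (
        make_partition(model.n_cells, partition)
        if isinstance(partition, int)
        else partition
    )

    def snapshot(st):
        if config.record_gates:
            return np.concatenate([st.V, st.y, st.s])
        return st.V.copy()

    times = [state.t]
    rows = [snapshot(state)]
    for step in range(config.n_steps):
        try:
            state = euler_step(
                model, state, config.stimuli, config.dt, partition=plan, layout=layout
            )
        except NumericalInstabilityError as err:
            raise NumericalInstabilityError(f"step {step}: {err}") from err
        if (step + 1) % config.record_stride == 0:
            times.append(state.t)
            rows.append(snapshot(state))
    return Trace(times=np.array(times), names=names, values=np.array(rows))
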