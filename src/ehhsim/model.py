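"""Core types and per-term evaluators for extended Hodgkin-Huxley networks.

An extended Hodgkin-Huxley (eHH) cell is a serial chain of electrical
compartments.  Each compartment carries a membrane voltage ``V`` obeying

    C dV/dt = I_app - I_channels - I_leak - I_mc - I_gap

where ``I_channels`` sums ohmic channel currents ``g_c (V - V_c) * yProd``,
``yProd`` is the product of the channel's gate-activation variables raised to
integer exponents, ``I_leak = g_l (V - V_l)``, ``I_mc`` couples chain
neighbours through the internal conductance and surface ratios, and ``I_gap``
couples the designated gap compartment of each cell to every other cell
through a voltage-difference-dependent conductance

    I_gap,i = sum_j w[i,j] * (c0 * exp(c1 * V_ij^2) + c2) * V_ij .

Gate kinetics use either transition rates (``dy/dt = (1-y) a - y b``) or a
target/time-constant pair (``dy/dt = (inf - y)/tau``).  Each rate is an
affine-wrapped instance of a three-branch generalized rate function
(:class:`RateFunction`), or a named built-in function for rate laws outside
that family (:class:`NamedRate`).

Units are not enforced; the library follows a consistent-unit contract
(presets use the unit conventions of their source publications: mV, ms,
mS/cm^2, uA/cm^2, uF/cm^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RATE_EPS",
    "EhhError",
    "InvalidParameterError",
    "NumericalInstabilityError",
    "RateFunction",
    "NamedRate",
    "BUILTIN_RATES",
    "GateSpec",
    "ChannelSpec",
    "AuxStateSpec",
    "CompartmentSpec",
    "CellSpec",
    "NetworkModel",
    "eval_rate",
    "gate_product",
    "channel_current",
    "leak_current",
    "mc_current",
    "gap_pair_terms",
    "gap_current_dense",
    "gate_derivative",
    "aux_derivative",
    "membrane_derivative",
]

#: half-width of the guard band around the removable singularity of branch 0
RATE_EPS = 1e-7


class EhhError(Exception):
    """Base class for all errors raised by ehhsim."""


class InvalidParameterError(EhhError, ValueError):
    """A model parameter is outside its admissible domain."""


class NumericalInstabilityError(EhhError, RuntimeError):
    """A state derivative became non-finite during integration."""


# registry of named rate laws that fall outside the generalized family;
# presets register entries on import, config loading resolves them by name
BUILTIN_RATES: dict = {}


@dataclass(frozen=True)
class RateFunction:
    """Affine-wrapped three-branch generalized transition-rate function.

    Evaluates ``a * f(f_t, v, k0, k1, k2) + b`` with

    * branch 0: ``k0 (k1 - v) / (exp((k1 - v) k2) - 1)``
    * branch 1: ``k0 exp((k1 - v) k2)``
    * branch 2: ``k0 / (exp((k1 - v) k2) + 1)``

    Branch 0 has a removable singularity at ``(k1 - v) k2 = 0``; inside the
    guard band ``|(k1 - v) k2| < RATE_EPS`` the analytic limit ``k0 / k2``
    is returned.
    """

    f_t: int
    k0: float
    k1: float
    k2: float
    a: float = 1.0
    b: float = 0.0

    def __post_init__(self):
        if self.f_t not in (0, 1, 2):
            raise InvalidParameterError(f"f_t must be 0, 1 or 2, got {self.f_t}")
        if self.f_t == 0 and self.k2 == 0.0:
            raise InvalidParameterError("branch 0 requires k2 != 0")
        for name in ("k0", "k1", "k2", "a", "b"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")

    def __call__(self, v):
        return eval_rate(self, v)


@dataclass(frozen=True)
class NamedRate:
    """Reference to a registered built-in rate law (see ``BUILTIN_RATES``)."""

    name: str

    def __post_init__(self):
        if self.name not in BUILTIN_RATES:
            raise InvalidParameterError(f"unknown named rate {self.name!r}")

    def __call__(self, v):
        return BUILTIN_RATES[self.name](v)


def eval_rate(r, v):
    """Evaluate a rate specification at driver value(s) ``v``.

    Accepts scalars or numpy arrays and returns the same shape.
    """
    if isinstance(r, NamedRate):
        return BUILTIN_RATES[r.name](v)
    if not isinstance(r, RateFunction):  # plain callable escape hatch
        return r(v)
    if isinstance(v, np.ndarray):
        x = (r.k1 - v) * r.k2
        if r.f_t == 0:
            core = np.where(
                np.abs(x) < RATE_EPS,
                r.k0 / r.k2,
                r.k0 * (r.k1 - v) / np.expm1(np.where(np.abs(x) < RATE_EPS, 1.0, x)),
            )
        elif r.f_t == 1:
            core = r.k0 * np.exp(x)
        else:
            core = r.k0 / (np.exp(x) + 1.0)
        return r.a * core + r.b
    # scalar fast path; overflow saturates to inf (as the array path does)
    # so runaway states surface as an instability error, not an exception
    x = (r.k1 - v) * r.k2
    if r.f_t == 0:
        if abs(x) < RATE_EPS:
            core = r.k0 / r.k2
        else:
            core = r.k0 * (r.k1 - v) / _expm1(x)
    elif r.f_t == 1:
        core = r.k0 * _exp(x)
    else:
        core = r.k0 / (_exp(x) + 1.0)
    return r.a * core + r.b


def _exp(x: float) -> float:
    try:
        return math.exp(x)
    except OverflowError:
        return math.inf


def _expm1(x: float) -> float:
    try:
        return math.expm1(x)
    except OverflowError:
        return math.inf


@dataclass(frozen=True)
class GateSpec:
    """One gate-activation variable of an ion channel.

    ``formulation`` selects the kinetic law: ``"alpha_beta"`` interprets
    ``rate1``/``rate2`` as transition rates (alpha, beta); ``"inf_tau"``
    interprets them as the target value and the time constant.  ``driver``
    names the variable the rates are evaluated at: ``"v"`` (the compartment
    voltage, default) or ``"aux:<k>"`` (the k-th auxiliary state of the same
    compartment, e.g. a calcium concentration).
    """

    name: str
    formulation: str
    rate1: RateFunction | NamedRate
    rate2: RateFunction | NamedRate
    exponent: int
    driver: str = "v"

    def __post_init__(self):
        if self.formulation not in ("alpha_beta", "inf_tau"):
            raise InvalidParameterError(
                f"formulation must be 'alpha_beta' or 'inf_tau', got {self.formulation!r}"
            )
        if not (isinstance(self.exponent, int) and self.exponent >= 0):
            raise InvalidParameterError("gate exponent must be a non-negative integer")
        if self.driver != "v" and not self.driver.startswith("aux:"):
            raise InvalidParameterError(f"driver must be 'v' or 'aux:<k>', got {self.driver!r}")

    @property
    def aux_index(self) -> int | None:
        if self.driver == "v":
            return None
        return int(self.driver.split(":", 1)[1])


@dataclass(frozen=True)
class ChannelSpec:
    """Ohmic ion channel: ``I = g (V - e_rev) * yProd``."""

    name: str
    g: float
    e_rev: float
    gates: tuple = ()

    def __post_init__(self):
        if self.g < 0:
            raise InvalidParameterError("channel conductance must be >= 0")
        object.__setattr__(self, "gates", tuple(self.gates))


@dataclass(frozen=True)
class AuxStateSpec:
    """Auxiliary first-order state (e.g. a calcium concentration).

    ``ds/dt = c_current * I_channel + c_self * s`` where ``I_channel`` is the
    current of the referenced channel (index into the compartment's channel
    list).
    """

    name: str
    channel: int
    c_current: float
    c_self: float


@dataclass(frozen=True)
class CompartmentSpec:
    """One electrical compartment of a cell.

    ``p_up`` is the surface ratio towards the *previous* compartment in the
    serial chain: the coupling current uses ``p_up`` in the direction towards
    the previous neighbour and ``1 - p_up`` (of the downstream compartment)
    towards the next.  The first compartment's ``p_up`` is unused.
    """

    name: str
    C: float
    g_leak: float
    e_leak: float
    channels: tuple = ()
    p_up: float = 1.0
    has_gap: bool = False
    aux_states: tuple = ()

    def __post_init__(self):
        if not self.C > 0:
            raise InvalidParameterError("capacitance must be > 0")
        if self.g_leak < 0:
            raise InvalidParameterError("leak conductance must be >= 0")
        if not self.p_up > 0:
            raise InvalidParameterError("surface ratio p_up must be > 0")
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "aux_states", tuple(self.aux_states))
        for a in self.aux_states:
            if not (0 <= a.channel < len(self.channels)):
                raise InvalidParameterError(
                    f"aux state {a.name!r} references channel {a.channel} "
                    f"but compartment {self.name!r} has {len(self.channels)} channels"
                )

    @property
    def n_gate_states(self) -> int:
        """Gate-state variables stored for this compartment (gates + aux)."""
        return sum(len(ch.gates) for ch in self.channels) + len(self.aux_states)


@dataclass(frozen=True)
class CellSpec:
    """Serial chain of compartments with internal conductance ``g_int``."""

    compartments: tuple
    g_int: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "compartments", tuple(self.compartments))
        if len(self.compartments) < 1:
            raise InvalidParameterError("a cell needs at least one compartment")
        if sum(c.has_gap for c in self.compartments) > 1:
            raise InvalidParameterError("at most one compartment may terminate gap junctions")
        if self.g_int < 0:
            raise InvalidParameterError("g_int must be >= 0")
        # p_up and 1 - p_up both act as divisors along the chain
        for c in self.compartments[1:]:
            if not 0 < c.p_up < 1:
                raise InvalidParameterError(
                    f"surface ratio of compartment {c.name!r} must lie in (0, 1)"
                )

    @property
    def n_comps(self) -> int:
        return len(self.compartments)

    @property
    def gap_comp(self) -> int | None:
        """Index of the compartment terminating gap junctions, or None."""
        for i, c in enumerate(self.compartments):
            if c.has_gap:
                return i
        return None

    def gate_state_counts(self) -> list:
        """Per-compartment count of stored gate-state variables.

        Auxiliary concentrations are counted with the gates: the state
        memory holds them in the same bank, so this is the quantity the
        per-compartment state bookkeeping works with.
        """
        return [c.n_gate_states for c in self.compartments]

    @property
    def n_gate_states(self) -> int:
        return sum(self.gate_state_counts())


class NetworkModel:
    """A network of eHH cells coupled all-to-all through gap junctions.

    Parameters
    ----------
    cells : sequence of CellSpec
        Heterogeneous cells are allowed.
    c0, c1, c2 : float
        Gap-junction conductance constants of
        ``I = w (c0 exp(c1 V^2) + c2) V``.
    weights : (n, n) array_like
        ``weights[i][j]`` multiplies the junction current into cell *i*
        contributed by cell *j*.  The diagonal is ignored (zeroed on
        construction).
    weight_source : dict, optional
        Provenance record for serialization (e.g. the generator spec the
        matrix came from).
    """

    def __init__(self, cells, c0=0.0, c1=0.0, c2=0.0, weights=None, weight_source=None):
        self.cells = tuple(cells)
        if not self.cells:
            raise InvalidParameterError("a network needs at least one cell")
        self.c0 = float(c0)
        self.c1 = float(c1)
        self.c2 = float(c2)
        n = len(self.cells)
        if weights is None:
            weights = np.zeros((n, n))
        w = np.array(weights, dtype=float, copy=True)
        if w.shape != (n, n):
            raise InvalidParameterError(
                f"weight matrix shape {w.shape} does not match {n} cells"
            )
        if not np.all(np.isfinite(w)):
            raise InvalidParameterError("weights must be finite")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        self.weight_source = weight_source
        gap_flags = [c.gap_comp is not None for c in self.cells]
        if any(gap_flags) and not all(gap_flags):
            raise InvalidParameterError(
                "either every cell or no cell must have a gap compartment"
            )
        self.has_gap = all(gap_flags) if gap_flags else False

    @property
    def n_cells(self) -> int:
        return len(self.cells)


# ---------------------------------------------------------------------------
# per-term evaluators


def gate_product(gates) -> float:
    """``prod(y_k ** p_k)`` over (value, exponent) pairs; empty product is 1."""
    out = 1.0
    for y, p in gates:
        out *= y**p
    return out


def channel_current(ch: ChannelSpec, v: float, yprod: float) -> float:
    """Ohmic channel current ``g (V - e_rev) * yProd``."""
    return ch.g * (v - ch.e_rev) * yprod


def leak_current(comp: CompartmentSpec, v: float) -> float:
    """Leak current ``g_l (V - V_l)``."""
    return comp.g_leak * (v - comp.e_leak)


def mc_current(cell: CellSpec, i: int, v) -> float:
    """Inter-compartment current for compartment ``i`` of ``cell``.

    ``g_int * sum_j (V_i - V_j) / p_{i,j}`` over the (at most two) serial
    chain neighbours, with ``p_{i,i-1} = p_up[i]`` and
    ``p_{i,i+1} = 1 - p_up[i+1]``.
    """
    comps = cell.compartments
    if not 0 <= i < len(comps):
        raise IndexError(f"compartment index {i} out of range for {len(comps)} compartments")
    out = 0.0
    if i > 0:
        out += (v[i] - v[i - 1]) / comps[i].p_up
    if i < len(comps) - 1:
        out += (v[i] - v[i + 1]) / (1.0 - comps[i + 1].p_up)
    return cell.g_int * out


def gap_pair_terms(model: NetworkModel, v_gap) -> np.ndarray:
    """Matrix of per-pair gap-current terms.

    ``terms[i, j] = w[i, j] (c0 exp(c1 V_ij^2) + c2) V_ij`` with
    ``V_ij = V_i - V_j`` and a zero diagonal.  Both the dense and the
    ring-partitioned paths sum exactly these terms, so their results can be
    compared bit-for-bit.
    """
    v = np.asarray(v_gap, dtype=float)
    if v.shape != (model.n_cells,):
        raise InvalidParameterError(
            f"expected {model.n_cells} gap voltages, got shape {v.shape}"
        )
    d = v[:, None] - v[None, :]
    cond = model.c0 * np.exp(model.c1 * d * d) + model.c2
    terms = model.weights * cond * d
    np.fill_diagonal(terms, 0.0)
    return terms


def gap_current_dense(model: NetworkModel, v_gap) -> np.ndarray:
    """Per-cell gap currents from the dense all-to-all sum.

    Each cell's current is the exactly rounded sum (``math.fsum``) of its
    pair terms, which makes the result independent of summation order and
    identical to the ring-partitioned computation.
    """
    terms = gap_pair_terms(model, v_gap)
    return np.array([math.fsum(row) for row in terms])


def gate_derivative(g: GateSpec, y: float, v: float) -> float:
    """Rate of change of a gate-activation variable at driver value ``v``."""
    r1 = eval_rate(g.rate1, v)
    r2 = eval_rate(g.rate2, v)
    if g.formulation == "alpha_beta":
        return (1.0 - y) * r1 - y * r2
    if r2 <= 0:
        raise InvalidParameterError(
            f"gate {g.name!r}: time constant must be > 0, got {r2} at driver {v}"
        )
    return (r1 - y) / r2


def aux_derivative(a: AuxStateSpec, s: float, i_channel: float) -> float:
    """``c_current * I + c_self * s`` (first-order linear auxiliary state)."""
    return a.c_current * i_channel + a.c_self * s


def membrane_derivative(
    comp: CompartmentSpec,
    i_app: float,
    i_channels: float,
    i_leak: float,
    i_mc: float = 0.0,
    i_gap: float = 0.0,
) -> float:
    """``(I_app - I_channels - I_leak - I_mc - I_gap) / C``."""
    return (i_app - i_channels - i_leak - i_mc - i_gap) / comp.C
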