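"""Built-in, fully parameterized models.

Two presets are provided:

* :func:`build_original_hh` — the classic squid-axon cell in its original
  sign convention (rest at V = 0, depolarization negative, V_Na = -115 mV),
  with the K (n^4), Na (m^3 h) and leak conductances, all rates expressed
  as generalized :class:`~ehhsim.model.RateFunction` records.

* :func:`build_io_cell` / :func:`build_io_network` — a three-compartment
  inferior-olive cell (dendrite, soma, axon) after the De Gruijl /
  Schweighofer olive model: low- and high-threshold calcium, a
  calcium-gated potassium conductance with an explicit calcium
  concentration, an h-current, sodium and two potassium conductances, and
  dendro-dendritic gap junctions with the voltage-difference-dependent
  conductance ``0.8 exp(-0.01 V^2) + 0.2``.

Three olive rate laws (the l-gate and q-gate time constants and the
calcium-driven s-gate forward rate) fall outside the generalized family and
are registered as named built-in rates.
"""

from __future__ import annotations

import numpy as np

from .model import (
    BUILTIN_RATES,
    AuxStateSpec,
    CellSpec,
    ChannelSpec,
    CompartmentSpec,
    GateSpec,
    InvalidParameterError,
    NamedRate,
    NetworkModel,
    RateFunction,
)

__all__ = [
    "HH_DT",
    "IO_DT",
    "build_original_hh",
    "build_io_cell",
    "build_io_network",
]

#: default forward-Euler step sizes (ms) giving a comfortable stability margin
HH_DT = 0.01
IO_DT = 0.05


# -- named rate laws outside the generalized family -------------------------

def _io_tau_l(v):
    """Time constant of the low-threshold calcium inactivation gate (ms)."""
    return 20.0 * np.exp((v + 160.0) / 30.0) / (1.0 + np.exp((v + 84.0) / 7.3)) + 35.0


def _io_tau_q(v):
    """Time constant of the h-current activation gate (ms)."""
    return 1.0 / (np.exp(-0.086 * v - 14.6) + np.exp(0.070 * v - 1.87))


def _io_alpha_s(ca):
    """Forward rate of the calcium-gated potassium gate, driven by [Ca]."""
    return np.minimum(2.0e-5 * ca, 0.01)


BUILTIN_RATES.setdefault("io_tau_l", _io_tau_l)
BUILTIN_RATES.setdefault("io_tau_q", _io_tau_q)
BUILTIN_RATES.setdefault("io_alpha_s", _io_alpha_s)


def _const(value: float) -> RateFunction:
    """Constant rate: branch 1 with k2 = 0 gives k0 for every driver value."""
    return RateFunction(f_t=1, k0=value, k1=0.0, k2=0.0)


# -- original squid-axon cell ------------------------------------------------

def build_original_hh() -> NetworkModel:
    """Single-cell, single-compartment squid-axon model.

    Original 1952 sign convention: rest at V = 0, an action potential is a
    negative excursion of roughly -100 mV, reversal potentials
    V_Na = -115, V_K = +12, V_l = -10.613 mV; conductances in mS/cm^2.
    """
    n_gate = GateSpec(
        name="n",
        formulation="alpha_beta",
        # alpha_n = 0.01 (V + 10) / (exp((V + 10)/10) - 1)
        rate1=RateFunction(f_t=0, k0=-0.01, k1=-10.0, k2=-0.1),
        # beta_n = 0.125 exp(V / 80)
        rate2=RateFunction(f_t=1, k0=0.125, k1=0.0, k2=-1.0 / 80.0),
        exponent=4,
    )
    m_gate = GateSpec(
        name="m",
        formulation="alpha_beta",
        # alpha_m = 0.1 (V + 25) / (exp((V + 25)/10) - 1)
        rate1=RateFunction(f_t=0, k0=-0.1, k1=-25.0, k2=-0.1),
        # beta_m = 4 exp(V / 18)
        rate2=RateFunction(f_t=1, k0=4.0, k1=0.0, k2=-1.0 / 18.0),
        exponent=3,
    )
    h_gate = GateSpec(
        name="h",
        formulation="alpha_beta",
        # alpha_h = 0.07 exp(V / 20)
        rate1=RateFunction(f_t=1, k0=0.07, k1=0.0, k2=-1.0 / 20.0),
        # beta_h = 1 / (exp((V + 30)/10) + 1)
        rate2=RateFunction(f_t=2, k0=1.0, k1=-30.0, k2=-0.1),
        exponent=1,
    )
    membrane = CompartmentSpec(
        name="membrane",
        C=1.0,
        g_leak=0.3,
        e_leak=-10.613,
        channels=(
            ChannelSpec(name="K", g=36.0, e_rev=12.0, gates=(n_gate,)),
            ChannelSpec(name="Na", g=120.0, e_rev=-115.0, gates=(m_gate, h_gate)),
        ),
    )
    cell = CellSpec(compartments=(membrane,), g_int=0.0)
    return NetworkModel(cells=[cell])


# -- inferior-olive cell -----------------------------------------------------

# reversal potentials (mV) and shared constants of the olive model
_V_NA, _V_K, _V_CA, _V_H, _V_L = 55.0, -75.0, 120.0, -43.0, 10.0
_G_LEAK = 0.016
_G_INT, _P1, _P2 = 0.13, 0.25, 0.15

#: gap-junction conductance constants: 0.8 exp(-0.01 V^2) + 0.2
IO_GAP_C0, IO_GAP_C1, IO_GAP_C2 = 0.8, -0.01, 0.2

# quasi-instantaneous sodium activation: tau equal to the preset step size,
# so one Euler step with dt = IO_DT lands the gate exactly on its target
_TAU_INSTANT = IO_DT


def _sigmoid(k0, midpoint, slope) -> RateFunction:
    """``k0 / (1 + exp(-(v - midpoint)/slope))`` as a branch-2 record."""
    return RateFunction(f_t=2, k0=k0, k1=midpoint, k2=1.0 / slope)


def build_io_cell() -> CellSpec:
    """Three-compartment inferior-olive cell (dendrite, soma, axon).

    The dendrite terminates the gap junctions and carries the calcium
    concentration as an auxiliary state; per-compartment gate-state counts
    are 4 (dendrite, incl. [Ca]), 6 (soma) and 3 (axon), 13 per cell.
    """
    # --- dendrite ---
    r_gate = GateSpec(  # high-threshold calcium activation, r^2
        name="r",
        formulation="alpha_beta",
        # dr/dt = 0.2 (alpha (1 - r) - beta r): the affine scale a = 0.2
        # carries the 1/5 factor of the source's tau = 5/(alpha + beta)
        rate1=RateFunction(f_t=2, k0=1.7, k1=5.0, k2=1.0 / 13.9, a=0.2),
        rate2=RateFunction(f_t=0, k0=-0.02, k1=-8.5, k2=-0.2, a=0.2),
        exponent=2,
    )
    s_gate = GateSpec(  # calcium-gated potassium, driven by [Ca]
        name="s",
        formulation="alpha_beta",
        rate1=NamedRate("io_alpha_s"),
        rate2=_const(0.015),
        exponent=1,
        driver="aux:0",
    )
    q_gate = GateSpec(  # h-current activation
        name="q",
        formulation="inf_tau",
        rate1=_sigmoid(1.0, -80.0, -4.0),
        rate2=NamedRate("io_tau_q"),
        exponent=1,
    )
    dendrite = CompartmentSpec(
        name="dendrite",
        C=1.0,
        g_leak=_G_LEAK,
        e_leak=_V_L,
        channels=(
            ChannelSpec(name="CaH", g=4.5, e_rev=_V_CA, gates=(r_gate,)),
            ChannelSpec(name="KCa", g=35.0, e_rev=_V_K, gates=(s_gate,)),
            ChannelSpec(name="H", g=0.125, e_rev=_V_H, gates=(q_gate,)),
        ),
        has_gap=True,
        aux_states=(AuxStateSpec(name="Ca", channel=0, c_current=-3.0, c_self=-0.075),),
    )

    # --- soma ---
    k_gate = GateSpec(  # low-threshold calcium activation, k^3
        name="k",
        formulation="inf_tau",
        rate1=_sigmoid(1.0, -61.0, 4.2),
        rate2=_const(1.0),
        exponent=3,
    )
    l_gate = GateSpec(  # low-threshold calcium inactivation
        name="l",
        formulation="inf_tau",
        rate1=_sigmoid(1.0, -85.5, -8.5),
        rate2=NamedRate("io_tau_l"),
        exponent=1,
    )
    m_gate = GateSpec(  # sodium activation, quasi-instantaneous
        name="m",
        formulation="inf_tau",
        rate1=_sigmoid(1.0, -30.0, 5.5),
        rate2=_const(_TAU_INSTANT),
        exponent=3,
    )
    h_gate = GateSpec(  # sodium inactivation
        name="h",
        formulation="inf_tau",
        rate1=_sigmoid(1.0, -70.0, -5.8),
        rate2=RateFunction(f_t=1, k0=3.0, k1=-40.0, k2=1.0 / 33.0),
        exponent=1,
    )
    n_gate = GateSpec(  # delayed-rectifier potassium, n^4
        name="n",
        formulation="inf_tau",
        rate1=_sigmoid(1.0, -3.0, 10.0),
        rate2=RateFunction(f_t=1, k0=47.0, k1=-50.0, k2=-1.0 / 900.0, b=5.0),
        exponent=4,
    )
    xs_gate = GateSpec(  # slow potassium, x_s^4
        name="x_s",
        formulation="alpha_beta",
        rate1=RateFunction(f_t=0, k0=0.13, k1=-25.0, k2=0.1),
        rate2=RateFunction(f_t=1, k0=1.69, k1=-35.0, k2=0.0125),
        exponent=4,
    )
    soma = CompartmentSpec(
        name="soma",
        C=1.0,
        g_leak=_G_LEAK,
        e_leak=_V_L,
        channels=(
            ChannelSpec(name="CaL", g=1.1, e_rev=_V_CA, gates=(k_gate, l_gate)),
            ChannelSpec(name="Na", g=150.0, e_rev=_V_NA, gates=(m_gate, h_gate)),
            ChannelSpec(name="Kdr", g=9.0, e_rev=_V_K, gates=(n_gate,)),
            ChannelSpec(name="Ks", g=5.0, e_rev=_V_K, gates=(xs_gate,)),
        ),
        p_up=_P1,  # soma <-> dendrite surface ratio
    )

    # --- axon ---
    ma_gate = GateSpec(
        name="m_a",
        formulation="inf_tau",
        rate1=_sigmoid(1.0, -30.0, 5.5),
        rate2=_const(_TAU_INSTANT),
        exponent=3,
    )
    ha_gate = GateSpec(
        name="h_a",
        formulation="inf_tau",
        rate1=_sigmoid(1.0, -60.0, -5.8),
        rate2=RateFunction(f_t=1, k0=1.5, k1=-40.0, k2=1.0 / 33.0),
        exponent=1,
    )
    xa_gate = GateSpec(
        name="x_a",
        formulation="alpha_beta",
        rate1=RateFunction(f_t=0, k0=0.13, k1=-25.0, k2=0.1),
        rate2=RateFunction(f_t=1, k0=1.69, k1=-35.0, k2=0.0125),
        exponent=4,
    )
    axon = CompartmentSpec(
        name="axon",
        C=1.0,
        g_leak=_G_LEAK,
        e_leak=_V_L,
        channels=(
            ChannelSpec(name="Na_a", g=240.0, e_rev=_V_NA, gates=(ma_gate, ha_gate)),
            ChannelSpec(name="K_a", g=20.0, e_rev=_V_K, gates=(xa_gate,)),
        ),
        p_up=_P2,  # axon <-> soma surface ratio
    )

    return CellSpec(compartments=(dendrite, soma, axon), g_int=_G_INT)


def build_io_network(n_cells: int, weights=None, *, weight_seed: int = 0) -> NetworkModel:
    """All-to-all network of identical inferior-olive cells.

    Parameters
    ----------
    n_cells : int
        Number of cells (>= 1).
    weights : (n, n) array_like or dict, optional
        Explicit weight matrix, or a generator spec understood by
        :func:`ehhsim.connectivity.generate_weights`
        (``{"dist": "uniform"|"gaussian", "key_seed": ..., "mu": ...,
        "sigma": ..., "symmetric": ...}``).  Defaults to symmetric uniform
        weights generated from ``weight_seed``.
    weight_seed : int
        Seed for the default generated connectivity.
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    from .connectivity import generate_weights, make_key

    source = None
    if weights is None:
        weights = {"dist": "uniform", "key_seed": weight_seed, "symmetric": True}
    if isinstance(weights, dict):
        spec = dict(weights)
        spec.setdefault("dist", "uniform")
        spec.setdefault("symmetric", True)
        key = spec.pop("key", None)
        if key is None:
            key = make_key(spec.pop("key_seed", weight_seed))
        else:
            spec.pop("key_seed", None)
        source = {"kind": "generated", "key": int(key), **spec}
        w = generate_weights(n_cells, key=key, **spec)
    else:
        w = np.asarray(weights, dtype=float)
    cell = build_io_cell()
    return NetworkModel(
        cells=[cell] * n_cells,
        c0=IO_GAP_C0,
        c1=IO_GAP_C1,
        c2=IO_GAP_C2,
        weights=w,
        weight_source=source,
    )
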