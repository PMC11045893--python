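"""Native configuration documents (JSON) for models and simulations.

The document carries a schema tag, the full network description (cells,
compartments, channels, gates, gap constants) and the simulation settings.
Weights are stored inline or as a generator spec (regenerated on load from
the counter-based generator, so the document stays small for any network
size).  Loading validates strictly: unknown fields are rejected with the
offending JSON path.
"""

from __future__ import annotations

import json

import numpy as np

from . import presets  # noqa: F401  (registers the named built-in rates)
from .model import (
    AuxStateSpec,
    CellSpec,
    ChannelSpec,
    CompartmentSpec,
    EhhError,
    GateSpec,
    NamedRate,
    NetworkModel,
    RateFunction,
)
from .simulate import SimulationConfig, StimulusSpec

__all__ = ["ConfigError", "SCHEMA", "export_config", "load_config"]

SCHEMA = "ehh-network/1"


class ConfigError(EhhError):
    """A configuration document violates the schema."""


def _check_fields(d: dict, path: str, required, optional=()):
    missing = [n for n in required if n not in d]
    if missing:
        raise ConfigError(f"{path}: missing required field {missing[0]!r}")
    unknown = [n for n in d if n not in required and n not in optional]
    if unknown:
        raise ConfigError(f"{path}: unknown field {unknown[0]!r}")


# -- rate / gate / channel / compartment / cell ------------------------------

def _rate_to_dict(r):
    if isinstance(r, NamedRate):
        return {"type": "named", "name": r.name}
    d = {"type": "rate", "f_t": r.f_t, "k0": float(r.k0), "k1": float(r.k1),
         "k2": float(r.k2)}
    if r.a != 1.0:
        d["a"] = float(r.a)
    if r.b != 0.0:
        d["b"] = float(r.b)
    return d


def _rate_from_dict(d, path):
    if not isinstance(d, dict) or "type" not in d:
        raise ConfigError(f"{path}: expected a rate object with a 'type' field")
    if d["type"] == "named":
        _check_fields(d, path, ("type", "name"))
        return NamedRate(d["name"])
    if d["type"] != "rate":
        raise ConfigError(f"{path}: unknown rate type {d['type']!r}")
    _check_fields(d, path, ("type", "f_t", "k0", "k1", "k2"), ("a", "b"))
    return RateFunction(
        f_t=int(d["f_t"]), k0=float(d["k0"]), k1=float(d["k1"]), k2=float(d["k2"]),
        a=float(d.get("a", 1.0)), b=float(d.get("b", 0.0)),
    )


def _gate_to_dict(g: GateSpec):
    d = {
        "name": g.name,
        "formulation": g.formulation,
        "rate1": _rate_to_dict(g.rate1),
        "rate2": _rate_to_dict(g.rate2),
        "exponent": g.exponent,
    }
    if g.driver != "v":
        d["driver"] = g.driver
    return d


def _gate_from_dict(d, path):
    _check_fields(d, path, ("name", "formulation", "rate1", "rate2", "exponent"), ("driver",))
    return GateSpec(
        name=d["name"],
        formulation=d["formulation"],
        rate1=_rate_from_dict(d["rate1"], f"{path}.rate1"),
        rate2=_rate_from_dict(d["rate2"], f"{path}.rate2"),
        exponent=int(d["exponent"]),
        driver=d.get("driver", "v"),
    )


def _channel_to_dict(ch: ChannelSpec):
    return {
        "name": ch.name,
        "g": float(ch.g),
        "e_rev": float(ch.e_rev),
        "gates": [_gate_to_dict(g) for g in ch.gates],
    }


def _channel_from_dict(d, path):
    _check_fields(d, path, ("name", "g", "e_rev", "gates"))
    return ChannelSpec(
        name=d["name"],
        g=float(d["g"]),
        e_rev=float(d["e_rev"]),
        gates=tuple(
            _gate_from_dict(g, f"{path}.gates[{i}]") for i, g in enumerate(d["gates"])
        ),
    )


def _comp_to_dict(c: CompartmentSpec):
    d = {
        "name": c.name,
        "C": float(c.C),
        "g_leak": float(c.g_leak),
        "e_leak": float(c.e_leak),
        "channels": [_channel_to_dict(ch) for ch in c.channels],
        "p_up": float(c.p_up),
        "has_gap": c.has_gap,
    }
    if c.aux_states:
        d["aux_states"] = [
            {"name": a.name, "channel": a.channel,
             "c_current": float(a.c_current), "c_self": float(a.c_self)}
            for a in c.aux_states
        ]
    return d


def _comp_from_dict(d, path):
    _check_fields(
        d, path,
        ("name", "C", "g_leak", "e_leak", "channels", "p_up", "has_gap"),
        ("aux_states",),
    )
    aux = []
    for i, a in enumerate(d.get("aux_states", [])):
        _check_fields(a, f"{path}.aux_states[{i}]", ("name", "channel", "c_current", "c_self"))
        aux.append(
            AuxStateSpec(
                name=a["name"], channel=int(a["channel"]),
                c_current=float(a["c_current"]), c_self=float(a["c_self"]),
            )
        )
    return CompartmentSpec(
        name=d["name"],
        C=float(d["C"]),
        g_leak=float(d["g_leak"]),
        e_leak=float(d["e_leak"]),
        channels=tuple(
            _channel_from_dict(ch, f"{path}.channels[{i}]")
            for i, ch in enumerate(d["channels"])
        ),
        p_up=float(d["p_up"]),
        has_gap=bool(d["has_gap"]),
        aux_states=tuple(aux),
    )


def _cell_to_dict(cell: CellSpec):
    return {
        "g_int": float(cell.g_int),
        "compartments": [_comp_to_dict(c) for c in cell.compartments],
    }


def _cell_from_dict(d, path):
    _check_fields(d, path, ("g_int", "compartments"))
    return CellSpec(
        compartments=tuple(
            _comp_from_dict(c, f"{path}.compartments[{i}]")
            for i, c in enumerate(d["compartments"])
        ),
        g_int=float(d["g_int"]),
    )


# -- stimuli and simulation config -------------------------------------------

def _stim_to_dict(key, s: StimulusSpec):
    d = {"cell": key[0], "compartment": key[1], "kind": s.kind}
    if s.kind == "constant":
        d["amplitude"] = float(s.amplitude)
    elif s.kind == "pulse":
        d.update(amplitude=float(s.amplitude), t_on=float(s.t_on), t_off=float(s.t_off))
    else:
        d.update(times=[float(t) for t in s.times], values=[float(v) for v in s.values])
    return d


def _stim_from_dict(d, path):
    kind = d.get("kind")
    if kind == "constant":
        _check_fields(d, path, ("cell", "compartment", "kind", "amplitude"))
        spec = StimulusSpec(kind="constant", amplitude=float(d["amplitude"]))
    elif kind == "pulse":
        _check_fields(d, path, ("cell", "compartment", "kind", "amplitude", "t_on", "t_off"))
        spec = StimulusSpec(
            kind="pulse", amplitude=float(d["amplitude"]),
            t_on=float(d["t_on"]), t_off=float(d["t_off"]),
        )
    elif kind == "series":
        _check_fields(d, path, ("cell", "compartment", "kind", "times", "values"))
        spec = StimulusSpec(
            kind="series",
            times=tuple(float(t) for t in d["times"]),
            values=tuple(float(v) for v in d["values"]),
        )
    else:
        raise ConfigError(f"{path}: unknown stimulus kind {kind!r}")
    return (int(d["cell"]), int(d["compartment"])), spec


def _sim_to_dict(cfg: SimulationConfig):
    d = {
        "dt": float(cfg.dt),
        "n_steps": int(cfg.n_steps),
        "record_stride": int(cfg.record_stride),
        "init": cfg.init,
        "v_init": float(cfg.v_init),
        "record_gates": cfg.record_gates,
    }
    if cfg.precision != "double":
        d["precision"] = cfg.precision
    if cfg.stimuli:
        d["stimuli"] = [_stim_to_dict(k, s) for k, s in sorted(cfg.stimuli.items())]
    return d


def _sim_from_dict(d, path):
    _check_fields(
        d, path, ("dt", "n_steps"),
        ("record_stride", "init", "v_init", "record_gates", "stimuli", "precision"),
    )
    stimuli = dict(
        _stim_from_dict(s, f"{path}.stimuli[{i}]")
        for i, s in enumerate(d.get("stimuli", []))
    )
    return SimulationConfig(
        dt=float(d["dt"]),
        n_steps=int(d["n_steps"]),
        stimuli=stimuli,
        record_stride=int(d.get("record_stride", 1)),
        init=d.get("init", "steady_state"),
        v_init=float(d.get("v_init", 0.0)),
        record_gates=bool(d.get("record_gates", False)),
        precision=d.get("precision", "double"),
    )


# -- weights ------------------------------------------------------------------

def _weights_to_dict(model: NetworkModel):
    if model.weight_source is not None and model.weight_source.get("kind") == "generated":
        return dict(model.weight_source)
    return {"kind": "explicit", "matrix": [[float(x) for x in row] for row in model.weights]}


def _weights_from_dict(d, path, n_cells):
    kind = d.get("kind")
    if kind == "explicit":
        _check_fields(d, path, ("kind", "matrix"))
        return np.array(d["matrix"], dtype=float), None
    if kind == "generated":
        _check_fields(d, path, ("kind", "dist", "key"), ("mu", "sigma", "symmetric"))
        from .connectivity import generate_weights

        kwargs = {k: d[k] for k in ("mu", "sigma") if k in d}
        w = generate_weights(
            n_cells, d["dist"], key=int(d["key"]),
            symmetric=bool(d.get("symmetric", False)), **kwargs,
        )
        return w, dict(d)
    raise ConfigError(f"{path}: unknown weights kind {kind!r}")


# -- top level -----------------------------------------------------------------

def export_config(model: NetworkModel, config: SimulationConfig) -> str:
    """Serialize a model + simulation config to the native JSON document."""
    doc = {
        "schema": SCHEMA,
        "model": {
            "gap": {"c0": float(model.c0), "c1": float(model.c1), "c2": float(model.c2)},
            "cells": [_cell_to_dict(c) for c in model.cells],
        },
        "simulation": _sim_to_dict(config),
    }
    if model.has_gap:
        doc["model"]["weights"] = _weights_to_dict(model)
    return json.dumps(doc, indent=2) + "\n"


def load_config(text: str):
    """Parse a native JSON document into ``(NetworkModel, SimulationConfig)``.

    Unknown fields are rejected with their JSON path; a model whose cells
    terminate gap junctions must carry a weight source.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as err:
        raise ConfigError(f"not valid JSON: {err}") from err
    _check_fields(doc, "$", ("schema", "model", "simulation"))
    if doc["schema"] != SCHEMA:
        raise ConfigError(f"$.schema: expected {SCHEMA!r}, got {doc['schema']!r}")
    _check_fields(doc["model"], "$.model", ("gap", "cells"), ("weights",))
    gap = doc["model"]["gap"]
    _check_fields(gap, "$.model.gap", ("c0", "c1", "c2"))
    cells = [
        _cell_from_dict(c, f"$.model.cells[{i}]")
        for i, c in enumerate(doc["model"]["cells"])
    ]
    any_gap = any(cell.gap_comp is not None for cell in cells)
    weights, source = None, None
    if "weights" in doc["model"]:
        weights, source = _weights_from_dict(
            doc["model"]["weights"], "$.model.weights", len(cells)
        )
    elif any_gap:
        raise ConfigError(
            "$.model: cells terminate gap junctions but no weight source is given"
        )
    model = NetworkModel(
        cells=cells,
        c0=float(gap["c0"]), c1=float(gap["c1"]), c2=float(gap["c2"]),
        weights=weights,
        weight_source=source,
    )
    sim = _sim_from_dict(doc["simulation"], "$.simulation")
    return model, sim
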