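"""Import of the Hodgkin-Huxley gate subset of NeuroML channel documents.

Only the three classic HH rate shapes are supported — they are exactly the
shapes the generalized rate function covers:

======================  ===============================================  ==========
NeuroML rate type       closed form                                      mapping
======================  ===============================================  ==========
HHSigmoidRate           ``rate / (1 + exp(-(v - midpoint)/scale))``      branch 2
HHExpRate               ``rate * exp((v - midpoint)/scale)``             branch 1
HHExpLinearRate         ``rate * x / (1 - exp(-x))``, x=(v-mid)/scale    branch 0
======================  ===============================================  ==========

Both the current type names and the older ``HH...Variable`` spellings are
accepted.  Anything else raises :class:`UnsupportedNeuroMLError` naming the
element — nothing is silently ignored.  Attribute values may carry unit
suffixes (``"10mV"``, ``"1per_ms"``); the numeric prefix is taken literally
under the library's consistent-unit contract.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET

from .model import EhhError, GateSpec, RateFunction

__all__ = [
    "UnsupportedNeuroMLError",
    "parse_rate_element",
    "parse_neuroml_gate",
    "parse_neuroml_channels",
]


class UnsupportedNeuroMLError(EhhError):
    """The document uses a NeuroML feature outside the supported subset."""


_SIGMOID = {"HHSigmoidRate", "HHSigmoidVariable"}
_EXP = {"HHExpRate", "HHExponentialRate", "HHExponentialVariable"}
_EXPLINEAR = {"HHExpLinearRate", "HHExpLinearVariable"}

_NUM = re.compile(r"^\s*([-+]?[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*([A-Za-z_]*)\s*$")


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _attr(elem, name: str) -> float:
    raw = elem.get(name)
    if raw is None:
        raise UnsupportedNeuroMLError(
            f"element <{_strip_ns(elem.tag)}> is missing attribute {name!r}"
        )
    m = _NUM.match(raw)
    if m is None:
        raise UnsupportedNeuroMLError(
            f"cannot parse attribute {name}={raw!r} of <{_strip_ns(elem.tag)}>"
        )
    return float(m.group(1))


def parse_rate_element(elem) -> RateFunction:
    """Map one NeuroML HH rate element to a :class:`RateFunction`."""
    kind = elem.get("type") or _strip_ns(elem.tag)
    rate, midpoint, scale = (_attr(elem, n) for n in ("rate", "midpoint", "scale"))
    if scale == 0:
        raise UnsupportedNeuroMLError(
            f"<{_strip_ns(elem.tag)}> type {kind!r}: scale must be non-zero"
        )
    if kind in _SIGMOID:
        return RateFunction(f_t=2, k0=rate, k1=midpoint, k2=1.0 / scale)
    if kind in _EXP:
        return RateFunction(f_t=1, k0=rate, k1=midpoint, k2=-1.0 / scale)
    if kind in _EXPLINEAR:
        return RateFunction(f_t=0, k0=rate / scale, k1=midpoint, k2=1.0 / scale)
    raise UnsupportedNeuroMLError(f"unsupported rate element type {kind!r}")


def parse_neuroml_gate(elem) -> GateSpec:
    """Map a NeuroML gate element (a document fragment) to a GateSpec.

    ``gateHHrates`` (forwardRate/reverseRate children) becomes an
    ``alpha_beta`` gate; ``gateHHtauInf`` (timeCourse/steadyState) becomes
    ``inf_tau``.  The ``instances`` attribute is the gate exponent.
    """
    if isinstance(elem, (str, bytes)):
        elem = ET.fromstring(elem)
    tag = _strip_ns(elem.tag)
    kind = elem.get("type") or tag
    children = {_strip_ns(c.tag): c for c in elem}
    exponent = int(float(elem.get("instances", "1")))
    name = elem.get("id", "gate")
    if kind in ("gateHHrates", "gate") and {"forwardRate", "reverseRate"} <= set(children):
        return GateSpec(
            name=name,
            formulation="alpha_beta",
            rate1=parse_rate_element(children["forwardRate"]),
            rate2=parse_rate_element(children["reverseRate"]),
            exponent=exponent,
        )
    if kind in ("gateHHtauInf", "gate") and {"timeCourse", "steadyState"} <= set(children):
        return GateSpec(
            name=name,
            formulation="inf_tau",
            rate1=parse_rate_element(children["steadyState"]),
            rate2=parse_rate_element(children["timeCourse"]),
            exponent=exponent,
        )
    raise UnsupportedNeuroMLError(
        f"unsupported gate element <{tag}> (type {kind!r}) with children "
        f"{sorted(children)}"
    )


def parse_neuroml_channels(source) -> list:
    """Parse every ``ionChannel`` of a NeuroML document into gate lists.

    Returns ``[(channel_id, [GateSpec, ...]), ...]``.  Conductance
    densities and reversal potentials live outside the channel document in
    NeuroML and are supplied by the native config instead.
    """
    if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("<"):
        root = ET.fromstring(source)
    else:
        root = ET.parse(source).getroot()
    out = []
    for chan in root.iter():
        if _strip_ns(chan.tag) not in ("ionChannel", "ionChannelHH"):
            continue
        gates = [
            parse_neuroml_gate(child)
            for child in chan
            if _strip_ns(child.tag).startswith("gate")
        ]
        out.append((chan.get("id", "channel"), gates))
    if not out:
        raise UnsupportedNeuroMLError("document contains no ionChannel elements")
    return out
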