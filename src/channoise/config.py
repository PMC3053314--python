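"""Declarative (YAML) configuration for schemes and simulations.

Keys carry explicit units in their names (``duration_ms``, ``diameter_um``,
``amplitude_ua_cm2``) to prevent unit bugs. A scheme document is either

.. code-block:: yaml

    name: k
    subunits:
      - {name: n, count: 4,
         alpha: {law: exp_linear, a: 0.01, b: 10.0, v0: -55.0},
         beta:  {law: exponential, a: 0.125, b: -80.0, v0: -65.0}}

or a general scheme with explicit states and a transition table:

.. code-block:: yaml

    name: two_state
    states: [closed, open]
    open_state: open
    transitions:
      - {from: closed, to: open, rate: {law: constant, a: 1.0}}
      - {from: open, to: closed, rate: {law: constant, a: 2.0}}
"""

from __future__ import annotations

import numpy as np
import yaml

from .errors import ConfigError
from .kinetics import ChannelScheme, SubunitSpec
from .rates import (
    RatePair,
    constant_rate,
    exp_linear_rate,
    exponential_rate,
    sigmoid_rate,
)

__all__ = ["rate_from_dict", "scheme_from_dict", "load_scheme", "load_config"]

_LAWS = {
    "exp_linear": lambda p: exp_linear_rate(p["a"], p["b"], p["v0"]),
    "exponential": lambda p: exponential_rate(p["a"], p["b"], p["v0"]),
    "sigmoid": lambda p: sigmoid_rate(p["a"], p["b"], p["v0"]),
    "constant": lambda p: constant_rate(p["a"]),
}


def rate_from_dict(doc: dict):
    try:
        law = doc["law"]
        return _LAWS[law](doc)
    except KeyError as exc:
        raise ConfigError(f"bad rate law document {doc!r}: {exc}") from exc


def scheme_from_dict(doc: dict) -> ChannelScheme:
    name = doc.get("name", "scheme")
    if "subunits" in doc:
        subs = []
        for s in doc["subunits"]:
            try:
                subs.append(
                    SubunitSpec(
                        name=s["name"], count=int(s["count"]),
                        rates=RatePair(alpha=rate_from_dict(s["alpha"]),
                                       beta=rate_from_dict(s["beta"])),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"bad subunit document {s!r}: {exc}") from exc
        return ChannelScheme.from_subunits(name, subs)
    if "states" in doc:
        states = list(doc["states"])
        try:
            open_state = states.index(doc["open_state"])
        except (KeyError, ValueError) as exc:
            raise ConfigError("general scheme needs a valid open_state") from exc
        idx = {s: i for i, s in enumerate(states)}
        trans = []
        for tr in doc.get("transitions", []):
            try:
                trans.append((idx[tr["from"]], idx[tr["to"]], rate_from_dict(tr["rate"])))
            except KeyError as exc:
                raise ConfigError(f"bad transition document {tr!r}: {exc}") from exc
        m = len(states)

        def build(v, _trans=trans, _m=m):
            a = np.zeros((_m, _m))
            for j, i, rate in _trans:
                a[i, j] += rate(v)
            np.fill_diagonal(a, -a.sum(axis=0))
            return a

        return ChannelScheme.from_rate_matrix(name, states, build, open_state)
    raise ConfigError("scheme document needs either 'subunits' or 'states'")


def load_scheme(path: str) -> ChannelScheme:
    with open(path) as fh:
        return scheme_from_dict(yaml.safe_load(fh))


def load_config(path: str) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return doc
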