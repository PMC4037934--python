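"""Bundled case-study networks with verified reference attractors.

* ``aba_reduced`` — the 7-node reduced abscisic-acid (ABA) stomatal-closure
  signaling network (drought response in plant guard cells).  Its sole
  synchronous attractor is a 5-state limit cycle.  Nodes are declared in the
  column order of the published attractor table, so the reference cycle rows
  are literal state strings.
* ``tlgl_reduced`` — the 6-node reduced T cell large granular lymphocyte
  (T-LGL) leukemia survival-signaling network.  Under general asynchronous
  update it has two fixed points: healthy (Apoptosis ON) and diseased T-LGL
  (S1P and FLIP ON, everything else OFF).
* ``toy_chain`` / ``toy_oscillator`` — tiny synthetic networks for examples
  and tests.

Both biological rule sets are the *unrepaired* models: the published repair
clauses ("or not KOUT" on Ca2+c, "or S1P" on DISC) are absent, so the repair
and elimination machinery can rediscover them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dynamics import Attractor, find_synchronous_attractor, synchronous_step
from .network import BooleanNetwork, NetworkState, parse_rules

ABA_REDUCED_RULES = """\
# Reduced ABA-induced stomatal closure network (7 nodes).
# Node order follows the published attractor table columns.
CIS = Ca2+c
Ca2+c = (CaIM or CIS) and not Ca2+ATPase
Ca2+ATPase = Ca2+c
CaIM = not Depolar
Closure = KOUT and Ca2+c
Depolar = (not KOUT) or Ca2+c
KOUT = Depolar
"""

# the 5-state synchronous limit cycle, in successor order
ABA_CYCLE = ("1010111", "0000001", "0001000", "0101010", "1110011")

TLGL_REDUCED_RULES = """\
# Reduced T-LGL leukemia survival signaling network (6 nodes).
S1P = not (Ceramide or Apoptosis)
FLIP = not (DISC or Apoptosis)
FAS = not (S1P or Apoptosis)
Ceramide = FAS and not (S1P or Apoptosis)
DISC = (Ceramide or (FAS and not FLIP)) and not Apoptosis
Apoptosis = DISC or Apoptosis
"""

TLGL_STATE = "110000"  # diseased fixed point: S1P = FLIP = ON, rest OFF
APOPTOSIS_STATE = "000001"  # healthy fixed point: Apoptosis ON

TOY_CHAIN_RULES = """\
# A -> B -> C chain with a self-sustaining source.
A = A
B = A
C = B
"""

TOY_OSCILLATOR_RULES = """\
# negative feedback pair: 4-state synchronous limit cycle
A = not B
B = A
"""

_RULES = {
    "aba_reduced": ABA_REDUCED_RULES,
    "tlgl_reduced": TLGL_REDUCED_RULES,
    "toy_chain": TOY_CHAIN_RULES,
    "toy_oscillator": TOY_OSCILLATOR_RULES,
}

FIXTURE_NAMES = tuple(_RULES)


@dataclass
class Fixture:
    name: str
    network: BooleanNetwork
    attractors: list[Attractor]
    rules_text: str


def _rotate_cycle(att: Attractor, first: NetworkState) -> Attractor:
    i = att.states.index(first)
    return Attractor(att.kind, att.states[i:] + att.states[:i], att.scheme)


def load_fixture(name: str) -> Fixture:
    """Parse a bundled network and verify its reference attractors."""
    try:
        text = _RULES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    net = parse_rules(text)
    attractors: list[Attractor] = []

    if name == "aba_reduced":
        first = net.state_from_string(ABA_CYCLE[0])
        att = _rotate_cycle(find_synchronous_attractor(net, first), first)
        if att.state_strings != ABA_CYCLE:
            raise RuntimeError("ABA fixture failed its reference-cycle check")
        attractors.append(att)
    elif name == "tlgl_reduced":
        for s in (APOPTOSIS_STATE, TLGL_STATE):
            st = net.state_from_string(s)
            if synchronous_step(net, st) != st:
                raise RuntimeError(
                    f"T-LGL fixture failed its fixed-point check for {s}"
                )
            attractors.append(Attractor("steady_state", (st,), "synchronous"))
    elif name == "toy_chain":
        for s in ("000", "111"):
            st = net.state_from_string(s)
            if synchronous_step(net, st) != st:
                raise RuntimeError("toy_chain fixture fixed-point check failed")
            attractors.append(Attractor("steady_state", (st,), "synchronous"))
    else:  # toy_oscillator
        st = net.state_from_string("00")
        attractors.append(find_synchronous_attractor(net, st))

    return Fixture(name, net, attractors, text)


def fixture_rules(name: str) -> str:
    """Rule-file text of a bundled network."""
    if name not in _RULES:
        raise KeyError(f"unknown fixture {name!r}")
    return _RULES[name]
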