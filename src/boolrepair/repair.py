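"""Attractor repair through compensatory rule modifications.

Given a network, an attractor of the undamaged network, and a damage (one
node clamped ON or OFF), this module finds minimal *additions* to the update
rules of other nodes that make the damage-modified attractor an attractor of
the damaged network.

The admissible modifications scaffold on the original rule: each appends one
clause involving a regulator the node did not previously have (``new``),
optionally paired with one existing regulator (``orig``).  There are two
template families of six rows each:

=====  =================================  ================================
row    AND family (forces ON -> OFF)      OR family (forces OFF -> ON)
=====  =================================  ================================
1      ``f = ... and NEW``                ``f = ... or NEW``
2      ``f = ... and not NEW``            ``f = ... or not NEW``
3      ``f = ... and (ORIG or NEW)``      ``f = ... or (ORIG and NEW)``
4      ``f = ... and (not NEW or ORIG)``  ``f = ... or (not NEW and ORIG)``
5      ``f = ... and (not NEW or not      ``f = ... or (not NEW and not
       ORIG)``                            ORIG)``
6      ``f = ... and (NEW or not ORIG)``  ``f = ... or (NEW and not ORIG)``
=====  =================================  ================================

In the template labels, a regulator written as ``a`` ("absent") must be OFF
and one written as ``p`` ("present") must be ON.  For the *new* regulator
this occupancy requirement at the corrected state is implied by evaluating
the composed rule, which is how viability is checked here.  For the paired
*original* regulator the occupancy is a standing side-condition: it must
hold in every state over which the modification is evaluated (so across a
limit-cycle target, rows 3-6 reduce to rows 1-2 plus the requirement that
the paired regulator keep its labeled value throughout the cycle).  An
AND-family clause can only turn a 1 into a 0 and an OR-family clause a 0
into a 1, so modifications never disturb updates in the opposite direction.

A single state can always be stabilized this way provided some admissible
new regulator exists (i.e. no sensitive node is already regulated by every
candidate); a limit cycle may fail in three ways:

* **case 1** — some node needs both an ON->OFF and an OFF->ON correction;
* **case 2** — no single modification covers all of a node's corrections;
* **case 3** — corrections are satisfiable in isolation, but every candidate
  breaks some originally-correct transition elsewhere in the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dynamics import (
    Attractor,
    find_synchronous_attractor,
    synchronous_attractors,
    synchronous_step,
)
from .network import (
    And,
    BooleanNetwork,
    Expr,
    NetworkState,
    Not,
    Or,
    Var,
    expr_to_text,
    parse_expression,
)

AND_FAMILY = "and"
OR_FAMILY = "or"

ON_TO_OFF = "on_to_off"
OFF_TO_ON = "off_to_on"


class RepairError(ValueError):
    """Raised for invalid repair inputs."""


class ContractionError(RepairError):
    """Projected limit-cycle states cannot be contracted to a single cycle."""


class PoolExhaustedError(RepairError):
    """A sensitive node is already regulated by every admissible candidate."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Damage:
    """One node clamped to a constant (knockout or constitutive expression)."""

    node: str
    value: int

    def __post_init__(self):
        if self.value not in (0, 1):
            raise RepairError(f"damage value must be 0 or 1, got {self.value!r}")


@dataclass
class DamagedAttractorTarget:
    """The damage-modified target: states plus each state's required successor.

    ``mode`` is ``steady_state`` (single fixed point), ``limit_cycle``
    (cyclic successor order over >= 1 contracted states) or ``superset``
    (single fixed point summarizing a limit cycle's transient activity).
    """

    states: tuple[NetworkState, ...]
    desired_next: dict[NetworkState, NetworkState]
    mode: str

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise RepairError("target states must be distinct")
        if set(self.desired_next) != set(self.states):
            raise RepairError("desired_next must cover exactly the target states")
        if set(self.desired_next.values()) != set(self.states):
            raise RepairError("desired_next must permute the target states")

    def desired_bit(self, state: NetworkState, node_index: int) -> int:
        return self.desired_next[state].bits[node_index]


@dataclass
class SensitivityRecord:
    """A node deregulated by the damage within the target attractor."""

    node: str
    mismatches: list[tuple[NetworkState, int, int]]  # (state, current, desired)
    correction_types: frozenset[str]


@dataclass(frozen=True)
class RuleModification:
    """One template instance: family, row, new regulator, optional paired one.

    ``context``, when set, names a guard sub-expression of the target's rule
    (e.g. ``"not Apoptosis"``): the clause is appended inside it, i.e. to the
    other operand of the rule's top-level connective.
    """

    target: str
    family: str  # "and" | "or"
    row: int  # 1..6
    new_regulator: str
    orig_regulator: str | None = None
    context: str | None = None

    def __post_init__(self):
        if self.family not in (AND_FAMILY, OR_FAMILY):
            raise RepairError(f"unknown template family {self.family!r}")
        if not 1 <= self.row <= 6:
            raise RepairError(f"template row must be 1..6, got {self.row}")
        if (self.row >= 3) != (self.orig_regulator is not None):
            raise RepairError("rows 3-6 require orig_regulator; rows 1-2 forbid it")

    def clause_expr(self) -> Expr:
        new = Var(self.new_regulator)
        orig = Var(self.orig_regulator) if self.orig_regulator else None
        inner = Or if self.family == AND_FAMILY else And
        if self.row == 1:
            return new
        if self.row == 2:
            return Not(new)
        if self.row == 3:
            return inner(orig, new)
        if self.row == 4:
            return inner(Not(new), orig)
        if self.row == 5:
            return inner(Not(new), Not(orig))
        return inner(new, Not(orig))

    def clause_value(self, new_bit: int, orig_bit: int | None = None) -> int:
        if self.row == 1:
            return new_bit
        if self.row == 2:
            return 1 - new_bit
        assert orig_bit is not None
        if self.family == AND_FAMILY:  # inner connective is OR
            if self.row == 3:
                return orig_bit | new_bit
            if self.row == 4:
                return (1 - new_bit) | orig_bit
            if self.row == 5:
                return (1 - new_bit) | (1 - orig_bit)
            return new_bit | (1 - orig_bit)
        if self.row == 3:
            return orig_bit & new_bit
        if self.row == 4:
            return (1 - new_bit) & orig_bit
        if self.row == 5:
            return (1 - new_bit) & (1 - orig_bit)
        return new_bit & (1 - orig_bit)

    def compose(self, base: Expr) -> Expr:
        """Wrap ``base`` (the "..." operand) with this modification's clause."""
        clause = self.clause_expr()
        return And(base, clause) if self.family == AND_FAMILY else Or(base, clause)

    def rewritten_rule(self, net: BooleanNetwork) -> str:
        return expr_to_text(compose_expression(net, self))

    def to_dict(self, net: BooleanNetwork | None = None) -> dict:
        d = {
            "target": self.target,
            "family": self.family,
            "row": self.row,
            "new_regulator": self.new_regulator,
            "orig_regulator": self.orig_regulator,
            "context": self.context,
        }
        if net is not None:
            d["rewritten_rule"] = self.rewritten_rule(net)
        return d

    def sort_key(self):
        return (self.family, self.row, self.new_regulator,
                self.orig_regulator or "")


@dataclass
class RepairResult:
    """Outcome of the repair algorithm.

    ``viable`` maps each sensitive node to every admissible modification that
    realizes all of its required transitions; ``chosen`` holds one concrete
    modification per node when requested.
    """

    status: str  # already_stable | repaired | failure_case_{1,2,3}
    target: DamagedAttractorTarget | None = None
    sensitive: list[SensitivityRecord] = field(default_factory=list)
    viable: dict[str, list[RuleModification]] = field(default_factory=dict)
    chosen: dict[str, RuleModification] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def num_modifications(self) -> int:
        return len(self.chosen) if self.chosen else len(self.viable)

    def to_dict(self, net: BooleanNetwork | None = None) -> dict:
        return {
            "status": self.status,
            "target_states": [str(s) for s in (self.target.states if self.target else ())],
            "mode": self.target.mode if self.target else None,
            "sensitive_nodes": [r.node for r in self.sensitive],
            "viable": {
                node: [m.to_dict(net) for m in mods]
                for node, mods in self.viable.items()
            },
            "chosen": {node: m.to_dict(net) for node, m in self.chosen.items()},
            "diagnostics": {
                k: v for k, v in self.diagnostics.items()
            },
        }


# ---------------------------------------------------------------------------
# Target construction
# ---------------------------------------------------------------------------

def _force_bit(state: NetworkState, idx: int, value: int) -> NetworkState:
    if state.bits[idx] == value:
        return state
    bits = list(state.bits)
    bits[idx] = value
    return NetworkState(tuple(bits))


def _largest_cycle(walk: list[NetworkState]) -> list[NetworkState]:
    """Largest simple cycle obtainable from a closed walk with repeats."""
    seen: dict[NetworkState, int] = {}
    for j, s in enumerate(walk):
        if s in seen:
            i = seen[s]
            a = _largest_cycle(walk[i:j])
            b = _largest_cycle(walk[:i] + walk[j:])
            return a if len(a) >= len(b) else b
        seen[s] = j
    return walk


def project_attractor(
    net: BooleanNetwork,
    att: Attractor,
    damage: Damage,
    *,
    on_collision: str = "error",
) -> DamagedAttractorTarget:
    """Force the damaged bit in every attractor state and contract duplicates.

    A steady state projects to a single fixed-point target.  For limit
    cycles, projections that land on an already-present state close the cycle
    early; redundant self-loop requirements created that way are dropped.  If
    duplicated states demand two different successors, ``on_collision`` picks
    the behavior: ``"error"`` raises :class:`ContractionError`;
    ``"largest"`` keeps the largest simple cycle that can be formed from the
    projected walk (possibly discarding states).
    """
    if damage.node not in net.index:
        raise RepairError(f"unknown damaged node {damage.node!r}")
    idx = net.index[damage.node]
    projected = [_force_bit(s, idx, damage.value) for s in att.states]

    if att.kind == "steady_state" or len(projected) == 1:
        s = projected[0]
        return DamagedAttractorTarget((s,), {s: s}, "steady_state")

    distinct = list(dict.fromkeys(projected))
    n = len(projected)
    succ: dict[NetworkState, set[NetworkState]] = {s: set() for s in distinct}
    for i, s in enumerate(projected):
        succ[s].add(projected[(i + 1) % n])
    for s, targets in succ.items():
        if len(targets) > 1:
            targets.discard(s)  # a duplicate closing the cycle on itself
    if all(len(t) == 1 for t in succ.values()):
        if len(distinct) == 1:
            s = distinct[0]
            return DamagedAttractorTarget((s,), {s: s}, "steady_state")
        # closed walk with single successors => one cycle covering all states
        order = [distinct[0]]
        while (nxt := next(iter(succ[order[-1]]))) != order[0]:
            order.append(nxt)
        if len(order) != len(distinct):
            raise ContractionError(
                "projected states do not form a single cycle"
            )
        desired = {s: next(iter(succ[s])) for s in order}
        return DamagedAttractorTarget(tuple(order), desired, "limit_cycle")

    if on_collision == "largest":
        cycle = _largest_cycle(projected)
        if len(cycle) == 1:
            s = cycle[0]
            return DamagedAttractorTarget((s,), {s: s}, "steady_state")
        desired = {
            s: cycle[(i + 1) % len(cycle)] for i, s in enumerate(cycle)
        }
        return DamagedAttractorTarget(tuple(cycle), desired, "limit_cycle")
    raise ContractionError(
        "damage merges limit-cycle states with inconsistent successors; "
        "pass on_collision='largest' to contract to the largest formable cycle"
    )


def superset_state(
    net: BooleanNetwork,
    att: Attractor,
    damage: Damage | None = None,
    *,
    on_fraction: float | None = None,
) -> NetworkState:
    """Single-state summary of a limit cycle: transiently-ON nodes are ON.

    By default a node is ON in the superset if it is ON in *any* attractor
    state (bitwise OR).  ``on_fraction`` switches to a threshold rule: ON iff
    the node is ON in at least that fraction of the states.  The damaged bit,
    if a damage is given, is forced to the clamp value afterwards.
    """
    n = net.n
    if on_fraction is None:
        bits = [0] * n
        for s in att.states:
            bits = [b | x for b, x in zip(bits, s.bits)]
    else:
        counts = [sum(s.bits[i] for s in att.states) for i in range(n)]
        bits = [
            1 if c >= on_fraction * len(att.states) else 0 for c in counts
        ]
    state = NetworkState(tuple(bits))
    if damage is not None:
        state = _force_bit(state, net.index[damage.node], damage.value)
    return state


def superset_target(
    net: BooleanNetwork, att: Attractor, damage: Damage | None = None, **kw
) -> DamagedAttractorTarget:
    s = superset_state(net, att, damage, **kw)
    return DamagedAttractorTarget((s,), {s: s}, "superset")


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------

def identify_sensitive_nodes(
    net: BooleanNetwork,
    damage: Damage,
    target: DamagedAttractorTarget,
) -> list[SensitivityRecord]:
    """Nodes whose clamped-network update misses the desired next bit.

    Each node is updated from each target state with all other nodes held
    constant; a mismatch against the desired successor marks it sensitive.
    The damaged node itself always matches (its bit is the clamp value in
    every target state).
    """
    clamped = net.clamp(damage.node, damage.value)
    records = []
    for name in net.node_names:
        if name == damage.node:
            continue
        i = net.index[name]
        mismatches = []
        kinds = set()
        for s in target.states:
            cur = clamped.evaluate_node(name, s)
            des = target.desired_bit(s, i)
            if cur != des:
                mismatches.append((s, cur, des))
                kinds.add(ON_TO_OFF if (cur, des) == (1, 0) else OFF_TO_ON)
        if mismatches:
            records.append(SensitivityRecord(name, mismatches, frozenset(kinds)))
    return records


# ---------------------------------------------------------------------------
# Modification search
# ---------------------------------------------------------------------------

def candidate_pool(
    net: BooleanNetwork,
    node: str,
    damage: Damage | None = None,
    *,
    include_damaged: bool = False,
) -> list[str]:
    """Admissible new regulators: nodes playing no part in ``node``'s rule.

    The node itself qualifies when it does not self-regulate.  The damaged
    node is excluded by default (clamped, hence constant) but can be allowed.
    """
    regs = set(net.functions[node].regulators)
    pool = [n for n in net.node_names if n not in regs]
    if damage is not None and not include_damaged:
        pool = [n for n in pool if n != damage.node]
    return pool


# required value of the paired original regulator, by (family, row):
# "a" regulators must be absent (0), "p" regulators present (1)
_ORIG_REQUIRED = {
    (AND_FAMILY, 3): 0, (AND_FAMILY, 4): 0,
    (AND_FAMILY, 5): 1, (AND_FAMILY, 6): 1,
    (OR_FAMILY, 3): 1, (OR_FAMILY, 4): 1,
    (OR_FAMILY, 5): 0, (OR_FAMILY, 6): 0,
}


def _viable_over_states(
    net: BooleanNetwork,
    node: str,
    states: Sequence[NetworkState],
    desired: Sequence[int],
    family: str,
    pool: Iterable[str],
) -> list[RuleModification]:
    """All template instances whose composed rule hits ``desired`` everywhere.

    The composed value at a state is ``f(s) AND clause(s)`` or
    ``f(s) OR clause(s)``; ``f`` is evaluated once per state and the clause
    from the state's bits, so the search is linear in candidates x states.
    Rows 3-6 additionally require the paired original regulator to hold its
    labeled occupancy (a = OFF, p = ON) in every evaluated state.
    """
    f = net.functions[node]
    envs = [net.env(s) for s in states]
    fvals = [f.evaluate(e) for e in envs]
    origs = f.regulators
    out: list[RuleModification] = []
    combine = (lambda a, b: a & b) if family == AND_FAMILY else (lambda a, b: a | b)
    for new in pool:
        new_bits = [s.bits[net.index[new]] for s in states]
        for row in (1, 2):
            mod = RuleModification(node, family, row, new)
            if all(
                combine(fv, mod.clause_value(nb)) == d
                for fv, nb, d in zip(fvals, new_bits, desired)
            ):
                out.append(mod)
        for orig in origs:
            orig_bits = [s.bits[net.index[orig]] for s in states]
            for row in (3, 4, 5, 6):
                req = _ORIG_REQUIRED[(family, row)]
                if any(ob != req for ob in orig_bits):
                    continue
                mod = RuleModification(node, family, row, new, orig)
                if all(
                    combine(fv, mod.clause_value(nb, ob)) == d
                    for fv, nb, ob, d in zip(fvals, new_bits, orig_bits, desired)
                ):
                    out.append(mod)
    return out


def enumerate_modifications(
    net: BooleanNetwork,
    node: str,
    state: NetworkState,
    desired: int,
    pool: Iterable[str] | None = None,
    damage: Damage | None = None,
) -> list[RuleModification]:
    """Every template instance producing ``desired`` for ``node`` at ``state``.

    When the unmodified rule already produces ``desired``, the result is the
    set of modifications whose clause is neutral there (preservation mode);
    otherwise only the family able to force the correction contributes.
    """
    if pool is None:
        pool = candidate_pool(net, node, damage)
    else:
        regs = set(net.functions[node].regulators)
        bad = [p for p in pool if p in regs]
        if bad:
            raise RepairError(
                f"candidate pool contains current regulators {bad!r}"
            )
    mods = []
    for family in (AND_FAMILY, OR_FAMILY):
        mods.extend(
            _viable_over_states(net, node, [state], [desired], family, pool)
        )
    return sorted(mods, key=RuleModification.sort_key)


def _family_for(record: SensitivityRecord) -> str:
    return AND_FAMILY if record.correction_types == {ON_TO_OFF} else OR_FAMILY


def repair(
    net: BooleanNetwork,
    att: Attractor | DamagedAttractorTarget,
    damage: Damage,
    mode: str = "limit_cycle",
    *,
    rng: np.random.Generator | None = None,
    include_damaged: bool = False,
    case_rule: str = "mismatch",
    on_collision: str = "error",
) -> RepairResult:
    """Run the repair algorithm for one attractor and one damage.

    ``mode`` is ``limit_cycle`` (preserve the contracted damage-modified
    cycle), ``steady_state`` (the attractor is, or is treated as, a single
    state) or ``superset`` (collapse the cycle to its transiently-ON summary
    and stabilize that).  If ``rng`` is given, one viable modification per
    sensitive node is chosen uniformly at random into ``chosen``.

    ``case_rule`` controls failure-case 2/3 discrimination: ``"mismatch"``
    re-runs the search on the node's mismatch states only; ``"transition"``
    re-runs it omitting states where the node's desired next state equals its
    current one.
    """
    if isinstance(att, DamagedAttractorTarget):
        target = att
    elif mode == "superset":
        target = superset_target(net, att, damage)
    elif mode == "steady_state" or att.kind == "steady_state":
        target = project_attractor(net, att, damage)
        if target.mode == "limit_cycle":
            raise RepairError("steady_state mode given a multi-state attractor")
    else:
        target = project_attractor(net, att, damage, on_collision=on_collision)

    sensitive = identify_sensitive_nodes(net, damage, target)
    result = RepairResult(status="already_stable", target=target,
                          sensitive=sensitive)
    if not sensitive:
        return result

    both = [r.node for r in sensitive if len(r.correction_types) == 2]
    if both:
        result.status = "failure_case_1"
        result.diagnostics = {
            "nodes": both,
            "reason": "node(s) require both ON->OFF and OFF->ON corrections",
        }
        return result

    single_state = target.mode in ("steady_state", "superset")
    viable: dict[str, list[RuleModification]] = {}
    failing: list[tuple[str, str, dict]] = []
    for rec in sensitive:
        node = rec.node
        pool = candidate_pool(net, node, damage, include_damaged=include_damaged)
        if not pool:
            if single_state:
                raise PoolExhaustedError(
                    f"node {node!r} is regulated by every admissible candidate; "
                    "the single-state stabilization guarantee does not apply"
                )
            failing.append((node, "failure_case_2",
                            {"reason": "no admissible new regulator"}))
            continue
        family = _family_for(rec)
        idx = net.index[node]
        desired = [target.desired_bit(s, idx) for s in target.states]
        mods = _viable_over_states(net, node, target.states, desired,
                                   family, pool)
        if mods:
            viable[node] = sorted(mods, key=RuleModification.sort_key)
            continue
        # empty intersection: discriminate failure case 2 vs 3
        if case_rule == "mismatch":
            sub = [s for s, _, _ in rec.mismatches]
        elif case_rule == "transition":
            sub = [
                s for s in target.states
                if target.desired_bit(s, idx) != s.bits[idx]
            ]
        else:
            raise RepairError(f"unknown case_rule {case_rule!r}")
        sub_desired = [target.desired_bit(s, idx) for s in sub]
        sub_mods = _viable_over_states(net, node, sub, sub_desired, family, pool)
        if sub_mods:
            failing.append((node, "failure_case_3", {
                "reason": "corrections satisfiable but every candidate breaks "
                          "a correct transition",
                "correction_only_candidates": len(sub_mods),
            }))
        else:
            failing.append((node, "failure_case_2", {
                "reason": "no single modification covers all corrections",
            }))

    if failing:
        # Table-1 style: the first failing node (canonical order) sets the status
        order = {n: i for i, n in enumerate(net.node_names)}
        failing.sort(key=lambda t: order[t[0]])
        node, status, info = failing[0]
        result.status = status
        result.viable = viable
        result.diagnostics = {
            "node": node,
            **info,
            "all_failing": {n: s for n, s, _ in failing},
        }
        return result

    result.status = "repaired"
    result.viable = viable
    if rng is not None:
        result.chosen = {
            node: mods[int(rng.integers(len(mods)))]
            for node, mods in viable.items()
        }
    return result


# ---------------------------------------------------------------------------
# Applying and verifying modifications
# ---------------------------------------------------------------------------

def compose_expression(net: BooleanNetwork, mod: RuleModification) -> Expr:
    """The target node's rewritten expression under ``mod``.

    Without a context the whole original expression is the wrapped operand.
    With a context, the rule's top-level connective must have one operand
    structurally equal to the parsed context (the guard); the clause wraps
    the other operand and the guard is reattached outside.
    """
    f = net.functions[mod.target]
    if mod.new_regulator in f.regulators:
        raise RepairError(
            f"{mod.new_regulator!r} already regulates {mod.target!r}"
        )
    if mod.orig_regulator is not None and mod.orig_regulator not in f.regulators:
        raise RepairError(
            f"{mod.orig_regulator!r} is not a current regulator of {mod.target!r}"
        )
    base = f.expression
    if mod.context is None:
        return mod.compose(base)
    guard = parse_expression(mod.context)
    if not isinstance(base, (And, Or)):
        raise RepairError(
            f"rule for {mod.target!r} has no top-level connective to match "
            f"context {mod.context!r}"
        )
    ctor = type(base)
    if base.right == guard:
        return ctor(mod.compose(base.left), guard)
    if base.left == guard:
        return ctor(guard, mod.compose(base.right))
    raise RepairError(
        f"context {mod.context!r} is not an operand of the top-level "
        f"connective of the rule for {mod.target!r}"
    )


def apply_modifications(
    net: BooleanNetwork, mods: Sequence[RuleModification]
) -> BooleanNetwork:
    """Apply one modification per (distinct) target node; returns a new network."""
    targets = [m.target for m in mods]
    if len(set(targets)) != len(targets):
        raise RepairError("at most one modification per node may be applied")
    out = net
    for mod in mods:
        out = out.with_function(mod.target, compose_expression(net, mod))
    return out


def verify_repair(
    net_repaired: BooleanNetwork,
    damage: Damage,
    target: DamagedAttractorTarget,
    *,
    census_cap: int = 14,
) -> tuple[bool, dict]:
    """Check every target transition under the clamped repaired network.

    The report records per-state outcomes and, when the state space is small
    enough (N <= ``census_cap``), the repaired clamped network's full
    synchronous attractor list, so newly introduced attractors are visible.
    """
    clamped = net_repaired.clamp(damage.node, damage.value)
    mismatch = []
    for s in target.states:
        nxt = synchronous_step(clamped, s)
        if nxt != target.desired_next[s]:
            mismatch.append(
                {"state": str(s), "got": str(nxt),
                 "expected": str(target.desired_next[s])}
            )
    ok = not mismatch
    report: dict = {"stable": ok, "mismatches": mismatch}
    if net_repaired.n <= census_cap:
        census = synchronous_attractors(clamped)
        target_set = set(target.states)
        report["attractors"] = [a.to_dict() for a in census]
        report["new_attractors"] = [
            a.to_dict() for a in census if set(a.states) != target_set
        ]
    return ok, report


# ---------------------------------------------------------------------------
# Attractor elimination
# ---------------------------------------------------------------------------

def eliminate_attractor(
    net: BooleanNetwork,
    bad_state: NetworkState,
    target_node: str,
    context: str | None = None,
    pool: Iterable[str] | None = None,
) -> list[RuleModification]:
    """Modifications of ``target_node`` that destroy a fixed point.

    ``bad_state`` must be a steady state of ``net``; every returned
    modification flips ``target_node``'s update there, so the state is no
    longer fixed.  This is the single-state dual of repair: there are no
    preservation constraints.
    """
    if target_node not in net.index:
        raise RepairError(f"unknown node {target_node!r}")
    if synchronous_step(net, bad_state) != bad_state:
        raise RepairError(f"state {bad_state} is not a steady state")
    i = net.index[target_node]
    desired = 1 - bad_state.bits[i]
    if pool is None:
        pool = candidate_pool(net, target_node)
    family = OR_FAMILY if desired == 1 else AND_FAMILY
    mods = []
    raw = _viable_over_states(
        net, target_node, [bad_state], [desired], family, pool
    )
    for mod in raw:
        mod = RuleModification(
            mod.target, mod.family, mod.row, mod.new_regulator,
            mod.orig_regulator, context=context,
        )
        # with a context guard the clause lands inside it; re-check the flip
        modified = net.with_function(target_node, compose_expression(net, mod))
        if modified.evaluate_node(target_node, bad_state) == desired:
            mods.append(mod)
    return sorted(mods, key=RuleModification.sort_key)


# ---------------------------------------------------------------------------
# Convenience entry point
# ---------------------------------------------------------------------------

def repair_from_start(
    net: BooleanNetwork,
    start: NetworkState,
    damage: Damage,
    mode: str = "limit_cycle",
    **kw,
) -> RepairResult:
    """Find a synchronous attractor from ``start`` and repair it."""
    att = find_synchronous_attractor(net, start)
    return repair(net, att, damage, mode, **kw)
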