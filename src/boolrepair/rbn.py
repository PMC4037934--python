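"""Random Boolean network (Kauffman NK) damage/repair experiments.

Each node of an N-node network receives k distinct regulators drawn
uniformly (self-regulation allowed) and a truth table whose 2^k output rows
are independent Bernoulli(p) draws (p = 0.5: unbiased).  A trial finds a
synchronous attractor from a random start state, damages a uniformly random
node, checks whether the damage-modified attractor survives, and — if not —
runs the repair algorithm, applying one uniformly random viable modification
per sensitive node and verifying the result.

Two damage rules are available.  The default, ``"knockout"``, clamps the
selected node OFF regardless of its activity, so a node that is OFF
throughout the attractor leaves it trivially intact; this is the protocol
behind the published resilience and repair-effort statistics (steady-state
resilience near 81/70/63% for k = 1/2/3).  ``"opposite"`` clamps the node
against its attractor activity — OFF if it is ever ON, otherwise ON — so
the damaged bit always flips; steady-state resilience then drops to
roughly exp(-k/2).

All randomness derives from a single master seed through named substreams
(network generation / start state / damaged node / repair choice), so every
ensemble is reproducible.
"""

from __future__ import annotations

import functools
import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import SYNCHRONOUS, Attractor, _step_int
from .network import (
    And,
    BooleanNetwork,
    Const,
    Expr,
    NetworkState,
    Not,
    Or,
    UpdateFunction,
    Var,
)
from .repair import (
    Damage,
    apply_modifications,
    project_attractor,
    repair,
    verify_repair,
)


@dataclass(frozen=True)
class RBNSpec:
    """Ensemble parameters: size N, in-degree k, truth-table bias p."""

    n: int
    k: int
    p: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > self.n:
            raise ValueError(f"k={self.k} exceeds network size N={self.n}")
        if not 0 < self.p < 1:
            raise ValueError("bias p must lie strictly between 0 and 1")


@dataclass
class ExperimentRecord:
    """One damage/repair trial."""

    n: int
    k: int
    attractor_kind: str  # steady_state | limit_cycle
    attractor_length: int
    damaged_node: str
    clamp_value: int
    stable: bool
    repair_status: str | None = None
    num_modifications: int | None = None
    failure_case: int | None = None
    verified: bool | None = None


def _minterm(regs: Sequence[str], row: int, k: int) -> Expr:
    lits = []
    for j, r in enumerate(regs):
        bit = (row >> (k - 1 - j)) & 1
        lits.append(Var(r) if bit else Not(Var(r)))
    return functools.reduce(And, lits)


def generate_rbn(
    spec: RBNSpec, rng: np.random.Generator | None = None
) -> BooleanNetwork:
    """Draw one random Boolean network from the ensemble.

    Update functions are materialized as the full disjunctive normal form of
    the drawn truth table, so every nominal regulator appears literally in
    the expression (except for the all-zero table, which is the constant 0).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    names = [f"x{i}" for i in range(spec.n)]
    funcs = {}
    for name in names:
        regs = [names[j] for j in rng.choice(spec.n, size=spec.k, replace=False)]
        table = (rng.random(1 << spec.k) < spec.p).astype(int)
        ones = [r for r in range(1 << spec.k) if table[r]]
        if not ones:
            expr: Expr = Const(0)
        else:
            expr = functools.reduce(
                Or, (_minterm(regs, r, spec.k) for r in ones)
            )
        funcs[name] = UpdateFunction(expr)
    return BooleanNetwork(names, funcs)


def _find_attractor_ints(comp, n: int, x0: int) -> list[int]:
    seen: dict[int, int] = {}
    traj: list[int] = []
    x = x0
    while x not in seen:
        seen[x] = len(traj)
        traj.append(x)
        x = _step_int(comp, x, n)
    return traj[seen[x]:]


def damage_attractor_trial(
    net: BooleanNetwork,
    rng_start: np.random.Generator,
    rng_node: np.random.Generator,
    rng_choice: np.random.Generator,
    *,
    k: int,
    damage_rule: str = "knockout",
) -> ExperimentRecord:
    """Run one damage/stability/repair trial on ``net``."""
    if damage_rule not in ("knockout", "opposite"):
        raise ValueError(f"unknown damage_rule {damage_rule!r}")
    n = net.n
    comp = net.compiled()
    x0 = int(rng_start.integers(1 << n))
    cycle = _find_attractor_ints(comp, n, x0)
    kind = "steady_state" if len(cycle) == 1 else "limit_cycle"
    att = Attractor(
        kind, tuple(NetworkState.from_int(v, n) for v in cycle), SYNCHRONOUS
    )

    node_idx = int(rng_node.integers(n))
    node = net.node_names[node_idx]
    mask = 1 << (n - 1 - node_idx)
    if damage_rule == "knockout":
        clamp_value = 0
    else:
        ever_on = any(v & mask for v in cycle)
        clamp_value = 0 if ever_on else 1
    damage = Damage(node, clamp_value)

    clamped = net.clamp(node, clamp_value)
    ccomp = clamped.compiled()
    forced = [
        (v | mask) if clamp_value else (v & ~mask) for v in cycle
    ]
    rec = ExperimentRecord(
        n=n, k=k, attractor_kind=kind, attractor_length=len(cycle),
        damaged_node=node, clamp_value=clamp_value, stable=False,
    )

    if kind == "steady_state":
        ad = forced[0]
        if _step_int(ccomp, ad, n) == ad:
            rec.stable = True
            return rec
        target = project_attractor(net, att, damage)
        rr = repair(net, target, damage, mode="steady_state", rng=rng_choice)
        rec.repair_status = rr.status
        if rr.status == "repaired":
            repaired = apply_modifications(net, list(rr.chosen.values()))
            ok, _ = verify_repair(repaired, damage, target, census_cap=0)
            rec.verified = ok
            rec.num_modifications = len(rr.chosen)
        return rec

    # limit cycle: stable iff every projected state's clamped successor is
    # again a projected state (the surviving states contain a limit cycle)
    pset = set(forced)
    if all(_step_int(ccomp, v, n) in pset for v in pset):
        rec.stable = True
        return rec
    target = project_attractor(net, att, damage, on_collision="largest")
    if target.mode == "steady_state":
        # collisions collapsed the cycle to one state; repair it as such
        rr = repair(net, target, damage, mode="steady_state", rng=rng_choice)
    else:
        rr = repair(net, target, damage, mode="limit_cycle", rng=rng_choice)
    rec.repair_status = rr.status
    if rr.status == "already_stable":
        # the contracted target is stable even though the full set was not
        rec.stable = True
        return rec
    if rr.status == "repaired":
        repaired = apply_modifications(net, list(rr.chosen.values()))
        ok, _ = verify_repair(repaired, damage, target, census_cap=0)
        rec.verified = ok
        rec.num_modifications = len(rr.chosen)
    elif rr.status.startswith("failure_case_"):
        rec.failure_case = int(rr.status[-1])
    return rec


def run_trials(
    n: int, k: int, reps: int, seed: int, p: float = 0.5,
    damage_rule: str = "knockout",
) -> list[ExperimentRecord]:
    """``reps`` independent trials at one (N, k) combination."""
    master = np.random.SeedSequence(seed, spawn_key=(n, k))
    records = []
    for child in master.spawn(reps):
        g_net, g_start, g_node, g_choice = (
            np.random.default_rng(s) for s in child.spawn(4)
        )
        net = generate_rbn(RBNSpec(n, k, p), g_net)
        records.append(
            damage_attractor_trial(net, g_start, g_node, g_choice, k=k,
                                   damage_rule=damage_rule)
        )
    return records


def records_frame(records: Sequence[ExperimentRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def _se(frac: float, count: int) -> float:
    return float(np.sqrt(frac * (1 - frac) / count)) if count else float("nan")


def summarize(df: pd.DataFrame) -> dict:
    """Per-(N, k) resilience, repair and failure-case statistics."""
    out = {}
    for (n, k), grp in df.groupby(["n", "k"]):
        entry: dict = {"n": int(n), "k": int(k), "trials": len(grp)}
        for kind in ("steady_state", "limit_cycle"):
            sub = grp[grp.attractor_kind == kind]
            e: dict = {"count": len(sub), "fraction_of_trials":
                       len(sub) / len(grp)}
            if len(sub):
                stable = float(sub.stable.mean())
                e["resilient_fraction"] = stable
                e["resilient_se"] = _se(stable, len(sub))
                unstable = sub[~sub.stable]
                rep = unstable[unstable.repair_status == "repaired"]
                e["unstable_count"] = len(unstable)
                if len(unstable):
                    e["repaired_fraction"] = len(rep) / len(unstable)
                    fails = unstable[unstable.failure_case.notna()]
                    e["failure_case_counts"] = {
                        int(c): int((fails.failure_case == c).sum())
                        for c in (1, 2, 3)
                    }
                if len(rep):
                    e["mean_modifications"] = float(
                        rep.num_modifications.mean()
                    )
                    e["verified_fraction"] = float(rep.verified.mean())
            entry[kind] = e
        out[f"N{n}_k{k}"] = entry
    return out


def run_experiment(
    ns: Sequence[int],
    ks: Sequence[int],
    reps: int,
    seed: int,
    p: float = 0.5,
    damage_rule: str = "knockout",
) -> tuple[pd.DataFrame, dict]:
    """Full ensemble sweep; returns the per-trial table and a summary."""
    records: list[ExperimentRecord] = []
    for n in ns:
        for k in ks:
            records.extend(run_trials(n, k, reps, seed, p, damage_rule))
    df = records_frame(records)
    return df, summarize(df)


def write_outputs(df: pd.DataFrame, summary: dict, records_path, summary_path):
    df.to_csv(records_path, sep="\t", index=False)
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
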