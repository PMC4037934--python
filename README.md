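# boolrepair

Stabilize attractors of damaged Boolean networks through compensatory
interaction modifications.

## The problem

Boolean networks are a standard framework for modeling signal transduction
and gene regulation: each node *x<sub>i</sub>* is ON or OFF and updates by a
logical rule *x<sub>i</sub>(t+τ<sub>i</sub>) = f<sub>i</sub>(x₁(t), …,
x<sub>N</sub>(t))*.  The long-run behaviors are the network's **attractors**
— steady states, limit cycles, or (under stochastic update) complex
attractors — and in cellular models they correspond to phenotypes such as
apoptosis or unregulated growth.

**Damage** — a mutation that leaves a node permanently OFF (knockout) or
permanently ON (constitutive expression) — is modeled by clamping that
node's update rule to a constant.  Clamping deregulates the damaged node's
targets and can cascade until the system lands in a very different
attractor.  Rather than reversing the damage or clamping further nodes,
`boolrepair` **modifies regulatory interactions**: it finds minimal
*additions* to the update rules of the deregulated nodes so that the
damage-modified attractor *a<sup>d</sup>* (the original attractor states
with the damaged bit forced, merged states contracted) is again an attractor
of the damaged network.

Each admissible modification appends one clause to an existing rule using
one **new** regulator, optionally paired with one **existing** regulator:
six AND-family templates (`f = … and NEW`, `f = … and not NEW`,
`f = … and (ORIG or NEW)`, …) that force an ON→OFF correction, and six
mirror-image OR-family templates for OFF→ON corrections.  Any single state
can be stabilized this way whenever no deregulated node is already regulated
by every undamaged node; limit cycles can additionally fail in three
characteristic ways (a node needing both correction directions; no single
modification covering all of a node's corrections; corrections that
unavoidably break originally-correct transitions).  The same machinery runs
in reverse to *eliminate* an unwanted steady state, and a limit cycle can
always be collapsed to its **superset** (every transiently-ON node set ON)
and stabilized as a steady state.

The package includes:

* a parser/serializer for `NODE = expr` rule files (AND/OR/NOT grammar),
* synchronous, random-order-asynchronous and general-asynchronous dynamics,
  state transition graphs, the GA Markov transition matrix **T**, and
  attractor/basin analysis via terminal strongly connected components
  (cross-checked against **T**<sup>m</sup>),
* the repair algorithm, failure classification and attractor elimination,
* Kauffman NK random-network ensembles reproducing the published damage /
  resilience / repair statistics,
* bundled case studies: the 7-node reduced abscisic-acid (ABA) stomatal
  closure network and the 6-node reduced T-LGL leukemia network,
* a CLI: `boolrepair attractors | stg | repair | eliminate | rbn-sim`.

## Worked example

Knock out CaIM (plasma-membrane Ca²⁺ influx) in the reduced ABA network and
repair its 5-state limit cycle:

```sh
boolrepair repair --rules aba_reduced --damage CaIM=0 --mode limit_cycle
```

prints (abridged):

```json
{
  "status": "repaired",
  "mode": "limit_cycle",
  "sensitive_nodes": ["Ca2+c"],
  "viable": {
    "Ca2+c": [
      {"family": "or", "row": 2, "new_regulator": "KOUT",
       "rewritten_rule": "(CaIM or CIS) and not Ca2+ATPase or not KOUT"},
      {"family": "or", "row": 5, "new_regulator": "KOUT",
       "orig_regulator": "CaIM", "rewritten_rule":
       "(CaIM or CIS) and not Ca2+ATPase or not KOUT and not CaIM"}
    ]
  },
  "verification_of_first_viable": {"stable": true, "new_attractors": []}
}
```

Only cytosolic calcium (`Ca2+c`) is deregulated by the knockout, and
appending `or not KOUT` to its rule restores every transition of the cycle:
KOUT is OFF in exactly the two states where CaIM's activation was needed,
and ON elsewhere, so the new clause fires only where the correction is
required.  Verification confirms the repaired, damaged network has no other
attractor in its 128-state space.  Damage to `Depolar` instead exits with
code 1 and `"status": "failure_case_2"`: no single added clause can cover
all of the required corrections.

The T-LGL case runs in reverse — eliminating the diseased fixed point
(S1P = FLIP = ON, all else OFF) by letting S1P activate the death-inducing
complex DISC:

```sh
boolrepair eliminate --rules tlgl_reduced --state 110000 --target DISC \
    --context "not Apoptosis"
boolrepair attractors --rules tlgl_reduced --scheme ga
```

The second command reports the two fixed points of the unmodified model and
the basin split `{"exclusive": [3, 36], "shared": 25}`: of the 64 states,
36 always reach apoptosis, 3 always reach the leukemic state, 25 can reach
either.  After applying the `or S1P` modification (inside the `and not
Apoptosis` guard), the apoptosis state is the only attractor and its basin
is the whole state space.

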