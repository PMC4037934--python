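# Methods

## Model

A Boolean network is a list of named nodes, each with a logical update rule
over the current states of its regulators.  The canonical state order is
declaration order in the rule file; a state is a bit string in that order,
indexed as an integer with the first node as the most significant bit.

Three update schemes are implemented.  *Synchronous*: all nodes update each
step (a deterministic map on the 2^N states).  *Random order asynchronous*
(ROA): each round draws a fresh permutation of the nodes and updates them
sequentially with the latest values.  *General asynchronous* (GA): one
uniformly random node updates per step, a Markov chain whose one-step
matrix **T** has T_ij = (number of nodes taking state i to state j)/N.
Fixed points — states where every node's rule returns its current value —
are identical across all three schemes; limit cycles are
scheme-dependent.  Attractors of the stochastic schemes are the terminal
strongly connected components (SCCs) of the scheme's transition graph.  For
GA the package computes them from the sparse nonzero structure of **T**
and cross-checks against the matrix-power criterion: after m > 10^3 steps
(computed by repeated squaring) the columns carrying probability mass above
10^-5 must be exactly the terminal-SCC states, and the row masses must
reproduce the reachability-based basin labels.  A state's *basin label* is
the set of attractors reachable from it; a basin is *exclusive* when that
set is a singleton.

Damage is a clamp: the damaged node's rule is replaced by a constant 0
(knockout) or 1 (constitutive expression).

## Repair

Given an attractor of the undamaged network and a damage, the target
a^d is built by forcing the damaged bit in every attractor state.  States
of a limit cycle that become identical are contracted; a projection that
lands on an already-present state closes the cycle early and the redundant
self-successor requirement is dropped.  If merged states demand two
different successors the contraction is ambiguous: the default is an
explicit error, and the ensemble harness instead keeps the largest simple
cycle obtainable from the projected closed walk (`on_collision="largest"`),
accepting the loss of the discarded states.  A limit cycle can also be
collapsed to its *superset* — the single state in which every node that is
ON anywhere in the cycle is ON — and stabilized as a steady state; a
threshold variant (ON in at least a given fraction of the cycle's states)
is available but OR is the default.

A node is *sensitive* if, updated from some target state with all other
nodes held fixed, the clamped network gives a value different from the
desired successor's bit; only regulatory targets of the damaged node can be
sensitive.  Each sensitive node must be made robust by appending one clause
to its rule, drawn from twelve templates: an AND family used for ON→OFF
corrections and an OR family for OFF→ON ones, each with two single-regulator
rows (`… and NEW`, `… and not NEW`; `… or NEW`, `… or not NEW`) and four
rows pairing the new regulator with one existing regulator.

### Template semantics

The templates label regulators `a` (must be absent/OFF) or `p` (must be
present/ON).  For the **new** regulator this occupancy at a corrected state
is exactly the condition for the clause to force the correction, so it is
implied by evaluating the composed rule.  For the paired **original**
regulator the occupancy is enforced as a standing side-condition in *every*
state over which the modification is evaluated, not just the corrected
ones.  This choice is deliberate and load-bearing: with occupancy required
only at corrected states, paired templates can exploit an existing
regulator that changes value across the cycle as a free phase signal, and
the reduced ABA model's KOUT knockout (among others) would be classified
repairable — contradicting the published classification, which this
stricter reading reproduces exactly for all seven knockouts.  Under it a
paired row is equivalent to its single-regulator row plus the occupancy
requirement; paired rows still enlarge the catalogue of biologically
distinct interventions but not the set of repairable cases.

A modification is *viable* for a node when the composed rule produces the
desired next bit in every target state — corrections forced where needed,
already-correct transitions preserved.  Repair succeeds when every
sensitive node has at least one viable modification; the repaired network
applies exactly one modification (one new regulatory edge) per sensitive
node, all simultaneously.  Verification re-checks every target transition
under the clamped repaired network and, for small networks, enumerates all
synchronous attractors so newly introduced attractors are visible.

Single states (steady-state and superset targets) can always be stabilized
provided some admissible new regulator exists — the candidate pool is every
node not currently regulating the target (the target itself qualifies when
it does not self-regulate; the damaged node is excluded by default since a
clamped regulator is constant).  If a sensitive node is regulated by every
admissible candidate the package raises an explicit error naming it.  Limit
cycles fail in three recorded classes: **case 1**, a node needs both
correction directions; **case 2**, no single modification covers all of a
node's corrections; **case 3**, corrections are coverable in isolation but
every candidate breaks a correct transition elsewhere.  Cases 2 and 3 are
discriminated by re-running the search restricted to the node's mismatch
states (an alternative restriction — omitting states where the node's
desired next state equals its current one — is switchable via
`case_rule="transition"`).  When several nodes fail, the first in
canonical order determines the reported status; diagnostics list all.

Attractor *elimination* is the single-state dual: given an unwanted fixed
point, enumerate the modifications of a chosen node that flip its update
there (no preservation constraints).  A `context` argument confines the
modification inside a guard: for a rule of the form `W and G` (or `W or
G`), `context="G"` wraps `W`, leaving the guard outermost — used in the
T-LGL case so repairs stay subordinate to the overarching OFF signal from
apoptosis.

## Random-ensemble protocol

Random networks draw, per node, k distinct regulators uniformly (self
allowed) and 2^k independent Bernoulli(p) truth-table outputs, p = 0.5
(each rule is materialized as the table's full disjunctive normal form).  A
trial: find a synchronous attractor from one uniformly random start state;
select a uniformly random node; damage it; test stability; if unstable,
repair, choosing one viable modification per sensitive node uniformly at
random, and verify.  A steady state is stable when its damage-modified
state is a fixed point of the clamped network; a limit cycle is stable when
every projected state's clamped successor is again a projected state (the
surviving states then contain a limit cycle, covering state merging).

Two damage rules are provided.  The default, **knockout**, clamps the
selected node OFF regardless of its activity; a node already OFF throughout
the attractor then leaves it trivially intact.  This is the protocol under
which the package reproduces the reference resilience statistics
(steady-state resilience near 81/70/63% and limit-cycle resilience near
78/54/27% for k = 1/2/3 at N = 20) and repair-effort statistics (mean
modifications per successful k = 2 repair of 1.50 for steady states and
1.48 for limit cycles, pooled over N ∈ {10, 20, 30}).  The alternative,
**opposite**, clamps the node against its attractor activity (OFF if ever
ON, otherwise ON) so the damaged bit always flips; steady-state resilience
then falls to about exp(-k/2) ≈ 61/37/22% — each regulatory target of the
damaged node is deregulated independently with probability 1/2 and the
damaged node acquires on average k targets.  Destabilized steady states
are repaired and verified with 100% success under both rules, as the
single-state guarantee requires.

All randomness flows from one master seed through named substreams
(network generation / start state / damaged node / repair choice) via
`numpy` SeedSequence spawning, so every trial is independently
reproducible.

### Problem sizes

The ensembles are sized for stable statistics on a single CPU: the per-k
sweeps use N = 20 with 3000 networks per k in the acceptance script (8000
in the test suite), and the k = 2 repair-effort pool uses 5000 networks per
size over N ∈ {10, 20, 30}, yielding upwards of 1000 successful repairs of
each attractor type.  Binomial standard errors at these sizes are below
1.5 percentage points for the headline fractions (about 3 points for the
small steady-state subpopulation at k = 3).

### What the generator does and does not emulate

The ensemble reproduces the homogeneous-in-degree, unbiased Kauffman NK
family: fixed k per node, independent uniform truth tables, no topological
correlations.  Real signaling networks differ — long-tailed out-degree
distributions, canalizing rules, biased activity — so passing ensemble
statistics demonstrates correctness of the machinery on that family, not
quantitative predictions for biological networks; those are probed instead
by the two bundled case studies with published rules.  One published
ensemble quantity is knowingly not reproduced: the distribution of
limit-cycle failures over the three classes at k = 3 (reported as
case-3-dominated; here case 1 dominates at both N = 10 and N = 20).  The
class composition is sensitive to cycle-length distributions and hence to
the unprinted size grid averaged over; the failure *rates* themselves
(about 1%, 18% and 54% of sampled limit cycles for k = 1/2/3) do
reproduce.

## Numerical and design notes

* Exhaustive state-space operations are capped (default 20 nodes
  synchronous, 16 asynchronous) with an explicit override.
* ROA transition graphs are exhaustive over all N! permutations up to
  N = 7 and sampled (10·N! capped at 10^5 permutations, seeded, flagged
  `approximate`) beyond; ROA limit sets are reported as terminal SCCs with
  no traversal probabilities.
* **T** is stored sparse; powers use repeated squaring; rows are validated
  to sum to 1 within 10^-9.
* Expression evaluation and the per-node truth-table compilation used by
  the simulators are cross-checked by construction (the table is built from
  the expression); parse → serialize → parse is a truth-table fixed point.
* Tie-breaks: viable modification lists are sorted (family, row, new
  regulator, original regulator); random choices use the trial's dedicated
  substream.

## Known limitations

* Repairs only add clauses; removing terms, multi-node simultaneous damage,
  and joint optimization across several attractors are out of scope.
* Limit-cycle repair guarantees nothing outside the target states; basin
  shapes may change, which is why verification reports the full attractor
  census for small networks.
* The contraction of colliding projected cycles to the largest formable
  cycle discards states; the strict mode refuses instead.
* ROA analyses for N > 7 are sampled and may miss rare transitions.
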