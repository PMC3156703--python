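# Methods

## The model class

`spermnet` implements synchronous multi-valued logical networks.  A network
has `N` nodes; node `i` takes integer levels `0 .. a_i - 1` (arity `a_i`,
2 or 3 here) and carries an ordered list of regulators together with a
complete truth table `F_i`.  The global state `σ(t) = (σ_1, .., σ_N)`
advances deterministically and synchronously:

    σ_i(t+1) = F_i(σ_{j1}(t), .., σ_{jk}(t))

Because the state space is finite and the update is a function, the
transition system is a functional graph: every trajectory is a transient
followed by a periodic cycle (attractor), and the state space partitions
exactly into basins of attraction.  All analysis in the package —
simulation with first-revisit cycle detection, exhaustive attractor
enumeration, in-silico knockouts, Derrida-map criticality — is built on
this structure.

States are encoded bijectively as mixed-radix integers (C order, last node
least significant).  Exhaustive enumeration computes the successor of every
index blockwise (vectorized table lookups), collapses the successor map by
pointer doubling until every image lies on a cycle (verified directly, not
assumed from an iteration count), labels the cycles, and tallies exact
basin sizes with a bincount.  The memory budget is a hard ceiling
(default 2^28 states): larger spaces are refused, never silently sampled.

## The speract network

The packaged model has 22 nodes: the constant stimulus (speract), its
receptor (SR), guanylate cyclase (GC), cGMP, the cGMP-gated K+ channel
(KCNG), K+ permeability (dK), membrane potential (V, ternary:
hyperpolarized / resting / depolarized), the Na+/Ca2+ exchanger (NCE), the
Na+/H+ exchanger (NHE), intracellular pH (pHi), soluble adenylate cyclase
(sAC), cAMP, phosphodiesterase (PDE), the HCN channel, a cAMP-gated Ca2+
channel (cAMPCC), the high- and low-voltage-activated Ca2+ channels (HVA,
LVA, ternary: inactive / closed / open), intracellular Ca2+ (ternary:
basal / tonic / supratonic), the Ca2+-activated Cl- and K+ channels (CaCC,
CaKC), the constitutive Ca2+ pumps (CaP), and Cl- permeability (dCl).
Eighteen nodes are binary, four ternary, so the state space has
2^18 · 3^4 = 21,233,664 configurations.

Constant inputs (speract, CaP) are modeled with a self-regulator and a
constant/identity table, which keeps the speract-on and speract-off halves
of the state space closed under the dynamics.

### Reconstructed truth tables

The original model's tables were distributed through a web page that is no
longer reachable; only their logical structure is documented (roster,
interaction signs, the cAMP table, the dimensions of the Ca table).  The
packaged tables are therefore reconstructed: each table is generated from
an explicit qualitative rule whose discrete parameters (dominance weights,
gating thresholds) were calibrated until the model reproduces every
published dynamical outcome, and then frozen.  Equivalence with the
original tables is claimed only at the level of those outcomes, not
bit-for-bit.  The main rules:

- **Membrane potential.**  Hyperpolarizing (dK, CaKC, dCl) and
  depolarizing (HCN, cAMPCC, open LVA/HVA, and a weak constitutive
  receptor current present whenever speract is bound) drives are combined
  as a weighted difference; V moves to hyperpolarized or depolarized when
  the difference passes a threshold, otherwise toward resting.  Two
  dominance refinements fix the behaviour at balanced drive: with the K+
  conductance open and no depolarizing conductance at all, a resting
  potential collapses toward E_K (hyperpolarized); and at exactly balanced
  drive with an open low-threshold channel at resting V, the T-type
  current prevails (depolarization).  V reads its own level to express
  these rules.
- **LVA (T-type-like).**  Inactivation is removed by hyperpolarization;
  a primed (closed) channel opens as a rebound after a hyperpolarized
  step, or as a window current at rest in an alkalinized cell with basal
  calcium; sustained depolarization does not close a primed channel;
  recovery from inactivation requires hyperpolarization and basal calcium,
  with alkalinization extending the gate to tonic calcium.
- **HVA (L-type-like).**  Opens on depolarization with calcium-dependent
  facilitation (tonic calcium, or cAMP priming) and is blocked by
  supratonic calcium (calcium-dependent inactivation); recovery from
  inactivation requires hyperpolarization and basal calcium, with the
  gate overridden when cAMP is high (PKA-type facilitation).
- **Calcium.**  A net-flux score adds influx (open LVA dominating, open
  HVA, a speract-dependent tonic influx) and subtracts extrusion (NCE and
  the constitutive pumps, combined as a maximum — the extrusion pathways
  saturate); the supratonic level requires an open Ca2+ channel (LVA, HVA
  or cAMPCC), a mild positive balance gives the tonic level, deficits
  decay toward basal.
- **cAMP.**  PDE is a dominant inhibitor: if PDE is active, cAMP is off
  next step regardless of sAC; otherwise cAMP is produced by sAC and
  sustains itself (self-input).
- **HCN.**  Activated by hyperpolarization, but only with a cyclic
  nucleotide (cGMP or cAMP) present — the channel is cyclic-nucleotide
  gated.
- **CaKC.**  A voltage-dependent calcium-activated K+ channel: it opens on
  depolarization once calcium is at least tonic.  CaCC opens on
  supratonic calcium and acts on V through the Cl- permeability node.

One documented interaction was dropped during calibration: the inhibition
of guanylate cyclase by elevated pHi.  No table choice we found retains it
while reproducing the published attractor landscape; in the packaged model
GC follows the occupied receptor alone, and the pathway's negative
feedback is carried entirely by the calcium branch.

## Node deletions

"Deleting" a network element clamps its node to level 0 (absent / closed /
inactive) by replacing its table with the constant function; the table
domain and every other table are untouched.  This matches the
pharmacological blockage the deletions model, and from step 1 onward the
clamped node holds its level in every trajectory.  The six packaged presets
clamp dK, LVA, PDE, CaCC, CaKC and HVA.

## Phenotype readouts

A trajectory's phenotype is read off the calcium node: attractor period,
number of supratonic (level 2) attractor states, their fraction of the
period, the delay (in steps, with the initial state at t = 0) until the
first supratonic state ("never" is an explicit value, not a sentinel
number), and whether calcium oscillates on the attractor at all.  Ensemble
readouts (the mean-calcium time course and the delay comparison between
wild type and the HVA deletion) draw initial states uniformly from the
speract-on sector with a fixed seed and are bit-reproducible.

## Criticality analysis

The Derrida map is estimated by sampling base states uniformly, flipping
exactly `m` distinct nodes to uniformly chosen other levels, advancing both
states one synchronous step, and averaging the number of differing nodes.
Distances are reported as fractions of N; the slope at the origin is kept
on the raw node-count scale (the expected number of changed nodes caused by
a single-node perturbation), which is scale-free.  Any level change counts
as distance 1 — no ordinal weighting.  The regime is ordered / critical /
chaotic as the slope is below / at / above 1 (default tolerance 0.05).

`exact_sensitivity` is the deterministic cross-check.  Under the uniform
measure on the full state space the node levels are independent, so the
exact average over all states and all single-node perturbations factorizes
into per-truth-table row averages; the "exhaustive" mode computes that
closed form at the cost of the table sizes only.  The sampled mode
enumerates every single perturbation of each sampled base state; tests
verify the two agree and that the Monte-Carlo slope converges to the exact
value.  Base states for the packaged model's Derrida map are drawn from the
full state space (both speract sectors); a speract-on-only mode is
available.

Random Boolean networks (N nodes, K distinct inputs each, output bias p)
serve as ordered/critical/chaotic calibration references; their ensemble
sensitivity is checked against the annealed approximation 2p(1-p)K.

## Numerical and design choices

- Synchronous update only; no asynchronous or continuous-time mode.
- Attractor cycles are canonicalized by rotating the minimal encoded state
  to the front, so attractor identity is independent of the entry point.
- The transient is the number of steps strictly before the first state
  that belongs to the cycle.
- Enumeration verifies cyclicity of the pointer-doubled image directly;
  at most 64 doublings (2^64 steps) are ever needed.
- Model files are plain JSON with explicit truth-table rows; reading
  validates completeness (the missing input tuple is named on error) and
  all structural invariants.  Writes are atomic (temp file + rename).
- A content hash of the canonicalized model JSON pins results to the
  frozen tables.

## Calibration outcome

With the frozen tables the model reproduces: the wild-type period-4
attractor with supratonic fraction 1/4 from the basal speract-on state;
the exact partition of all 21,233,664 states into 11 attractors — six
speract-off point attractors and five active ones, four of period 4 and
one of period 8; suppression of calcium oscillations under the dK
deletion; loss of all supratonic states at unchanged period under the LVA
deletion; an unchanged calcium pattern under the CaCC deletion; the
period-11 attractor under the PDE deletion; a longer mean delay to the
first supratonic state (and a slower ensemble calcium rise) without HVA;
and a Derrida slope at the origin of about 1.06 (critical regime).

Three published outcomes are not met by the frozen tables and are left as
failing checks rather than weakened: the PDE-deletion attractor carries
three supratonic states per period instead of two (fraction 3/11, not
2/11); and the CaKC deletion yields attractors of period 9 (from the
basal state; 4, 9 or 10 across random speract-on states) instead of a
uniform period 8, so its supratonic density (2/9) does not exceed 1/4.
Within the rule family explored, every table change that repaired the
CaKC phenotype destroyed part of the 11-attractor landscape; the published
model evidently satisfies both, so this is a limitation of the
reconstruction, not of the published result.  The period-8 basin
(about 0.8 million states) is smaller than every period-4 basin but about
a third of their mean rather than the published "roughly one tenth"; this
statistic is reported, not asserted.

## Problem sizes used in the test suite

The full landscape enumeration (21.2 million states) runs once in the
acceptance path (a few minutes on one CPU).  Sampled checks use seeded
ensembles: 1000 initial states for the delay and mean-calcium comparisons,
300 for the CaKC-deletion period check, 10^5 perturbation pairs for the
Derrida slope.  Property tests on the generic engine use small fixture
networks (identity, copy-rings, a binary-clock/ternary-counter toggle)
whose ground truth is enumerable by brute force.

## What the packaged model does and does not show

The packaged tables reproduce the published discrete outcomes, and the
engine's conclusions about them are exact (the state space is enumerated,
not sampled).  The model remains a coarse-grained logical caricature of
flagellar signaling: one time step is an abstract signaling delay, not a
measured interval; levels are qualitative; and agreement with the published
outcomes does not imply the tables equal the original, unpublished ones —
several table choices may satisfy the same constraints.  Conclusions about
real sperm physiology inherit all the idealizations of the discrete
formalism.
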