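# Methods

## Scope and model overview

`dgnet` models the dentate gyrus microcircuit reduced to its four
numerically dominant cell types — granule cells (GC, excitatory principal
cells), mossy cells (MC, excitatory hilar cells), basket cells (BC,
perisomatic inhibition) and HIPP cells (dendritic inhibition) — at a 2000:1
reduction of the anatomical counts.  The remaining interneuron classes
(AAC, MOPP, HICAP, IS) are excluded: their physiological data are too
sparse to constrain a model, and they are a small minority of the circuit.
Three stages are implemented: connectivity generation, conductance-based
network simulation, and small-world graph analysis.

## Connectivity generation

Cells sit on a single normalized septotemporal axis; population `p` of size
`n` occupies the lattice `(i + 0.5)/n`, so every population spans [0, 1]
with even spacing.  One connection rule per (pre-type → post-type) pair
specifies

- **divergence** — the exact out-degree of every presynaptic cell,
- **pool size** — the number of nearest postsynaptic cells (by axis
  distance) forming the candidate pool,
- **center exclusion** — the nearest pool members to skip (used by MC→GC,
  which avoids the 50 GCs closest to the mossy cell, and MC→BC).

Targets are drawn uniformly without replacement from the pool, so each
rule produces a simple directed graph with exact out-degrees, and mean
convergence equals `pre_count × divergence / post_count` identically —
the convergence column of the connection table is conserved by
construction, not statistically.  Distance ties break toward the lower
index, which on an even lattice is equivalent to clamping the pool window
inside the population (no wraparound; the axis models a strip of tissue).
Autapses are always excluded; for the same-type rules (MC→MC, BC→BC) the
presynaptic cell is removed from its own pool after the window is taken.

Two published count ambiguities are resolved in favour of the convergence
table, which is the tighter constraint: the BC count is 6 (83.33 = 500/6
and 1.2 = 6·100/500 are inconsistent with 5), and the GC→HIPP divergence
is 3 (mean convergence 250 = 500·3/6).  Both are configurable.

**Modes.**  Healthy mode applies the rule table only; it contains no GC→GC
rule (granule cells are not directly interconnected in healthy tissue) and
no BC→HIPP rule.  Pathological mode emulates two epilepsy-associated
changes: mossy-fiber sprouting (each GC gains `sprouting_degree` recurrent
GC→GC contacts, default 2, drawn from its 100 nearest GCs) and mossy-cell
loss (all edges of `mc_loss` randomly chosen MCs removed, default 0).

**Randomness.**  A single integer seed; every rule draws from its own
deterministic substream (`default_rng([seed, pre_code, post_code])`), so
adding or removing a rule does not perturb the draws of any other rule.
Degree statistics are seed-invariant; only the identity of the sampled
targets changes.

## Cell models

Each cell is a soma plus identical dendrites split into four serial
sections (proximal → distal), giving 9/17/17/13 compartments for
GC/MC/BC/HIPP.  Geometry defaults: GC soma 10 µm × 10 µm (the small
granule-cell soma), larger somata for MC/BC/HIPP; dendritic sections 50 µm
long with diameters tapering distally, uniform within a section.
Membrane: specific capacitance 1 µF/cm², leak 0.1 mS/cm² (membrane time
constant 10 ms), axial resistivity 150 Ω·cm.

Active currents are classic Hodgkin–Huxley transient Na and
delayed-rectifier K with two per-type degrees of freedom: a common
depolarizing voltage shift of all rate functions (positions the spike
threshold) and the Na reversal potential (positions the spike peak).
Rates run at three times the classic values.  Channel density is maximal
at the soma (Na 250, K 60 mS/cm²) and decays along the dendrite
(× 0.3 / 0.1 / 0 / 0 per section): the spike initiates at the soma and
invades the dendrites decrementally, so recorded spike peaks decrease
monotonically from soma to distal section.  Fully passive dendrites would
also attenuate but are more easily masked by local synaptic depolarization
at the stimulated section; the weakly active gradient makes the
attenuation ordering robust.

**Calibration.**  Published membrane landmarks per type (rest / threshold /
peak, mV): GC −70.44 / −39.44 / +37.14; MC −60.11 / −39.05 / +46.72;
BC −60 / −38.86 / +46.87; HIPP −70.67 / −42.67 / +76.53.  The leak
reversal of every compartment is solved analytically so the target rest is
an exact fixed point of the membrane equations.  The kinetic shift and Na
reversal are then tuned against a single-cell somatic current clamp
(amplitude derived from the cell's input conductance) until the measured
onset potential (first sample with dV/dt ≥ 20 mV/ms) and spike peak are
within 2 and 3 mV of target — tighter than the 5/10 mV the downstream
checks require.  These landmarks are calibration targets, not emergent
predictions: the underlying channel kinetics of the reference cells are
not published, so the model's claim is that a circuit of cells *with these
landmarks* reproduces the network-level findings.

## Synapses and stimulation

Synaptic conductance is a normalized double exponential (rise/decay time
constants, peak conductance, reversal, total delay ≥ dt); the current is
`g(t) (V − E_rev)`.  GC and MC sources are excitatory (E_rev 0 mV), BC and
HIPP sources GABAergic (E_rev −70 mV).  Placement follows standard dentate
targeting: BC output perisomatic, HIPP output distal-dendritic, MC input to
GCs proximal.  Weights (per-contact peak conductances, in `config.py`) were
chosen once so that the circuit reproduces the published qualitative
behaviour — single inputs are subthreshold for principal cells, the ~50
coincident granule-cell inputs that a HIPP cell receives after the stimulus
volley fire it reliably, the ~35 coincident inputs onto a basket cell do
not, and a sprouted recurrent mossy-fiber contact is giant-bouton strong
(25 nS) so recurrent excitation can propagate.  Inter-cell delays are
1–1.5 ms (GABAergic 1 ms).

The stimulus is a virtual perforant-path source — not a network node —
delivering the same double-exponential conductance to 100 GCs (contiguous
central block; topographic stimulation), 2 BCs (central block) and 2
randomly selected MCs, with a 4 ms total delay representing the combined
cell/transmission/synaptic latency, at onset 5 ms.  The source fires either
a single pulse or a train read from a plain-text spike-time file (one ms
value per line).  Stimulus contacts land on the middle dendritic band
(section 2; section 1 for MCs): in this reduced model a purely distal
placement charges the soma too slowly and drives Na inactivation
(depolarization block) instead of spiking, so the medial-perforant-path
band is used.

## Network integration

Fixed time step (default 0.1 ms, duration 100 ms, all cells initialized to
−60 mV and allowed to relax to their own rests).  Gating variables advance
by exact exponential relaxation at frozen voltage; the voltage advances by
an unconditionally stable backward-Euler cable solve.  Because axial
coupling is block-diagonal per cell and cells of a type share one
morphology, the implicit solve batches into one dense LAPACK call per
population.  A midpoint corrector (rates re-evaluated at the predicted
half-step voltage) keeps spike timing accurate: halving dt from 0.1 ms
shifts spike times by ~0.04 ms on a 20-cell network, and the dt = 0.1 ms
threshold-crossing time of a calibrated GC lies within 0.1 ms of an
LSODA reference solution.  A purely explicit per-compartment exponential
Euler was tried first and rejected: the per-step local equilibration makes
whole-cell charging grid-limited, lagging spike times by over 1 ms at
dt = 0.1 ms.

Spikes are somatic upward crossings of 0 mV, linearly interpolated between
samples, with a 2 ms refractory merge window.  Each spike enqueues
conductance increments on all outgoing synapses at the next grid point at
or after `t_spike + delay` (deterministic fixed-step queue).  Integration
aborts with the offending cell and time if |V| exceeds 200 mV.  Identical
configuration and seed give a bit-identical raster.

## Graph analysis

The directed multigraph is collapsed to a simple undirected graph (edge
{u,v} iff any contact in either direction; self-loops dropped).  Path
length uses exact all-pairs BFS implemented as boolean level-set matrix
products; clustering counts neighbour-pair edges via `(A² ∘ A)`; nodes
with degree < 2 contribute 0 to the clustering mean (over all N nodes).
A disconnected graph is an error naming an unreachable pair.  The random
reference uses the closed forms `L_rand = ln N / ln⟨k⟩`, `C_rand = ⟨k⟩/N`
(no graph sampling), and `Q = (C/L)/(C_rand/L_rand)`.

**Mean-degree convention.**  ⟨k⟩ fed to the random reference counts every
directed synaptic contact once (`2 × contacts / N`, the conventional
summary of a connection matrix), *not* the collapsed simple graph's
`2E/N`.  The rule table necessarily produces many reciprocal pairs — each
HIPP cell receives from ~250 of 500 GCs and projects back to 160 of them —
so the two conventions differ by ~13%; the contact convention is the one
consistent with the published mean degree of this circuit (27.43 for 7228
contacts on 527 nodes), and the simple-graph convention remains available
(`analyze_network(net, degree="simple")`).  The artificial stimulation
source is never a graph node.

## What the default conditions show (and what they do not)

Under the standard protocol the healthy network produces one spike per
directly stimulated cell (~11–13 ms) followed by network-driven firing of
all six HIPP cells (~14–16 ms) — inhibitory interneurons that integrate
hundreds of granule-cell inputs fire from the volley, while basket cells
fire only their direct-input spike.  The pathological network (sprouting 2,
no MC loss) sustains recurrent granule-cell firing for the whole 100 ms and
multiplies the total spike count ~30-fold under the same seed — the
hyperexcitability contrast between the two modes.  Unstimulated basket
cells, silent at rest in the healthy run, are strongly depolarized by the
granule-cell barrage in the pathological run; with the default weight this
network drive remains subthreshold rather than producing extra BC spikes,
because any weight at which the asynchronous pathological barrage fires a
BC also lets the *synchronous* healthy volley fire it.  This is a known
limitation of the reduced model's BC dynamics.

The generator emulates exact-out-degree topographic wiring on a 1-D axis;
it does not model 3-D axonal morphology, distance-dependent connection
probabilities, synaptic weight heterogeneity, or the full 1:1-scale
circuit.  Passing tests therefore validate the bookkeeping and dynamics of
this reduced preparation, not quantitative millivolt/millisecond agreement
with recordings — the published per-type response-time table depends on
unpublished channel kinetics and is treated as qualitative ordering only
(directly stimulated cells before network-driven HIPP cells).

## Default problem sizes

Tests and the acceptance script use the full 527-cell network for topology
and graph statistics (20 seeds for the stochastic quantities), the full
network for the two protocol simulations (healthy and pathological, 100 ms
each), and a 20-cell scaled network for the dt-convergence check; these
sizes match the modelled preparation, and the whole suite runs in well
under a minute of simulation time.
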