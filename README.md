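# dgnet — a dentate gyrus microcircuit model

`dgnet` is a self-contained simulator of the rodent dentate gyrus
microcircuit at 2000:1 scale, for studying how the healthy circuit differs
from the epileptic (mossy-fiber-sprouting) one.  It covers three stages that
are usually scattered across separate tools:

1. **Topographic connectivity generation** for the four numerically dominant
   cell types — granule cells (GC), mossy cells (MC), basket cells (BC) and
   HIPP interneurons — laid out on a normalized septotemporal axis
   (default counts 500/15/6/6).  Each connection rule fixes an exact
   out-degree (*divergence*) drawn from a *postsynaptic target pool* of the
   nearest cells, optionally excluding the closest ones (e.g. each MC
   contacts 200 GCs drawn from its 350 nearest, skipping the central 50).
   The *healthy* mode has no recurrent GC→GC contacts and intact mossy
   cells; the *pathological* mode adds sprouted GC→GC contacts and can
   delete mossy cells.
2. **Multicompartment conductance-based simulation.**  Cells are soma +
   dendrites split into four serial sections (9/17/17/13 compartments for
   GC/MC/BC/HIPP), with Hodgkin–Huxley-type Na/K currents calibrated to the
   published resting potential, spike threshold and spike peak of each type.
   The standard protocol delivers a perforant-path-like pulse at 5 ms to
   100 GCs, 2 BCs and 2 random MCs and integrates 100 ms at dt = 0.1 ms.
3. **Small-world graph analysis** of the resulting connectivity:
   characteristic path length `L = mean_i L_i` with
   `L_i = Σ_j d_ij / (N−1)`, clustering coefficient `C = mean_i C_i` with
   `C_i = 2 E_i / (k_i (k_i − 1))`, the equivalent-random-graph references
   `L_rand = ln N / ln⟨k⟩`, `C_rand = ⟨k⟩ / N`, and the small-world quotient

   ```
   Q = (C / L) / (C_rand / L_rand)      (Q > 1 ⇒ small-world)
   ```

## Worked example

```python
from dgnet import generate_network, connectivity_summary, analyze_network

net = generate_network(mode="healthy", seed=1)
print(connectivity_summary(net).loc[("MC", "GC")])
stats = analyze_network(net)
print(stats.tsv_row())
print(stats.verdict)
```

prints

```
edge_count          3000.0000
divergence_mean      200.0000
convergence_mean       6.0000
convergence_sd         2.8844

mean_degree	L	C	L_rand	C_rand	Q
27.4307	1.9596	0.4633	1.8925	0.0521	8.5953

L >= L_rand; C/C_rand = 8.90; Q = 8.5953 (small-world)
```

Every mossy cell contacts exactly 200 granule cells (divergence 200) and
each granule cell receives on average 6.0 mossy-cell inputs — the
divergence/convergence bookkeeping of the connection table is conserved
exactly by construction.  The symmetrized 527-cell graph has mean degree
27.43 (two contacts per directed synapse, divided by N), clusters almost
nine times more strongly than a degree-matched random graph, and its
small-world quotient is well above 1: the healthy circuit is a small-world
network.

The same stages are available from the shell:

```bash
dgnet generate --seed 1 --out-dir net/            # edges.tsv + summary
dgnet generate --mode pathological --sprouting 2  # epileptic variant
dgnet simulate --edges net/edges.tsv --out-dir sim/   # raster + traces
dgnet analyze --edges net/edges.tsv --out-dir stats/  # small-world row
```

`dgnet simulate` writes a spike raster (`cell_id  time_ms`) and membrane
traces of GC 0's soma and its four dendritic sections; in the healthy run
the directly stimulated cells fire first (~11–13 ms), the network-driven
HIPP interneurons follow (~14–16 ms), and spike peaks attenuate
monotonically from soma to distal dendrite.  Re-running the pathological
variant under the same seed multiplies the total spike count roughly
thirty-fold — the hyperexcitability signature of mossy-fiber sprouting.

## Layout

- `src/dgnet/topology.py` — populations, connection rules, network generation
- `src/dgnet/cells.py` — compartment trees, HH-type membrane dynamics, calibration
- `src/dgnet/synapses.py` — double-exponential synapses, stimulation sources
- `src/dgnet/engine.py` — fixed-step network integration, spike delivery, recording
- `src/dgnet/metrics.py` — path length, clustering, random reference, quotient
- `src/dgnet/config.py`, `cli.py`, `fixtures.py` — configuration, CLI, toy fixtures
- `docs/methods.md` — model description, parameter rationale, limitations
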