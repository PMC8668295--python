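"""Fixed-step network integration with delayed spike delivery.

The whole network is flattened into per-compartment state vectors and
advanced with exponential-Euler steps of ``dt``.  Somatic 0 mV upward
crossings are detected online (with linear interpolation between samples and
a refractory merge window); each spike enqueues conductance increments on
every outgoing synapse at the next grid point at or after
``t_spike + delay``.  Identical configuration and seed give a bit-identical
raster.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cells as _cells
from .config import DEFAULT_SYNAPSES, STIMULUS_SYNAPSES
from .exceptions import ConfigurationError, SimulationError
from .synapses import StimTarget, SynapseParams
from .topology import NetworkModel

# re-export for callers that build record selectors
COMPARTMENT_LAYOUT = _cells.COMPARTMENT_LAYOUT


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for one network run."""

    dt: float = 0.1  # ms
    duration: float = 100.0  # ms
    v_init: float = -60.0  # mV for every compartment before stimulation
    seed: int = 0
    threshold: float = 0.0  # mV, somatic spike detection level
    refractory: float = 2.0  # ms, spike merge window
    abort_v: float = 200.0  # |V| beyond which integration aborts
    record: tuple = ()  # tuples (gid, dendrite, section); section 0 = soma

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.duration <= 0:
            raise ConfigurationError("duration must be > 0")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("duration must be an integer multiple of dt")


@dataclass
class SimResult:
    """Spike raster plus recorded membrane traces."""

    time: np.ndarray
    raster: list  # (gid, spike time ms), ordered by time
    traces: dict  # "CELL:compartment" -> mV array, len(time)
    network: NetworkModel
    config: SimConfig

    @property
    def n_spikes(self) -> int:
        return len(self.raster)

    def spikes_of(self, gid: int) -> list[float]:
        return [t for g, t in self.raster if g == gid]

    def first_spike(self, gid: int) -> float | None:
        ts = self.spikes_of(gid)
        return min(ts) if ts else None

    def spike_counts_by_type(self) -> dict[str, int]:
        out = {t: 0 for t in self.network.populations}
        for g, _ in self.raster:
            out[self.network.cell_type_of(g)] += 1
        return out

    def raster_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [self.network.cell_label(g) for g, _ in self.raster],
                "time_ms": [t for _, t in self.raster],
            }
        )

    def write_raster(self, path) -> None:
        self.raster_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")

    def write_traces(self, path) -> None:
        df = pd.DataFrame({"time_ms": self.time})
        for key, v in self.traces.items():
            df[key] = v
        df.to_csv(path, index=False, float_format="%.5f")


def detect_spikes(
    trace: np.ndarray,
    dt: float,
    threshold: float = 0.0,
    refractory: float = 2.0,
) -> list[float]:
    """Interpolated upward threshold-crossing times with a merge window."""
    v = np.asarray(trace, dtype=float)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    times = []
    last = -np.inf
    for k in idx:
        t = (k + (threshold - v[k]) / (v[k + 1] - v[k])) * dt
        if t - last >= refractory:
            times.append(float(t))
            last = t
    return times


def default_record_set(network: NetworkModel, stimulation=()) -> tuple:
    """GC 0 soma + its four dendritic sections, ditto for the first
    stimulated GC, plus the first soma of each other population."""
    rec = []
    gc0 = network.populations["GC"].offset
    rec += [(gc0, 0, s) for s in range(5)]
    stim_gcs = [s.cell_id for s in stimulation if s.cell_type == "GC"]
    if stim_gcs and stim_gcs[0] != gc0:
        rec += [(stim_gcs[0], 0, s) for s in range(5)]
    for t in ("MC", "BC", "HIPP"):
        rec.append((network.populations[t].offset, 0, 0))
    return tuple(rec)


def _comp_key(network: NetworkModel, gid: int, dendrite: int, section: int) -> str:
    label = network.cell_label(gid)
    if section == 0:
        return f"{label}:soma"
    return f"{label}:dend{dendrite}.sec{section}"


class _FlatNetwork:
    """Per-compartment state vectors for all cells plus the coupling matrix."""

    def __init__(self, network: NetworkModel, cell_params: dict):
        trees = {t: _cells.build_cell(t, cell_params[t]) for t in network.populations}
        self.trees = trees
        n_cells = network.n_cells
        self.comp_offset = np.zeros(n_cells + 1, dtype=int)
        gid_type = [network.cell_type_of(g) for g in range(n_cells)]
        sizes = np.array([trees[t].n_compartments for t in gid_type])
        self.comp_offset[1:] = np.cumsum(sizes)
        n_comp = int(self.comp_offset[-1])
        self.n_comp = n_comp
        self.gid_type = gid_type

        def tile(attr):
            return np.concatenate([getattr(trees[t], attr) for t in gid_type])

        self.capacitance = tile("capacitance")
        self.g_leak = tile("g_leak")
        self.e_leak = tile("e_leak")
        self.g_na = tile("g_na")
        self.g_k = tile("g_k")
        self.comp_cell = np.repeat(np.arange(n_cells), sizes)
        self.soma = self.comp_offset[:-1].copy()

        def per_comp(getter):
            return np.concatenate(
                [np.full(trees[t].n_compartments, getter(cell_params[t])) for t in gid_type]
            )

        self.e_na = per_comp(lambda p: p.e_na)
        self.e_k = per_comp(lambda p: p.e_k)
        self.shift = per_comp(lambda p: p.shift)
        self.rate_scale = per_comp(lambda p: p.rate_scale)

        # Axial coupling is block-diagonal per cell, and cells of one type
        # are contiguous, so the implicit cable solve batches into one dense
        # LAPACK call per population: (n_cells, nc, nc) systems.
        self.blocks = []
        for t, pop_t in network.populations.items():
            tr = trees[t]
            nc = tr.n_compartments
            start = int(self.comp_offset[pop_t.offset])
            stop = int(self.comp_offset[pop_t.offset + pop_t.count - 1]) + nc
            self.blocks.append(
                (slice(start, stop), pop_t.count, nc, _cells.axial_laplacian(tr))
            )

    def compartment_index(self, network, gid: int, dendrite: int, section: int) -> int:
        tr = self.trees[network.cell_type_of(gid)]
        return int(self.comp_offset[gid] + tr.compartment_index(dendrite, section))


def _edge_arrays(network, flat, synapse_table, dt):
    """Per-edge synapse constants for the network's directed edges."""
    pairs = set(map(tuple, network.edges[["pre_type", "post_type"]].drop_duplicates().values))
    missing = [f"{a}->{b}" for a, b in sorted(pairs) if f"{a}->{b}" not in synapse_table]
    if missing:
        raise ConfigurationError(f"missing synapse parameters for edge types {missing}")
    for key in synapse_table:
        synapse_table[key].validate(dt)

    pre = network.edges.pre_id.to_numpy()
    post = network.edges.post_id.to_numpy()
    refs = network.edges.synapse_ref.to_numpy()
    n_e = len(pre)
    tgt = np.zeros(n_e, dtype=int)
    dec_r = np.zeros(n_e)
    dec_d = np.zeros(n_e)
    inc = np.zeros(n_e)
    e_rev = np.zeros(n_e)
    delay = np.zeros(n_e)
    for k in range(n_e):
        p = synapse_table[refs[k]]
        post_type = network.cell_type_of(int(post[k]))
        n_dend, _ = COMPARTMENT_LAYOUT[post_type]
        dend = int(pre[k]) % n_dend if p.target_section > 0 else 0
        tgt[k] = flat.compartment_index(network, int(post[k]), dend, p.target_section)
        dec_r[k] = np.exp(-dt / p.tau_rise)
        dec_d[k] = np.exp(-dt / p.tau_decay)
        inc[k] = p.g_peak / p.norm
        e_rev[k] = p.e_rev
        delay[k] = p.delay
    out_edges = defaultdict(list)
    for k in range(n_e):
        out_edges[int(pre[k])].append(k)
    out_edges = {g: np.asarray(v) for g, v in out_edges.items()}
    return dict(tgt=tgt, dec_r=dec_r, dec_d=dec_d, inc=inc, e_rev=e_rev,
                delay=delay, out_edges=out_edges, n=n_e)


def run_simulation(
    network: NetworkModel,
    stimulation: list[StimTarget] | None = None,
    config: SimConfig | None = None,
    synapse_table: dict[str, SynapseParams] | None = None,
    stimulus_synapses: dict[str, SynapseParams] | None = None,
    cell_params: dict | None = None,
) -> SimResult:
    """Integrate the network under the stimulation protocol.

    ``cell_params`` maps cell type to :class:`~dgnet.cells.CellTypeParams`;
    by default the landmark-calibrated parameters are used.  All validation
    (synapse coverage of every edge type, delay >= dt, timing grid) happens
    before the first integration step.
    """
    config = config or SimConfig()
    config.validate()
    stimulation = list(stimulation or [])
    synapse_table = dict(DEFAULT_SYNAPSES if synapse_table is None else synapse_table)
    stimulus_synapses = dict(
        STIMULUS_SYNAPSES if stimulus_synapses is None else stimulus_synapses
    )
    if cell_params is None:
        cell_params = {t: _cells.calibrated_params(t) for t in network.populations}

    dt, n_steps = config.dt, int(round(config.duration / config.dt))
    flat = _FlatNetwork(network, cell_params)
    syn = _edge_arrays(network, flat, synapse_table, dt)

    # Stimulus connections are extra synapse slots driven by a virtual
    # source; the source itself is not a network node.
    stim_slots = []
    deliveries: dict[int, list[int]] = defaultdict(list)
    for s_idx, stim in enumerate(stimulation):
        p = stimulus_synapses.get(stim.cell_type)
        if p is None:
            raise ConfigurationError(f"no stimulus synapse for type {stim.cell_type}")
        p.validate(dt)
        n_dend, _ = COMPARTMENT_LAYOUT[stim.cell_type]
        dend = s_idx % n_dend if p.target_section > 0 else 0
        slot = syn["n"] + len(stim_slots)
        stim_slots.append(
            (flat.compartment_index(network, stim.cell_id, dend, p.target_section),
             np.exp(-dt / p.tau_rise), np.exp(-dt / p.tau_decay),
             p.g_peak / p.norm, p.e_rev)
        )
        for t0 in stim.times:
            step = int(np.ceil((t0 + p.delay) / dt - 1e-9))
            if 0 <= step <= n_steps:
                deliveries[step].append(slot)

    n_syn = syn["n"] + len(stim_slots)
    tgt = np.concatenate([syn["tgt"], np.array([s[0] for s in stim_slots], dtype=int)])
    dec_r = np.concatenate([syn["dec_r"], np.array([s[1] for s in stim_slots])])
    dec_d = np.concatenate([syn["dec_d"], np.array([s[2] for s in stim_slots])])
    inc = np.concatenate([syn["inc"], np.array([s[3] for s in stim_slots])])
    e_rev = np.concatenate([syn["e_rev"], np.array([s[4] for s in stim_slots])])
    a_state = np.zeros(n_syn)
    b_state = np.zeros(n_syn)

    record = config.record or default_record_set(network, stimulation)
    rec_idx = np.array(
        [flat.compartment_index(network, g, d, s) for g, d, s in record], dtype=int
    )
    rec_keys = [_comp_key(network, g, d, s) for g, d, s in record]
    traces = np.empty((len(record), n_steps + 1))

    v = np.full(flat.n_comp, config.v_init, dtype=float)
    m, h, n_gate = _cells.steady_state_gates(v, flat.shift)
    traces[:, 0] = v[rec_idx]

    soma = flat.soma
    last_spike = np.full(network.n_cells, -np.inf)
    raster: list[tuple[int, float]] = []
    out_edges = syn["out_edges"]
    cap_dt = flat.capacitance / dt
    rr = {nc: np.arange(nc) for _, _, nc, _ in flat.blocks}

    for k in range(n_steps):
        t_k = k * dt
        if k in deliveries:
            idx = np.asarray(deliveries.pop(k))
            np.add.at(a_state, idx, inc[idx])
            np.add.at(b_state, idx, inc[idx])
        g_syn_e = b_state - a_state
        g_syn = np.bincount(tgt, weights=g_syn_e, minlength=flat.n_comp)
        ge_syn = np.bincount(tgt, weights=g_syn_e * e_rev, minlength=flat.n_comp)
        a_state *= dec_r
        b_state *= dec_d

        def stage(u):
            # exponential gate update with rates at u, then an implicit
            # (backward-Euler) cable solve, batched per population
            (am, bm), (ah, bh), (an, bn) = _cells.rate_constants(u, flat.shift)
            rs = flat.rate_scale
            mm = _cells._gate_step(m, am, bm, rs, dt)
            hh = _cells._gate_step(h, ah, bh, rs, dt)
            nn = _cells._gate_step(n_gate, an, bn, rs, dt)
            gna = flat.g_na * mm**3 * hh
            gk = flat.g_k * nn**4
            g_m = flat.g_leak + gna + gk + g_syn
            rhs = (flat.g_leak * flat.e_leak + gna * flat.e_na
                   + gk * flat.e_k + ge_syn + cap_dt * v)
            v_new = np.empty_like(v)
            for sl, n_c, nc, lap in flat.blocks:
                r = rr[nc]
                mats = np.broadcast_to(lap, (n_c, nc, nc)).copy()
                mats[:, r, r] += (cap_dt[sl] + g_m[sl]).reshape(n_c, nc)
                v_new[sl] = np.linalg.solve(
                    mats, rhs[sl].reshape(n_c, nc, 1)
                ).ravel()
            return v_new, mm, hh, nn

        # midpoint corrector keeps spike timing near second order in dt
        v_pred, _, _, _ = stage(v)
        v_old_soma = v[soma]
        v, m, h, n_gate = stage(0.5 * (v + v_pred))

        v_new_soma = v[soma]
        crossed = (v_old_soma < config.threshold) & (v_new_soma >= config.threshold)
        if crossed.any():
            for c in np.flatnonzero(crossed):
                frac = (config.threshold - v_old_soma[c]) / (v_new_soma[c] - v_old_soma[c])
                t_spike = t_k + frac * dt
                if t_spike - last_spike[c] < config.refractory:
                    continue
                last_spike[c] = t_spike
                raster.append((int(c), float(t_spike)))
                edges = out_edges.get(int(c))
                if edges is not None:
                    steps = np.ceil((t_spike + syn["delay"][edges]) / dt - 1e-9).astype(int)
                    for e_i, st in zip(edges, steps):
                        if st <= n_steps:
                            deliveries[int(st)].append(int(e_i))

        vmax = np.abs(v).max()
        if vmax > config.abort_v:
            bad = int(np.argmax(np.abs(v)))
            raise SimulationError(
                f"membrane potential diverged (|V| = {vmax:.1f} mV) in cell "
                f"{network.cell_label(int(flat.comp_cell[bad]))} at t = {t_k + dt:.2f} ms"
            )
        traces[:, k + 1] = v[rec_idx]

    raster.sort(key=lambda x: (x[1], x[0]))
    return SimResult(
        time=np.arange(n_steps + 1) * dt,
        raster=raster,
        traces={key: traces[i] for i, key in enumerate(rec_keys)},
        network=network,
        config=config,
    )
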