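"""Conductance-based synapses and the two stimulation sources.

Synaptic conductance follows a normalized double exponential: a presynaptic
spike at time ``t0`` contributes, after the total (axonal + synaptic) delay,

    g(t) = g_peak * (exp(-(t - t0 - delay)/tau_decay)
                     - exp(-(t - t0 - delay)/tau_rise)) / norm

where ``norm`` scales the waveform so its maximum is exactly ``g_peak``.
The synaptic current onto the postsynaptic compartment is
``I = g(t) * (V_post - E_rev)``.

Stimulation emulates perforant-path input: a virtual source (not a network
node) delivers either a single pulse at the protocol onset or a train of
pulses read from a plain-text spike-time file, onto 100 granule cells
(contiguous central block), 2 basket cells (central block) and 2 randomly
chosen mossy cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, ParseError


@dataclass(frozen=True)
class SynapseParams:
    """Double-exponential synapse: kinetics, strength, reversal, delay, site.

    ``target_section`` selects the postsynaptic compartment depth: 0 = soma,
    1..4 = dendritic section (proximal to distal); the dendrite branch is
    chosen deterministically per connection.
    """

    tau_rise: float  # ms
    tau_decay: float  # ms
    g_peak: float  # µS
    e_rev: float  # mV (excitatory ~ 0, inhibitory ~ -70)
    delay: float  # ms, axonal + synaptic
    target_section: int = 1

    def validate(self, dt: float | None = None) -> None:
        if not 0 < self.tau_rise < self.tau_decay:
            raise ConfigurationError(
                f"need 0 < tau_rise < tau_decay, got ({self.tau_rise}, {self.tau_decay})"
            )
        if self.g_peak < 0:
            raise ConfigurationError("g_peak must be >= 0")
        if dt is not None and self.delay < dt:
            raise ConfigurationError(f"delay {self.delay} ms must be >= dt {dt} ms")

    @property
    def peak_time(self) -> float:
        """Time to peak of the normalized waveform after onset."""
        return (math.log(self.tau_decay / self.tau_rise)
                / (1.0 / self.tau_rise - 1.0 / self.tau_decay))

    @property
    def norm(self) -> float:
        tp = self.peak_time
        return math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise)


def conductance(t, spike_times, params: SynapseParams) -> np.ndarray:
    """Closed-form summed conductance g(t) (µS) for sorted spike times."""
    params.validate()
    t = np.asarray(t, dtype=float)
    g = np.zeros_like(t)
    scale = params.g_peak / params.norm
    for t0 in spike_times:
        s = t - t0 - params.delay
        active = s > 0
        g[active] += scale * (
            np.exp(-s[active] / params.tau_decay) - np.exp(-s[active] / params.tau_rise)
        )
    return g


def synaptic_current(spike_times, params: SynapseParams, v_post, t) -> np.ndarray:
    """I(t) = g(t) * (V_post - E_rev), in nA for g in µS and V in mV."""
    return conductance(t, spike_times, params) * (np.asarray(v_post) - params.e_rev)


def load_spike_times(path) -> list[float]:
    """Read one non-negative spike time (ms) per non-empty line, sorted."""
    times = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            try:
                t = float(s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: not a number: {s!r}") from exc
            if not math.isfinite(t) or t < 0:
                raise ParseError(f"{path}: line {lineno}: spike time must be >= 0, got {t}")
            times.append(t)
    return sorted(times)


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulation targets and source timing.

    ``source`` is either "pulse" (a single pulse at ``onset``) or a path to
    a plain-text spike-time file (one time in ms per line).
    """

    onset: float = 5.0
    n_gc: int = 100
    n_bc: int = 2
    n_mc: int = 2
    source: str = "pulse"

    def source_times(self) -> list[float]:
        if self.source == "pulse":
            return [float(self.onset)]
        return load_spike_times(self.source)


@dataclass(frozen=True)
class StimTarget:
    cell_id: int
    cell_type: str
    times: tuple[float, ...]


def build_stimulation(
    protocol: StimulusProtocol,
    network,
    rng: np.random.Generator,
) -> list[StimTarget]:
    """Wire the stimulus source to its target cells.

    GC and BC targets are contiguous central blocks of their populations
    (topographic stimulation); MC targets are drawn uniformly at random.
    Reproducible given the generator's seed.
    """
    pops = network.populations
    for t, n in (("GC", protocol.n_gc), ("BC", protocol.n_bc), ("MC", protocol.n_mc)):
        if n < 0 or n > pops[t].count:
            raise ConfigurationError(
                f"protocol requests {n} stimulated {t} but population has {pops[t].count}"
            )
    times = tuple(protocol.source_times())
    targets: list[StimTarget] = []

    def central_block(pop, n):
        start = (pop.count - n) // 2
        return pop.global_ids()[start:start + n]

    for gid in central_block(pops["GC"], protocol.n_gc):
        targets.append(StimTarget(int(gid), "GC", times))
    for gid in central_block(pops["BC"], protocol.n_bc):
        targets.append(StimTarget(int(gid), "BC", times))
    if protocol.n_mc > 0:
        mcs = np.sort(rng.choice(pops["MC"].global_ids(), size=protocol.n_mc, replace=False))
        for gid in mcs:
            targets.append(StimTarget(int(gid), "MC", times))
    return targets
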