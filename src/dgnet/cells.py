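"""Multicompartment conductance-based models of the four dentate gyrus cells.

Each cell is a soma plus identical dendritic branches, every branch split
into four serial sections (1 = proximal, 4 = distal):

=====  =========  ============  ============
type   dendrites  compartments  role
=====  =========  ============  ============
GC     2          9             granule cell
MC     4          17            mossy cell
BC     4          17            basket cell
HIPP   3          13            HIPP interneuron
=====  =========  ============  ============

Membrane dynamics are Hodgkin-Huxley type: transient Na and delayed-rectifier
K currents plus leak, with a per-type voltage shift of the rate functions and
a per-type Na reversal.  Channel density is highest at the soma and decays
along the dendrite, so an action potential initiated at the soma propagates
into the dendrites with monotonically decreasing peak amplitude.

The published resting potential, spike threshold and spike peak of each type
are treated as calibration landmarks: :func:`calibrate` solves the leak
reversal analytically so the target rest is an exact fixed point, then tunes
the kinetic shift (threshold) and Na reversal (peak) against a single-cell
current-clamp simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

from .exceptions import CalibrationError, ConfigurationError, SimulationError

#: (number of dendrites, sections per dendrite) per cell type.
COMPARTMENT_LAYOUT = {"GC": (2, 4), "MC": (4, 4), "BC": (4, 4), "HIPP": (3, 4)}

#: Published membrane landmarks: rest, spike threshold, spike peak (mV).
MEMBRANE_LANDMARKS = {
    "GC": (-70.44, -39.44, 37.14),
    "MC": (-60.11, -39.05, 46.72),
    "BC": (-60.00, -38.86, 46.87),
    "HIPP": (-70.67, -42.67, 76.53),
}


@dataclass(frozen=True)
class Geometry:
    """Cylinder dimensions (µm); dendritic sections uniform within a section."""

    soma_diam: float
    soma_length: float
    section_lengths: tuple[float, float, float, float] = (50.0, 50.0, 50.0, 50.0)
    section_diams: tuple[float, float, float, float] = (2.5, 1.8, 1.2, 0.8)


DEFAULT_GEOMETRY = {
    "GC": Geometry(soma_diam=10.0, soma_length=10.0),
    "MC": Geometry(soma_diam=20.0, soma_length=20.0,
                   section_diams=(3.0, 2.2, 1.5, 1.0)),
    "BC": Geometry(soma_diam=15.0, soma_length=15.0,
                   section_diams=(3.0, 2.2, 1.5, 1.0)),
    "HIPP": Geometry(soma_diam=13.0, soma_length=13.0,
                     section_diams=(2.5, 1.8, 1.2, 0.8)),
}


@dataclass(frozen=True)
class CellTypeParams:
    """Biophysical parameters of one cell type.

    Conductance densities in mS/cm², capacitance in µF/cm², axial
    resistivity in Ω·cm, potentials in mV.  ``dend_active_scale`` scales the
    somatic Na/K density per dendritic section (proximal → distal).
    """

    cell_type: str
    geometry: Geometry
    cm: float = 1.0
    ra: float = 150.0
    g_leak: float = 0.1
    gna_soma: float = 250.0
    gk_soma: float = 60.0
    dend_active_scale: tuple[float, float, float, float] = (0.3, 0.1, 0.0, 0.0)
    e_na: float = 55.0
    e_k: float = -90.0
    shift: float = 15.0  # depolarizing shift of the HH rate functions
    rate_scale: float = 3.0  # temperature-like speedup of gating kinetics
    v_rest: float = -70.0
    threshold: float = -40.0
    peak: float = 40.0
    clamp_amp: float = 0.25  # nA; somatic step known to evoke a spike

    def validate(self) -> None:
        if self.cell_type not in COMPARTMENT_LAYOUT:
            raise ConfigurationError(f"unknown cell type {self.cell_type!r}")
        if not self.v_rest < self.threshold < self.peak:
            raise ConfigurationError(
                "landmarks must satisfy rest < threshold < peak, got "
                f"({self.v_rest}, {self.threshold}, {self.peak})"
            )
        for name, v in (("g_leak", self.g_leak), ("gna_soma", self.gna_soma),
                        ("gk_soma", self.gk_soma), ("cm", self.cm), ("ra", self.ra)):
            if v < 0:
                raise ConfigurationError(f"{name} must be >= 0")


def default_params(cell_type: str) -> CellTypeParams:
    """Uncalibrated starting parameters for one cell type."""
    if cell_type not in COMPARTMENT_LAYOUT:
        raise ConfigurationError(f"unknown cell type {cell_type!r}")
    rest, thr, peak = MEMBRANE_LANDMARKS[cell_type]
    return CellTypeParams(
        cell_type=cell_type,
        geometry=DEFAULT_GEOMETRY[cell_type],
        e_na=peak + 18.0,
        v_rest=rest,
        threshold=thr,
        peak=peak,
    )


# ---------------------------------------------------------------------------
# HH rate functions (classic squid formalism, voltage-shifted per type)

def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (1 - exp(-x/y)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    out = safe / (1.0 - np.exp(-safe / y))
    return np.where(small, y * (1.0 + x / (2.0 * y)), out)


def rate_constants(v, shift: float):
    """alpha/beta for m, h, n at membrane potential v (mV), in 1/ms."""
    u = np.asarray(v, dtype=float) - shift
    am = 0.1 * _vtrap(u + 40.0, 10.0)
    bm = 4.0 * np.exp(-(u + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(u + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(u + 35.0) / 10.0))
    an = 0.01 * _vtrap(u + 55.0, 10.0)
    bn = 0.125 * np.exp(-(u + 65.0) / 80.0)
    return (am, bm), (ah, bh), (an, bn)


def steady_state_gates(v, shift: float):
    (am, bm), (ah, bh), (an, bn) = rate_constants(v, shift)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


# ---------------------------------------------------------------------------
# Compartment tree

@dataclass
class CompartmentTree:
    """Flat arrays describing one cell's soma + dendrites.

    Compartment 0 is the soma; dendrite ``d``'s sections follow in proximal
    to distal order.  ``parent[i]`` is the index of the compartment toward
    the soma (-1 for the soma itself).  Conductances in µS, capacitance in
    nF, potentials in mV.
    """

    cell_type: str
    params: CellTypeParams
    parent: np.ndarray
    labels: list[tuple[str, int, int]]  # (role, dendrite_index, section_index)
    capacitance: np.ndarray
    g_leak: np.ndarray
    e_leak: np.ndarray
    g_na: np.ndarray
    g_k: np.ndarray
    g_axial: np.ndarray  # coupling conductance to parent, 0 for soma
    v: np.ndarray = field(default=None)
    m: np.ndarray = field(default=None)
    h: np.ndarray = field(default=None)
    n: np.ndarray = field(default=None)

    @property
    def n_compartments(self) -> int:
        return len(self.parent)

    @property
    def soma_index(self) -> int:
        return 0

    def compartment_index(self, dendrite: int, section: int) -> int:
        """Index of (dendrite, section); section 0 means the soma."""
        if section == 0:
            return 0
        n_dend, n_sec = COMPARTMENT_LAYOUT[self.cell_type]
        if not (0 <= dendrite < n_dend and 1 <= section <= n_sec):
            raise ConfigurationError(
                f"{self.cell_type} has no compartment (dendrite {dendrite}, section {section})"
            )
        return 1 + dendrite * n_sec + (section - 1)

    def set_state(self, v_init: float) -> None:
        nc = self.n_compartments
        self.v = np.full(nc, float(v_init))
        m, h, n = steady_state_gates(self.v, self.params.shift)
        self.m, self.h, self.n = m, h, n


def _cylinder_area_cm2(diam_um: float, length_um: float) -> float:
    return math.pi * diam_um * length_um * 1e-8


def _axial_half_resistance(ra: float, length_um: float, diam_um: float) -> float:
    """Ω from the center of a cylindrical compartment to its end."""
    area_cm2 = math.pi * (diam_um * 1e-4 / 2.0) ** 2
    return ra * (length_um * 1e-4 / 2.0) / area_cm2


def build_cell(cell_type: str, params: CellTypeParams | None = None,
               v_init: float | None = None) -> CompartmentTree:
    """Assemble the compartment tree for one cell.

    The leak reversal of every compartment is solved so that the uniform
    potential ``params.v_rest`` is an exact resting fixed point of the
    membrane equations (axial currents vanish at uniform potential).
    """
    params = params or default_params(cell_type)
    params.validate()
    if params.cell_type != cell_type:
        raise ConfigurationError("params.cell_type does not match requested type")
    n_dend, n_sec = COMPARTMENT_LAYOUT[cell_type]
    geo = params.geometry

    dims = [(geo.soma_diam, geo.soma_length)]
    parent = [-1]
    labels = [("soma", -1, 0)]
    gna_scale = [1.0]
    for d in range(n_dend):
        for s in range(n_sec):
            dims.append((geo.section_diams[s], geo.section_lengths[s]))
            parent.append(0 if s == 0 else len(parent) - 1)
            labels.append(("dendrite", d, s + 1))
            gna_scale.append(params.dend_active_scale[s])

    area = np.array([_cylinder_area_cm2(d, ln) for d, ln in dims])
    cap = params.cm * area * 1e3  # µF -> nF
    g_leak = params.g_leak * area * 1e3  # mS -> µS
    g_na = params.gna_soma * np.asarray(gna_scale) * area * 1e3
    g_k = params.gk_soma * np.asarray(gna_scale) * area * 1e3

    g_ax = np.zeros(len(dims))
    for i in range(1, len(dims)):
        p = parent[i]
        r = _axial_half_resistance(params.ra, dims[i][1], dims[i][0]) + \
            _axial_half_resistance(params.ra, dims[p][1], dims[p][0])
        g_ax[i] = 1e6 / r  # Ω -> µS

    # Leak reversal making v_rest an exact fixed point per compartment.
    m0, h0, n0 = steady_state_gates(params.v_rest, params.shift)
    i_na = g_na * m0**3 * h0 * (params.v_rest - params.e_na)
    i_k = g_k * n0**4 * (params.v_rest - params.e_k)
    e_leak = params.v_rest + (i_na + i_k) / g_leak

    tree = CompartmentTree(
        cell_type=cell_type,
        params=params,
        parent=np.asarray(parent),
        labels=labels,
        capacitance=cap,
        g_leak=g_leak,
        e_leak=e_leak,
        g_na=g_na,
        g_k=g_k,
        g_axial=g_ax,
    )
    tree.set_state(params.v_rest if v_init is None else v_init)
    return tree


def axial_currents(tree: CompartmentTree, v: np.ndarray) -> np.ndarray:
    """Net axial current (nA) leaving each compartment; sums to zero."""
    i_ax = np.zeros_like(v)
    p = tree.parent
    child = np.arange(1, tree.n_compartments)
    flow = tree.g_axial[child] * (v[child] - v[p[child]])
    np.add.at(i_ax, child, flow)
    np.add.at(i_ax, p[child], -flow)
    return i_ax


def membrane_derivatives(
    tree: CompartmentTree,
    i_inj: np.ndarray | float = 0.0,
    syn_g: np.ndarray | float = 0.0,
    syn_ge: np.ndarray | float = 0.0,
):
    """Time derivatives of V (mV/ms) and the gating variables.

    ``syn_g``/``syn_ge`` are the per-compartment summed synaptic conductance
    (µS) and conductance-weighted reversal (µS·mV); the synaptic current is
    ``syn_g * V - syn_ge``.
    """
    v, m, h, n = tree.v, tree.m, tree.h, tree.n
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(m))):
        raise SimulationError(f"non-finite state in {tree.cell_type} cell")
    p = tree.params
    i_ion = (
        tree.g_na * m**3 * h * (v - p.e_na)
        + tree.g_k * n**4 * (v - p.e_k)
        + tree.g_leak * (v - tree.e_leak)
    )
    i_syn = np.asarray(syn_g) * v - np.asarray(syn_ge)
    dv = (-(i_ion + i_syn) - axial_currents(tree, v) + i_inj) / tree.capacitance
    (am, bm), (ah, bh), (an, bn) = rate_constants(v, p.shift)
    r = p.rate_scale
    dm = r * (am * (1 - m) - bm * m)
    dh = r * (ah * (1 - h) - bh * h)
    dn = r * (an * (1 - n) - bn * n)
    return dv, dm, dh, dn


def _gate_step(x, a, b, rate_scale, dt):
    tot = a + b
    inf = a / tot
    return inf + (x - inf) * np.exp(-dt * rate_scale * tot)


def axial_laplacian(tree: CompartmentTree) -> np.ndarray:
    """Dense graph Laplacian of the axial coupling (µS)."""
    n = tree.n_compartments
    lap = np.zeros((n, n))
    for i in range(1, n):
        p = tree.parent[i]
        g = tree.g_axial[i]
        lap[i, i] += g
        lap[p, p] += g
        lap[i, p] -= g
        lap[p, i] -= g
    return lap


def _substep(tree: CompartmentTree, dt: float, u: np.ndarray, lap: np.ndarray,
             i_inj, syn_g, syn_ge):
    """One implicit stage: exponential gate update with rates at ``u``,
    then a backward-Euler voltage solve over the coupled cable.

    Returns (v_new, m_new, h_new, n_new) from the tree's stored state.
    """
    v, p = tree.v, tree.params
    (am, bm), (ah, bh), (an, bn) = rate_constants(u, p.shift)
    m = _gate_step(tree.m, am, bm, p.rate_scale, dt)
    h = _gate_step(tree.h, ah, bh, p.rate_scale, dt)
    n = _gate_step(tree.n, an, bn, p.rate_scale, dt)

    gna = tree.g_na * m**3 * h
    gk = tree.g_k * n**4
    syn_g = np.broadcast_to(np.asarray(syn_g, dtype=float), v.shape)
    syn_ge = np.broadcast_to(np.asarray(syn_ge, dtype=float), v.shape)
    i_inj = np.broadcast_to(np.asarray(i_inj, dtype=float), v.shape)

    g_m = tree.g_leak + gna + gk + syn_g
    rhs = (tree.g_leak * tree.e_leak + gna * p.e_na + gk * p.e_k
           + syn_ge + i_inj + tree.capacitance / dt * v)
    mat = lap + np.diag(tree.capacitance / dt + g_m)
    v_new = np.linalg.solve(mat, rhs)
    return v_new, m, h, n


def step_implicit(
    tree: CompartmentTree,
    dt: float,
    i_inj: np.ndarray | float = 0.0,
    syn_g: np.ndarray | float = 0.0,
    syn_ge: np.ndarray | float = 0.0,
    lap: np.ndarray | None = None,
) -> None:
    """Advance one cell by dt.

    Gating variables advance by exact exponential relaxation at frozen
    voltage; the voltage advances by an unconditionally stable implicit
    (backward-Euler) cable solve.  A midpoint corrector re-evaluates the
    rate constants at the predicted half-step voltage, keeping spike
    timing accurate at dt = 0.1 ms.
    """
    if lap is None:
        lap = axial_laplacian(tree)
    v_pred, _, _, _ = _substep(tree, dt, tree.v, lap, i_inj, syn_g, syn_ge)
    u_mid = 0.5 * (tree.v + v_pred)
    tree.v, tree.m, tree.h, tree.n = _substep(tree, dt, u_mid, lap, i_inj, syn_g, syn_ge)


# backwards-compatible name used by older call sites
step_exponential_euler = step_implicit


def simulate_cell(
    params: CellTypeParams,
    duration: float = 100.0,
    dt: float = 0.05,
    i_amp: float = 0.0,
    i_onset: float = 10.0,
    i_dur: float = 80.0,
    i_compartment: int = 0,
    v_init: float | None = None,
):
    """Current-clamp simulation of a single isolated cell.

    Returns (t, V) with V of shape (n_steps + 1, n_compartments).
    """
    tree = build_cell(params.cell_type, params, v_init=v_init)
    lap = axial_laplacian(tree)
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt
    v_rec = np.empty((n_steps + 1, tree.n_compartments))
    v_rec[0] = tree.v
    inj = np.zeros(tree.n_compartments)
    for k in range(n_steps):
        tk = k * dt
        inj[i_compartment] = i_amp if i_onset <= tk < i_onset + i_dur else 0.0
        step_implicit(tree, dt, i_inj=inj, lap=lap)
        if np.abs(tree.v).max() > 200.0:
            raise SimulationError(
                f"{params.cell_type} single-cell run diverged at t = {tk:.2f} ms"
            )
        v_rec[k + 1] = tree.v
    return t, v_rec


# ---------------------------------------------------------------------------
# Calibration

#: dV/dt level (mV/ms) defining spike onset for threshold diagnostics.
ONSET_DVDT = 20.0


def spike_landmarks(t: np.ndarray, v_soma: np.ndarray) -> tuple[float, float] | None:
    """(threshold, peak) of the first somatic spike, or None if no spike.

    Spike onset is the first sample where dV/dt exceeds ``ONSET_DVDT``
    during a regenerative upstroke; threshold is the potential there and
    peak the local maximum that follows.
    """
    dvdt = np.gradient(v_soma, t)
    onset_candidates = np.flatnonzero(dvdt >= ONSET_DVDT)
    if len(onset_candidates) == 0:
        return None
    k0 = onset_candidates[0]
    k = k0
    while k + 1 < len(v_soma) and v_soma[k + 1] >= v_soma[k]:
        k += 1
    return float(v_soma[k0]), float(v_soma[k])


def calibrate(
    params: CellTypeParams,
    targets: tuple[float, float, float] | None = None,
    tol_rest: float = 1.0,
    tol_threshold: float = 2.0,
    tol_peak: float = 3.0,
    max_iter: int = 60,
    clamp_amp: float | None = None,
) -> CellTypeParams:
    """Tune shift and E_Na until the current-clamp landmarks match targets.

    ``targets`` is (rest, threshold, peak) in mV; defaults to the published
    landmarks for the cell type.  The rest is met exactly by construction of
    the leak reversal; threshold and peak are matched iteratively within the
    given tolerances (tighter than the downstream acceptance tolerances).
    """
    if targets is None:
        targets = MEMBRANE_LANDMARKS[params.cell_type]
    rest_t, thr_t, peak_t = targets
    if not rest_t < thr_t < peak_t:
        raise ConfigurationError(
            f"targets must satisfy rest < threshold < peak, got {targets}"
        )
    p = replace(params, v_rest=rest_t, threshold=thr_t, peak=peak_t)
    # Clamp sized from the cell's input conductance: enough to depolarize
    # well past threshold, capped below the level that would push a purely
    # passive membrane toward the numerical abort limit.
    g_in = float(build_cell(p.cell_type, p).g_leak.sum())
    amp = clamp_amp if clamp_amp is not None else 1.5 * g_in * (thr_t - rest_t + 20.0)
    amp_max = g_in * (140.0 - rest_t)
    worst = None
    for _ in range(max_iter):
        t, v = simulate_cell(p, duration=80.0, dt=0.05, i_amp=amp, i_onset=10.0, i_dur=60.0)
        lm = spike_landmarks(t, v[:, 0])
        if lm is None:
            amp *= 1.5
            if amp > amp_max:
                raise CalibrationError(
                    f"{p.cell_type}: no spike evoked even at {amp:.2f} nA"
                )
            continue
        thr_m, peak_m = lm
        e_thr, e_peak = thr_t - thr_m, peak_t - peak_m
        worst = max(abs(e_thr), abs(e_peak))
        if abs(e_thr) <= tol_threshold and abs(e_peak) <= tol_peak:
            return replace(p, clamp_amp=amp)
        p = replace(
            p,
            shift=p.shift + 0.7 * e_thr,
            e_na=p.e_na + 0.8 * e_peak,
        )
    raise CalibrationError(
        f"{p.cell_type}: calibration not converged after {max_iter} iterations "
        f"(worst residual {worst} mV)"
    )


@lru_cache(maxsize=None)
def calibrated_params(cell_type: str) -> CellTypeParams:
    """Default parameters calibrated to the published membrane landmarks."""
    return calibrate(default_params(cell_type))


def rheobase_bracket(params: CellTypeParams, amps: np.ndarray | None = None):
    """Spike/no-spike outcome across clamp amplitudes (diagnostics)."""
    amps = np.asarray(amps) if amps is not None else np.linspace(0.0, 0.4, 9)
    out = []
    for a in amps:
        t, v = simulate_cell(params, duration=60.0, dt=0.05, i_amp=float(a),
                             i_onset=5.0, i_dur=50.0)
        out.append((float(a), bool((v[:, 0] > 0).any())))
    return out
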