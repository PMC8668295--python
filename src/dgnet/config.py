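"""Default run configuration: populations, rules, synapse table, protocol.

A configuration file (YAML or JSON) may override any of the sections
``populations``, ``rules``, ``mode``, ``seed``, ``synapses``, ``protocol``
and ``simulation``; omitted entries fall back to the defaults below.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .synapses import StimulusProtocol, SynapseParams
from .topology import DEFAULT_COUNTS, HEALTHY_RULES, ConnectionRule

#: Synapse parameter sets keyed by "PRE->POST".  GC and MC sources are
#: excitatory (E_rev 0 mV); BC and HIPP sources are GABAergic (E_rev -70 mV).
#: Placement follows standard dentate targeting: perforant-path and HIPP
#: inputs on distal GC dendrites, MC inputs proximal, BC inputs perisomatic.
DEFAULT_SYNAPSES: dict[str, SynapseParams] = {
    "GC->MC": SynapseParams(0.5, 3.0, 0.3e-3, 0.0, 1.5, target_section=1),
    "GC->BC": SynapseParams(0.3, 2.5, 0.4e-3, 0.0, 1.5, target_section=1),
    "GC->HIPP": SynapseParams(0.3, 3.0, 1.0e-3, 0.0, 1.5, target_section=1),
    # Sprouted recurrent mossy-fiber contact: giant-bouton strength, so a
    # single recurrent input can recruit a quiescent granule cell.
    "GC->GC": SynapseParams(0.5, 3.0, 25e-3, 0.0, 1.5, target_section=1),
    "MC->GC": SynapseParams(0.5, 4.0, 1.0e-3, 0.0, 1.5, target_section=1),
    "MC->MC": SynapseParams(0.5, 4.0, 0.5e-3, 0.0, 1.5, target_section=2),
    "MC->BC": SynapseParams(0.5, 4.0, 0.5e-3, 0.0, 1.5, target_section=2),
    "MC->HIPP": SynapseParams(0.5, 4.0, 0.5e-3, 0.0, 1.5, target_section=2),
    "BC->GC": SynapseParams(0.5, 6.0, 2.0e-3, -70.0, 1.0, target_section=0),
    "BC->MC": SynapseParams(0.5, 6.0, 1.0e-3, -70.0, 1.0, target_section=0),
    "BC->BC": SynapseParams(0.5, 6.0, 1.0e-3, -70.0, 1.0, target_section=0),
    "HIPP->GC": SynapseParams(0.5, 6.0, 1.0e-3, -70.0, 1.0, target_section=4),
    "HIPP->MC": SynapseParams(0.5, 6.0, 1.0e-3, -70.0, 1.0, target_section=4),
    "HIPP->BC": SynapseParams(0.5, 6.0, 1.0e-3, -70.0, 1.0, target_section=4),
}

#: Stimulus-source synapses by postsynaptic type.  The 4 ms delay models the
#: combined cell/transmission/synaptic latency between the artificial source
#: and its targets.  GC/BC input lands on the middle dendritic band
#: (medial-perforant-path-like); MC input is proximal.
STIMULUS_SYNAPSES: dict[str, SynapseParams] = {
    "GC": SynapseParams(0.5, 3.0, 50e-3, 0.0, 4.0, target_section=2),
    "BC": SynapseParams(0.5, 3.0, 50e-3, 0.0, 4.0, target_section=2),
    "MC": SynapseParams(0.5, 3.0, 60e-3, 0.0, 4.0, target_section=1),
}

DEFAULT_SIMULATION = {
    "dt": 0.1,  # ms
    "duration": 100.0,  # ms
    "v_init": -60.0,  # mV, all cells, before stimulation
}


def default_config() -> dict:
    return {
        "populations": dict(DEFAULT_COUNTS),
        "mode": "healthy",
        "seed": 0,
        "sprouting_degree": 2,
        "mc_loss": 0,
        "rules": [
            {
                "pre_type": r.pre_type,
                "post_type": r.post_type,
                "divergence": r.divergence,
                "pool_size": r.pool_size,
                "center_exclusion": r.center_exclusion,
            }
            for r in HEALTHY_RULES
        ],
        "synapses": {
            k: {
                "tau_rise": p.tau_rise,
                "tau_decay": p.tau_decay,
                "g_peak": p.g_peak,
                "e_rev": p.e_rev,
                "delay": p.delay,
                "target_section": p.target_section,
            }
            for k, p in DEFAULT_SYNAPSES.items()
        },
        "protocol": {"onset": 5.0, "n_gc": 100, "n_bc": 2, "n_mc": 2, "source": "pulse"},
        "simulation": dict(DEFAULT_SIMULATION),
    }


def load_config(path: str | Path | None = None) -> dict:
    """Merge a YAML/JSON config file over the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    try:
        user = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except Exception as exc:  # noqa: BLE001
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(user, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    for key, val in user.items():
        if key not in cfg:
            raise ConfigurationError(f"unknown config section {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict) and key != "populations":
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return cfg


def rules_from_config(cfg: dict) -> tuple[ConnectionRule, ...]:
    return tuple(
        ConnectionRule(
            pre_type=r["pre_type"],
            post_type=r["post_type"],
            divergence=int(r["divergence"]),
            pool_size=int(r["pool_size"]),
            center_exclusion=int(r.get("center_exclusion", 0)),
        )
        for r in cfg["rules"]
    )


def synapses_from_config(cfg: dict) -> dict[str, SynapseParams]:
    return {
        k: SynapseParams(
            tau_rise=float(v["tau_rise"]),
            tau_decay=float(v["tau_decay"]),
            g_peak=float(v["g_peak"]),
            e_rev=float(v["e_rev"]),
            delay=float(v["delay"]),
            target_section=int(v.get("target_section", 1)),
        )
        for k, v in cfg["synapses"].items()
    }


def protocol_from_config(cfg: dict) -> StimulusProtocol:
    p = cfg["protocol"]
    return StimulusProtocol(
        onset=float(p.get("onset", 5.0)),
        n_gc=int(p.get("n_gc", 100)),
        n_bc=int(p.get("n_bc", 2)),
        n_mc=int(p.get("n_mc", 2)),
        source=p.get("source", "pulse"),
    )
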