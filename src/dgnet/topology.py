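"""Topographic connectivity generation for the dentate gyrus microcircuit.

The network contains the four numerically dominant cell types of the dentate
gyrus — granule cells (GC), mossy cells (MC), basket cells (BC) and HIPP
cells — laid out on a single normalized septotemporal axis.  Each connection
rule specifies, for one (presynaptic type -> postsynaptic type) pair, an exact
out-degree (*divergence*) drawn uniformly without replacement from a
topographic *postsynaptic target pool*: the ``pool_size`` cells of the target
population nearest to the presynaptic cell's axis position, optionally
excluding the ``center_exclusion`` nearest of those.

Two modes are supported.  The *healthy* mode has no recurrent GC->GC edges
and all mossy cells keep their connections.  The *pathological* mode emulates
mossy-fiber sprouting (a configurable number of recurrent GC->GC contacts per
granule cell) and mossy-cell loss (all edges of a configurable number of
randomly chosen MCs removed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GenerationError, ParseError

CELL_TYPES = ("GC", "MC", "BC", "HIPP")

#: Default population sizes: a 2000:1 scaling of the anatomical counts.
#: The BC/HIPP counts (6/6) are the ones consistent with the printed
#: convergence table (83.33 = 500/6, 1.92 = 6*160/500), see docs/methods.md.
DEFAULT_COUNTS = {"GC": 500, "MC": 15, "BC": 6, "HIPP": 6}


@dataclass(frozen=True)
class PopulationSpec:
    """One cell population on the shared [0, 1] septotemporal axis."""

    cell_type: str
    count: int
    offset: int  # first global cell id of this population

    @property
    def axis_positions(self) -> np.ndarray:
        """Evenly spaced positions (i + 0.5)/count, strictly increasing."""
        return (np.arange(self.count) + 0.5) / self.count

    def global_ids(self) -> np.ndarray:
        return np.arange(self.offset, self.offset + self.count)


@dataclass(frozen=True)
class ConnectionRule:
    """One entry of the divergence/pool/convergence connection table."""

    pre_type: str
    post_type: str
    divergence: int
    pool_size: int
    center_exclusion: int = 0
    allow_self: bool = False

    def validate(self) -> None:
        if self.pre_type not in CELL_TYPES or self.post_type not in CELL_TYPES:
            raise ConfigurationError(f"unknown cell type in rule {self.name}")
        if self.divergence < 0:
            raise ConfigurationError(f"rule {self.name}: negative divergence")
        if self.pool_size <= 0:
            raise ConfigurationError(f"rule {self.name}: pool_size must be positive")
        if self.center_exclusion < 0 or self.center_exclusion >= self.pool_size:
            raise ConfigurationError(
                f"rule {self.name}: center_exclusion must lie in [0, pool_size)"
            )
        if self.divergence > self.pool_size - self.center_exclusion:
            raise ConfigurationError(
                f"rule {self.name}: divergence {self.divergence} exceeds pool "
                f"{self.pool_size} minus exclusion {self.center_exclusion}"
            )

    @property
    def name(self) -> str:
        return f"{self.pre_type}->{self.post_type}"


#: Healthy-mode connection table (divergence, pool, center exclusion).
#: GC->HIPP divergence is 3 so that mean convergence 500*3/6 = 250 matches
#: the printed table; same-type rules exclude autapses.
HEALTHY_RULES = (
    ConnectionRule("GC", "MC", divergence=1, pool_size=3),
    ConnectionRule("GC", "BC", divergence=1, pool_size=3),
    ConnectionRule("GC", "HIPP", divergence=3, pool_size=5),
    ConnectionRule("MC", "GC", divergence=200, pool_size=350, center_exclusion=50),
    ConnectionRule("MC", "MC", divergence=3, pool_size=6),
    ConnectionRule("MC", "BC", divergence=1, pool_size=3, center_exclusion=1),
    ConnectionRule("MC", "HIPP", divergence=2, pool_size=5),
    ConnectionRule("BC", "GC", divergence=100, pool_size=140),
    ConnectionRule("BC", "MC", divergence=3, pool_size=7),
    ConnectionRule("BC", "BC", divergence=2, pool_size=3),
    ConnectionRule("HIPP", "GC", divergence=160, pool_size=260),
    ConnectionRule("HIPP", "MC", divergence=4, pool_size=5),
    ConnectionRule("HIPP", "BC", divergence=4, pool_size=5),
)

#: Pool from which each granule cell draws its sprouted recurrent contacts.
SPROUTING_POOL = 100


@dataclass
class NetworkModel:
    """A generated connectivity graph plus the spec that produced it."""

    populations: dict[str, PopulationSpec]
    edges: pd.DataFrame  # columns: pre_id, post_id, pre_type, post_type, synapse_ref
    mode: str
    rng_seed: int
    rules: tuple[ConnectionRule, ...] = field(default=HEALTHY_RULES)
    sprouting_degree: int = 0
    mc_loss: int = 0

    @property
    def n_cells(self) -> int:
        return sum(p.count for p in self.populations.values())

    def cell_type_of(self, gid: int) -> str:
        for p in self.populations.values():
            if p.offset <= gid < p.offset + p.count:
                return p.cell_type
        raise KeyError(gid)

    def cell_label(self, gid: int) -> str:
        for p in self.populations.values():
            if p.offset <= gid < p.offset + p.count:
                return f"{p.cell_type}{gid - p.offset}"
        raise KeyError(gid)

    def gid_of(self, label: str) -> int:
        for t in sorted(CELL_TYPES, key=len, reverse=True):
            if label.startswith(t):
                idx = int(label[len(t):])
                pop = self.populations[t]
                if not 0 <= idx < pop.count:
                    raise KeyError(label)
                return pop.offset + idx
        raise KeyError(label)

    def edge_count(self, pre_type: str | None = None, post_type: str | None = None) -> int:
        e = self.edges
        if pre_type is not None:
            e = e[e.pre_type == pre_type]
        if post_type is not None:
            e = e[e.post_type == post_type]
        return len(e)


def place_cells(counts: dict[str, int]) -> dict[str, PopulationSpec]:
    """Lay every population out on [0, 1] with even spacing.

    Deterministic: population ``p`` of size ``n`` occupies positions
    ``(i + 0.5)/n``.  Global ids are assigned contiguously in the fixed
    order GC, MC, BC, HIPP.
    """
    missing = [t for t in CELL_TYPES if t not in counts]
    if missing:
        raise ConfigurationError(f"missing population counts for {missing}")
    unknown = [t for t in counts if t not in CELL_TYPES]
    if unknown:
        raise ConfigurationError(f"unknown cell types {unknown}")
    populations: dict[str, PopulationSpec] = {}
    offset = 0
    for t in CELL_TYPES:
        n = int(counts[t])
        if n < 1:
            raise ConfigurationError(f"population {t} must have count >= 1, got {n}")
        populations[t] = PopulationSpec(cell_type=t, count=n, offset=offset)
        offset += n
    return populations


def _pool_candidates(
    rule: ConnectionRule,
    pre_gid: int,
    pre_pos: float,
    post: PopulationSpec,
) -> np.ndarray:
    """Global ids eligible as targets: the pool minus exclusions and self.

    The pool is the ``pool_size`` target cells nearest the presynaptic
    position by axis distance (ties broken toward the lower index, which on
    an even lattice equals a window clamped inside the population — no
    wraparound).  The ``center_exclusion`` nearest pool members are removed,
    as is the presynaptic cell itself unless the rule allows autapses.
    """
    d = np.abs(post.axis_positions - pre_pos)
    order = np.argsort(d, kind="stable")
    pool = order[: min(rule.pool_size, post.count)]
    eligible = pool[rule.center_exclusion:]
    if not rule.allow_self:
        eligible = eligible[eligible + post.offset != pre_gid]
    return eligible + post.offset


def select_targets(
    rule: ConnectionRule,
    pre_gid: int,
    populations: dict[str, PopulationSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample exactly ``rule.divergence`` distinct targets for one cell."""
    rule.validate()
    pre_pop = populations[rule.pre_type]
    post_pop = populations[rule.post_type]
    pre_pos = pre_pop.axis_positions[pre_gid - pre_pop.offset]
    eligible = _pool_candidates(rule, pre_gid, pre_pos, post_pop)
    if rule.divergence == 0:
        return np.empty(0, dtype=int)
    if len(eligible) < rule.divergence:
        raise GenerationError(
            f"rule {rule.name}: only {len(eligible)} eligible targets for cell "
            f"{pre_gid} but divergence is {rule.divergence}"
        )
    chosen = rng.choice(eligible, size=rule.divergence, replace=False)
    return np.sort(chosen)


def _rule_rng(seed: int, rule: ConnectionRule) -> np.random.Generator:
    # Independent substream per rule so adding/removing one rule leaves the
    # draws of every other rule untouched.
    pre_i = CELL_TYPES.index(rule.pre_type)
    post_i = CELL_TYPES.index(rule.post_type)
    return np.random.default_rng([int(seed), pre_i, post_i])


def _edges_for_rule(
    rule: ConnectionRule,
    populations: dict[str, PopulationSpec],
    seed: int,
) -> pd.DataFrame:
    rng = _rule_rng(seed, rule)
    pre_pop = populations[rule.pre_type]
    pres, posts = [], []
    for gid in pre_pop.global_ids():
        targets = select_targets(rule, int(gid), populations, rng)
        pres.append(np.full(len(targets), gid))
        posts.append(targets)
    pre = np.concatenate(pres) if pres else np.empty(0, dtype=int)
    post = np.concatenate(posts) if posts else np.empty(0, dtype=int)
    return pd.DataFrame(
        {
            "pre_id": pre.astype(int),
            "post_id": post.astype(int),
            "pre_type": rule.pre_type,
            "post_type": rule.post_type,
            "synapse_ref": rule.name,
        }
    )


def generate_network(
    counts: dict[str, int] | None = None,
    mode: str = "healthy",
    seed: int = 0,
    rules: tuple[ConnectionRule, ...] = HEALTHY_RULES,
    sprouting_degree: int = 2,
    mc_loss: int = 0,
    sprouting_pool: int = SPROUTING_POOL,
) -> NetworkModel:
    """Generate the full connectivity graph for one mode and seed.

    Healthy mode applies the rule table only (it must not contain a GC->GC
    rule).  Pathological mode additionally wires ``sprouting_degree``
    recurrent GC->GC contacts per granule cell and then deletes every edge
    of ``mc_loss`` randomly chosen mossy cells.
    """
    if mode not in ("healthy", "pathological"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    populations = place_cells(counts or DEFAULT_COUNTS)
    for rule in rules:
        rule.validate()
        if mode == "healthy" and rule.pre_type == "GC" and rule.post_type == "GC":
            raise ConfigurationError("healthy mode admits no GC->GC rule")

    empty = pd.DataFrame(
        columns=["pre_id", "post_id", "pre_type", "post_type", "synapse_ref"]
    ).astype({"pre_id": int, "post_id": int})
    frames = [empty] + [_edges_for_rule(r, populations, seed) for r in rules]
    applied = list(rules)

    if mode == "pathological":
        if sprouting_degree > 0:
            sprout = ConnectionRule(
                "GC", "GC", divergence=int(sprouting_degree),
                pool_size=int(sprouting_pool),
            )
            sprout.validate()
            frames.append(_edges_for_rule(sprout, populations, seed))
            applied.append(sprout)
        edges = pd.concat(frames, ignore_index=True)
        if mc_loss > 0:
            mc = populations["MC"]
            if mc_loss > mc.count:
                raise ConfigurationError(
                    f"mc_loss {mc_loss} exceeds MC population {mc.count}"
                )
            rng = np.random.default_rng([int(seed), 97])
            lost = rng.choice(mc.global_ids(), size=int(mc_loss), replace=False)
            keep = ~(edges.pre_id.isin(lost) | edges.post_id.isin(lost))
            edges = edges[keep].reset_index(drop=True)
    else:
        edges = pd.concat(frames, ignore_index=True)

    return NetworkModel(
        populations=populations,
        edges=edges,
        mode=mode,
        rng_seed=int(seed),
        rules=tuple(applied),
        sprouting_degree=int(sprouting_degree) if mode == "pathological" else 0,
        mc_loss=int(mc_loss) if mode == "pathological" else 0,
    )


def connectivity_summary(network: NetworkModel) -> pd.DataFrame:
    """Per (pre_type, post_type) divergence/convergence statistics.

    Convergence statistics average over *all* cells of the postsynaptic
    type, including those receiving zero inputs; divergence likewise over
    all presynaptic cells.  With exact per-cell out-degree the mean
    convergence equals pre_count * divergence / post_count exactly.
    """
    rows = []
    pairs = {(r.pre_type, r.post_type) for r in network.rules}
    pairs |= set(map(tuple, network.edges[["pre_type", "post_type"]].drop_duplicates().values))
    for pre_t, post_t in sorted(pairs, key=lambda p: (CELL_TYPES.index(p[0]), CELL_TYPES.index(p[1]))):
        sub = network.edges[(network.edges.pre_type == pre_t) & (network.edges.post_type == post_t)]
        pre_pop = network.populations[pre_t]
        post_pop = network.populations[post_t]
        out_deg = np.zeros(pre_pop.count)
        if len(sub):
            ids, cnt = np.unique(sub.pre_id.to_numpy() - pre_pop.offset, return_counts=True)
            out_deg[ids] = cnt
        in_deg = np.zeros(post_pop.count)
        if len(sub):
            ids, cnt = np.unique(sub.post_id.to_numpy() - post_pop.offset, return_counts=True)
            in_deg[ids] = cnt
        rows.append(
            {
                "pre_type": pre_t,
                "post_type": post_t,
                "edge_count": int(len(sub)),
                "divergence_mean": float(out_deg.mean()),
                "convergence_mean": float(in_deg.mean()),
                "convergence_sd": float(in_deg.std(ddof=0)),
            }
        )
    cols = ["pre_type", "post_type", "edge_count", "divergence_mean",
            "convergence_mean", "convergence_sd"]
    return pd.DataFrame(rows, columns=cols).set_index(["pre_type", "post_type"])


# ---------------------------------------------------------------------------
# Edge-list / metadata I/O

def write_edge_list(network: NetworkModel, path) -> None:
    """TSV with header pre_id/post_id/pre_type/post_type; ids like GC0."""
    df = network.edges.copy()
    df["pre_id"] = [network.cell_label(g) for g in df.pre_id]
    df["post_id"] = [network.cell_label(g) for g in df.post_id]
    df[["pre_id", "post_id", "pre_type", "post_type"]].to_csv(path, sep="\t", index=False)


def read_edge_list(path, counts: dict[str, int] | None = None) -> NetworkModel:
    """Rebuild a NetworkModel (edges + populations) from an edge-list TSV.

    If ``counts`` is omitted the population sizes are inferred as the
    largest index seen per type plus one.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - wrap any pandas parse failure
        raise ParseError(f"cannot parse edge list {path}: {exc}") from exc
    required = {"pre_id", "post_id", "pre_type", "post_type"}
    if not required.issubset(df.columns):
        raise ParseError(f"edge list {path} lacks columns {sorted(required - set(df.columns))}")

    def split(label: str, lineno: int) -> tuple[str, int]:
        for t in sorted(CELL_TYPES, key=len, reverse=True):
            if label.startswith(t) and label[len(t):].isdigit():
                return t, int(label[len(t):])
        raise ParseError(f"{path}: line {lineno}: malformed cell id {label!r}")

    parsed = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pre_t, pre_i = split(row.pre_id, i)
        post_t, post_i = split(row.post_id, i)
        if pre_t != row.pre_type or post_t != row.post_type:
            raise ParseError(f"{path}: line {i}: id/type mismatch")
        parsed.append((pre_t, pre_i, post_t, post_i))
    if counts is None:
        counts = {t: 1 for t in CELL_TYPES}
        for pre_t, pre_i, post_t, post_i in parsed:
            counts[pre_t] = max(counts[pre_t], pre_i + 1)
            counts[post_t] = max(counts[post_t], post_i + 1)
    populations = place_cells(counts)
    rows = [
        {
            "pre_id": populations[pt].offset + pi,
            "post_id": populations[qt].offset + qi,
            "pre_type": pt,
            "post_type": qt,
            "synapse_ref": f"{pt}->{qt}",
        }
        for pt, pi, qt, qi in parsed
    ]
    edges = pd.DataFrame(rows, columns=["pre_id", "post_id", "pre_type", "post_type", "synapse_ref"])
    mode = "healthy" if not ((edges.pre_type == "GC") & (edges.post_type == "GC")).any() else "pathological"
    return NetworkModel(populations=populations, edges=edges, mode=mode, rng_seed=-1, rules=())


def write_metadata(network: NetworkModel, path) -> None:
    meta = {
        "counts": {t: p.count for t, p in network.populations.items()},
        "mode": network.mode,
        "seed": network.rng_seed,
        "sprouting_degree": network.sprouting_degree,
        "mc_loss": network.mc_loss,
        "rules": [
            {
                "pre_type": r.pre_type,
                "post_type": r.post_type,
                "divergence": r.divergence,
                "pool_size": r.pool_size,
                "center_exclusion": r.center_exclusion,
            }
            for r in network.rules
        ],
        "n_edges": int(len(network.edges)),
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)


def scaled_rules(counts: dict[str, int]) -> tuple[ConnectionRule, ...]:
    """Shrink the default rule table to fit small toy populations.

    Pools and divergences are scaled by each population's size relative to
    the defaults, keeping every rule feasible; used for test fixtures and
    quick convergence studies.
    """
    out = []
    for r in HEALTHY_RULES:
        f_post = counts[r.post_type] / DEFAULT_COUNTS[r.post_type]
        pool = max(2, min(int(round(r.pool_size * f_post)), counts[r.post_type]))
        same = r.pre_type == r.post_type
        max_div = pool - (1 if same else 0)
        div = max(1, min(int(round(r.divergence * f_post)), max_div))
        excl = min(r.center_exclusion, max(0, pool - div - (1 if same else 0)))
        out.append(replace(r, divergence=div, pool_size=pool, center_exclusion=excl))
    return tuple(out)
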