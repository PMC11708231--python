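"""Coalescent simulation of five-taxon species trees with gene-flow edges.

The model is a species tree of shape S, A or Q with node times (time 0 =
present, increasing into the past; one unit is roughly 2λNe generations),
per-pair coalescence rate λ within every population, optional ancient
sampling times per leaf, and unidirectional gene-flow edges.  Backward in
time, a lineage present in the target branch at the admixture time switches
into the donor side with probability β — directly into the source branch
when the two branches overlap in time (an instantaneous event), or into an
intermediate ghost population that later joins the source branch.

Mutations follow the infinite-sites model: each gene tree of total branch
length L below the sample MRCA carries k ~ Poisson(μL) mutations placed
uniformly on its branches, each yielding one polarized biallelic pattern.
Mutations above the MRCA are unobservable as polymorphism and are ignored.
Bulk pattern counting uses the exact rare-mutation limit of this protocol
(size-biased tree sampling with one mutation per accepted tree), which keeps
patterns i.i.d.; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import _kernel
from .patterns import PATTERNS, PatternCounts, pattern_from_mask
from .predictions import enumerate_nonzero_events, prediction_table
from .statistics import PANEL_DIVIDER, PANELS, StatisticPanel, compute_panel

__all__ = [
    "LEAVES",
    "GeneFlowEdge",
    "AdmixtureGraphModel",
    "GeneTree",
    "branch_intervals",
    "simulate_gene_tree",
    "drop_mutations",
    "simulate_pattern_counts",
    "build_scenario_model",
    "scenario_suite",
    "ScenarioResult",
    "ScenarioReport",
    "default_node_times",
]

LEAVES = ("1", "2", "3", "4", "5")

_NODE_KEYS = {
    "S": ("12", "34", "1234", "root"),
    "A": ("12", "123", "1234", "root"),
    "Q": ("12", "123", "45", "root"),
}

_DEFAULT_NODE_TIMES = {
    "S": {"12": 1.0, "34": 1.0, "1234": 2.0, "root": 3.0},
    "A": {"12": 0.75, "123": 1.5, "1234": 2.25, "root": 3.0},
    "Q": {"12": 1.0, "123": 2.0, "45": 1.0, "root": 3.0},
}

# population index per branch label (ghosts are appended past these)
_POP_INDEX = {
    "S": {"1": 0, "2": 1, "3": 2, "4": 3, "5": 4, "12": 5, "34": 6, "1234": 7, "12345": 8},
    "A": {"1": 0, "2": 1, "3": 2, "4": 3, "5": 4, "12": 5, "123": 6, "1234": 7, "12345": 8},
    "Q": {"1": 0, "2": 1, "3": 2, "4": 3, "5": 4, "12": 5, "123": 6, "45": 7, "12345": 8},
}

# the node whose time bounds each leaf branch, and that node's own upper bound
_LEAF_PARENT_NODE = {
    "S": {"1": "12", "2": "12", "3": "34", "4": "34", "5": "root"},
    "A": {"1": "12", "2": "12", "3": "123", "4": "1234", "5": "root"},
    "Q": {"1": "12", "2": "12", "3": "123", "4": "45", "5": "45"},
}
_NODE_UPPER = {
    "S": {"12": "1234", "34": "1234", "1234": "root"},
    "A": {"12": "123", "123": "1234", "1234": "root"},
    "Q": {"12": "123", "123": "root", "45": "root"},
}


def default_node_times(shape: str) -> Dict[str, float]:
    return dict(_DEFAULT_NODE_TIMES[shape])


def branch_intervals(shape: str, node_times: Dict[str, float]) -> Dict[str, Tuple[float, float]]:
    """Existence interval (start, end) of every branch, in time before present."""
    t = node_times
    inf = math.inf
    if shape == "S":
        return {
            "1": (0.0, t["12"]), "2": (0.0, t["12"]),
            "3": (0.0, t["34"]), "4": (0.0, t["34"]),
            "5": (0.0, t["root"]),
            "12": (t["12"], t["1234"]), "34": (t["34"], t["1234"]),
            "1234": (t["1234"], t["root"]), "12345": (t["root"], inf),
        }
    if shape == "A":
        return {
            "1": (0.0, t["12"]), "2": (0.0, t["12"]),
            "3": (0.0, t["123"]), "4": (0.0, t["1234"]), "5": (0.0, t["root"]),
            "12": (t["12"], t["123"]), "123": (t["123"], t["1234"]),
            "1234": (t["1234"], t["root"]), "12345": (t["root"], inf),
        }
    if shape == "Q":
        return {
            "1": (0.0, t["12"]), "2": (0.0, t["12"]),
            "3": (0.0, t["123"]), "4": (0.0, t["45"]), "5": (0.0, t["45"]),
            "12": (t["12"], t["123"]), "123": (t["123"], t["root"]),
            "45": (t["45"], t["root"]), "12345": (t["root"], inf),
        }
    raise ValueError(f"unknown tree shape {shape!r}")


@dataclass
class GeneFlowEdge:
    """Unidirectional gene flow from branch ``source`` into branch ``target``.

    ``time`` is the admixture time (within the target branch); ``ghost_join``,
    if set, is the later time at which the mediating ghost population joins
    the source branch.  ``beta`` is the admixture proportion.
    """

    source: str
    target: str
    time: float
    beta: float = 0.1
    ghost_join: Optional[float] = None


@dataclass
class AdmixtureGraphModel:
    shape: str
    node_times: Dict[str, float] = field(default_factory=dict)
    sampling_times: Dict[str, float] = field(default_factory=dict)
    lam: float = 1.0
    mu: float = 1e-4
    edges: List[GeneFlowEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shape not in _NODE_KEYS:
            raise ValueError(f"unknown tree shape {self.shape!r}")
        nt = default_node_times(self.shape)
        nt.update(self.node_times)
        self.node_times = nt
        st = {leaf: 0.0 for leaf in LEAVES}
        st.update({str(k): float(v) for k, v in self.sampling_times.items()})
        self.sampling_times = st
        self.validate()

    def validate(self) -> None:
        t = self.node_times
        shape = self.shape
        order = {
            "S": [("12", "1234"), ("34", "1234"), ("1234", "root")],
            "A": [("12", "123"), ("123", "1234"), ("1234", "root")],
            "Q": [("12", "123"), ("123", "root"), ("45", "root")],
        }[shape]
        for key in _NODE_KEYS[shape]:
            if t[key] <= 0:
                raise ValueError(f"node time {key} must be positive")
        for lo, hi in order:
            if not t[lo] < t[hi]:
                raise ValueError(f"node times must increase towards the root: {lo} < {hi}")
        if self.lam <= 0:
            raise ValueError("coalescence rate lambda must be positive")
        if self.mu < 0:
            raise ValueError("mutation intensity mu must be non-negative")
        iv = branch_intervals(shape, t)
        for leaf in LEAVES:
            st = self.sampling_times[leaf]
            if not 0.0 <= st < iv[leaf][1]:
                raise ValueError(
                    f"sampling time of leaf {leaf} must lie within its branch")
        for e in self.edges:
            if e.source == e.target:
                raise ValueError("gene-flow edge must connect distinct branches")
            for b in (e.source, e.target):
                if b not in iv:
                    raise ValueError(f"unknown branch label {b!r} for shape {shape}")
            if not 0.0 <= e.beta < 1.0:
                raise ValueError("admixture proportion beta must be in [0, 1)")
            t0, t1 = iv[e.target]
            if not t0 <= e.time <= t1:
                raise ValueError(
                    f"admixture time {e.time} outside target branch {e.target} {iv[e.target]}")
            s0, s1 = iv[e.source]
            if e.ghost_join is None:
                if not s0 <= e.time <= s1:
                    raise ValueError(
                        f"edge {e.source}->{e.target}: source branch does not exist at "
                        f"time {e.time}; a ghost_join time is required")
            else:
                if not e.ghost_join > e.time:
                    raise ValueError("ghost_join must be later (deeper) than the admixture time")
                if not s0 <= e.ghost_join <= s1:
                    raise ValueError(
                        f"ghost_join {e.ghost_join} outside source branch {e.source} {iv[e.source]}")

    # --- serialization ---
    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "node_times": dict(self.node_times),
            "sampling_times": dict(self.sampling_times),
            "lambda": self.lam,
            "mu": self.mu,
            "edges": [
                {k: v for k, v in
                 dict(source=e.source, target=e.target, time=e.time,
                      beta=e.beta, ghost_join=e.ghost_join).items()
                 if v is not None}
                for e in self.edges
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AdmixtureGraphModel":
        edges = [
            GeneFlowEdge(
                source=str(e["source"]), target=str(e["target"]),
                time=float(e["time"]), beta=float(e.get("beta", 0.1)),
                ghost_join=(float(e["ghost_join"]) if e.get("ghost_join") is not None else None),
            )
            for e in d.get("edges", [])
        ]
        return cls(
            shape=d["shape"],
            node_times={k: float(v) for k, v in d.get("node_times", {}).items()},
            sampling_times={str(k): float(v) for k, v in d.get("sampling_times", {}).items()},
            lam=float(d.get("lambda", d.get("lam", 1.0))),
            mu=float(d.get("mu", 1e-4)),
            edges=edges,
        )

    @classmethod
    def from_yaml(cls, path) -> "AdmixtureGraphModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # --- event compilation ---
    def compile_events(self):
        """Time-sorted event arrays for the coalescent walk.

        Returns ``(ev_time, ev_type, ev_a, ev_b, ev_p, n_pops)`` with the
        encoding documented in :mod:`deltastats._kernel`.
        """
        shape = self.shape
        pops = dict(_POP_INDEX[shape])
        t = self.node_times
        events: List[Tuple[float, int, int, int, float]] = []
        for i, leaf in enumerate(LEAVES):
            events.append((self.sampling_times[leaf], 0, i, pops[leaf], 0.0))
        merges = {
            "S": [("1", "12"), ("2", "12"), ("3", "34"), ("4", "34"),
                  ("12", "1234"), ("34", "1234"), ("1234", "12345"), ("5", "12345")],
            "A": [("1", "12"), ("2", "12"), ("12", "123"), ("3", "123"),
                  ("123", "1234"), ("4", "1234"), ("1234", "12345"), ("5", "12345")],
            "Q": [("1", "12"), ("2", "12"), ("12", "123"), ("3", "123"),
                  ("4", "45"), ("5", "45"), ("123", "12345"), ("45", "12345")],
        }[shape]
        iv = branch_intervals(shape, t)
        for child, parent in merges:
            events.append((iv[child][1], 2, pops[child], pops[parent], 0.0))
        n_pops = len(pops)
        for e in self.edges:
            if e.ghost_join is None:
                events.append((e.time, 1, pops[e.target], pops[e.source], e.beta))
            else:
                ghost = n_pops
                n_pops += 1
                events.append((e.time, 1, pops[e.target], ghost, e.beta))
                events.append((e.ghost_join, 2, ghost, pops[e.source], 0.0))
        events.sort(key=lambda ev: (ev[0], ev[1]))
        ev_time = np.array([ev[0] for ev in events], dtype=np.float64)
        ev_type = np.array([ev[1] for ev in events], dtype=np.int64)
        ev_a = np.array([ev[2] for ev in events], dtype=np.int64)
        ev_b = np.array([ev[3] for ev in events], dtype=np.int64)
        ev_p = np.array([ev[4] for ev in events], dtype=np.float64)
        return ev_time, ev_type, ev_a, ev_b, ev_p, n_pops


# --- gene trees (reference pure-Python path) -------------------------------

@dataclass
class GeneTreeNode:
    time: float
    children: Tuple["GeneTreeNode", ...] = ()
    leaf: Optional[int] = None  # 0-based leaf index

    @property
    def mask(self) -> int:
        if self.leaf is not None:
            return 1 << self.leaf
        m = 0
        for c in self.children:
            m |= c.mask
        return m


@dataclass
class GeneTree:
    """Binary gene tree over the five sampled lineages."""

    root: GeneTreeNode

    def edges(self) -> List[Tuple[int, float]]:
        """(descendant mask, length) of every edge below the root."""
        out: List[Tuple[int, float]] = []

        def rec(node: GeneTreeNode) -> int:
            m = (1 << node.leaf) if node.leaf is not None else 0
            for c in node.children:
                cm = rec(c)
                out.append((cm, node.time - c.time))
                m |= cm
            return m

        rec(self.root)
        return out

    @property
    def total_branch_length(self) -> float:
        return sum(length for _, length in self.edges())

    def newick(self) -> str:
        def rec(node: GeneTreeNode, parent_time: float) -> str:
            if node.leaf is not None:
                label = str(node.leaf + 1)
            else:
                label = "(" + ",".join(rec(c, node.time) for c in node.children) + ")"
            return f"{label}:{parent_time - node.time:.6g}"

        root = self.root
        return "(" + ",".join(rec(c, root.time) for c in root.children) + ");"


def simulate_gene_tree(model: AdmixtureGraphModel, rng: np.random.Generator) -> GeneTree:
    """One structured-coalescent gene tree (readable reference implementation).

    Backward in time: within a population every lineage pair coalesces at
    rate λ; at an admixture event each lineage in the target branch switches
    to the donor side with probability β; at species-tree nodes populations
    merge; ancient tips enter at their sampling time.
    """
    ev_time, ev_type, ev_a, ev_b, ev_p, _ = model.compile_events()
    lineages: List[Tuple[int, GeneTreeNode]] = []  # (pop, node)
    n_leaves = int(np.sum(ev_type == 0))
    n_entered = 0
    t = 0.0
    iev = 0
    nev = len(ev_time)
    while True:
        te = ev_time[iev] if iev < nev else math.inf
        pairs = [
            (i, j)
            for i in range(len(lineages))
            for j in range(i + 1, len(lineages))
            if lineages[i][0] == lineages[j][0]
        ]
        tc = t + rng.exponential(1.0 / (model.lam * len(pairs))) if pairs else math.inf
        if tc < te:
            i, j = pairs[rng.integers(len(pairs))]
            pop, a = lineages[i]
            _, b = lineages[j]
            parent = GeneTreeNode(time=tc, children=(a, b))
            lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
            lineages.append((pop, parent))
            t = tc
            if len(lineages) == 1 and n_entered == n_leaves:
                return GeneTree(root=lineages[0][1])
        else:
            if iev >= nev:
                raise RuntimeError("event list exhausted before coalescence completed")
            ty = ev_type[iev]
            if ty == 0:
                lineages.append(
                    (int(ev_b[iev]), GeneTreeNode(time=te, leaf=int(ev_a[iev])))
                )
                n_entered += 1
            elif ty == 1:
                if ev_p[iev] > 0.0:  # beta=0 edges must not perturb the RNG stream
                    lineages = [
                        ((int(ev_b[iev]) if pop == ev_a[iev] and rng.random() < ev_p[iev] else pop), node)
                        for pop, node in lineages
                    ]
            else:
                lineages = [
                    ((int(ev_b[iev]) if pop == ev_a[iev] else pop), node)
                    for pop, node in lineages
                ]
            t = te
            iev += 1


def drop_mutations(genetree: GeneTree, mu: float, rng: np.random.Generator) -> List[str]:
    """Poisson infinite-sites mutations on a gene tree -> polarized patterns.

    k ~ Poisson(μ · total branch length); each mutation falls on a branch
    with probability proportional to its length and yields the pattern whose
    minority allele marks the branch's descendant leaves.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    edges = genetree.edges()
    lengths = np.array([length for _, length in edges], dtype=float)
    total = float(lengths.sum())
    if total <= 0 or mu == 0:
        return []
    k = rng.poisson(mu * total)
    if k == 0:
        return []
    idx = rng.choice(len(edges), size=k, p=lengths / total)
    return [pattern_from_mask(edges[i][0]) for i in idx]


# --- bulk pattern simulation ----------------------------------------------

_MASK_TO_ROW = np.full(32, -1, dtype=np.int64)
for _m in range(1, 31):
    _c = _m if bin(_m).count("1") <= 2 else _m ^ 31
    _MASK_TO_ROW[_m] = PATTERNS.index(pattern_from_mask(_c))


def simulate_pattern_counts(
    model: AdmixtureGraphModel, n_patterns: int, seed: int
) -> PatternCounts:
    """Accumulate ``n_patterns`` polarized site patterns under the model.

    Patterns are i.i.d. draws from the stationary single-mutation pattern
    distribution of the model (the rare-mutation limit of the Poisson
    protocol in :func:`drop_mutations`); the run is reproducible under a
    fixed seed.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    ev_time, ev_type, ev_a, ev_b, ev_p, _ = model.compile_events()
    counts, n_trees = _kernel._sim_pattern_counts(
        np.int64(seed % (2**31)), np.int64(n_patterns),
        ev_time, ev_type, ev_a, ev_b, ev_p, float(model.lam), _MASK_TO_ROW,
    )
    if n_trees < 0:  # pragma: no cover - guarded by model validation
        raise RuntimeError("coalescent walk failed; malformed model")
    pc = PatternCounts.from_array(counts.astype(float))
    pc.n_sites_retained = int(n_patterns)
    return pc


# --- scenario construction and the sign-recovery suite ---------------------

def build_scenario_model(
    tree: str, event: str, beta: float = 0.1,
    sampling_times: Optional[Dict[str, float]] = None,
    lam: float = 1.0, mu: float = 1e-4,
) -> AdmixtureGraphModel:
    """Admixture-graph model realizing one unidirectional gene-flow event.

    The admixture edge is instantaneous when the source and target branches
    overlap in time, and ghost-mediated when the source branch is deeper than
    the target.  A handful of events (e.g. 3->12 in S) name a source terminal
    branch that, under the default node times, ends before the target branch
    begins; for those the source leaf's parent-node time is raised to the
    midpoint of its allowed interval so the event becomes realizable.
    """
    event = event.replace("→", "->").replace(" ", "")
    source, target = event.split("->")
    node_times = default_node_times(tree)
    iv = branch_intervals(tree, node_times)
    if source not in iv or target not in iv:
        raise ValueError(f"unknown branch in event {event!r} for tree {tree}")

    s0, s1 = iv[source]
    t0, t1 = iv[target]
    stretched = False
    if min(s1, t1) <= max(s0, t0) and s1 <= t1:
        # source ends before the target branch begins: stretch the source
        # terminal branch by delaying its parent node to 80% of its allowed
        # interval, leaving the introgressed lineages a long co-residence
        # with the donor (signal strength comparable to unstretched events)
        node = _LEAF_PARENT_NODE[tree].get(source)
        if node is None or node == "root":
            raise ValueError(f"event {event!r} is not realizable on tree {tree}")
        upper_key = _NODE_UPPER[tree].get(node, "root")
        upper = node_times[upper_key] if node != "root" else math.inf
        node_times[node] = t0 + 0.8 * (upper - t0)
        stretched = True
        iv = branch_intervals(tree, node_times)
        s0, s1 = iv[source]
        t0, t1 = iv[target]

    lo, hi = max(s0, t0), min(s1, t1)
    if hi > lo:  # instantaneous
        # early placement in a stretched overlap maximizes donor exposure
        t_a = lo + 0.1 * (hi - lo) if stretched else (lo + hi) / 2.0
        edge = GeneFlowEdge(source=source, target=target, time=t_a, beta=beta)
    else:  # ghost-mediated: source is deeper than the target branch
        t_a = (t0 + t1) / 2.0
        g0 = max(t_a, s0)
        g1 = s1 if math.isfinite(s1) else g0 + 1.0
        t_g = (g0 + g1) / 2.0
        edge = GeneFlowEdge(source=source, target=target, time=t_a, beta=beta,
                            ghost_join=t_g)
    return AdmixtureGraphModel(
        shape=tree, node_times=node_times,
        sampling_times=sampling_times or {},
        lam=lam, mu=mu, edges=[edge],
    )


@dataclass
class ScenarioResult:
    event: str
    predicted: Tuple[str, ...]
    observed: Tuple[str, ...]
    panel: StatisticPanel

    @property
    def full_match(self) -> bool:
        return self.predicted == self.observed

    def matches(self, upto: Optional[int] = None) -> bool:
        if upto is None:
            return self.full_match
        return self.predicted[:upto] == self.observed[:upto]


@dataclass
class ScenarioReport:
    tree: str
    n_patterns: int
    include_singletons: bool
    results: List[ScenarioResult]

    @property
    def n_match(self) -> int:
        return sum(r.full_match for r in self.results)

    def n_match_nonsingleton(self) -> int:
        div = PANEL_DIVIDER[self.tree]
        return sum(r.matches(div) for r in self.results)

    def to_rows(self) -> List[dict]:
        from .predictions import format_signature

        div = PANEL_DIVIDER[self.tree] if self.include_singletons else None
        rows = []
        for r in self.results:
            row = {
                "event": r.event,
                "predicted": format_signature(r.predicted, div),
                "observed": format_signature(r.observed, div),
                "match": r.full_match,
            }
            for res in r.panel.results:
                row[f"{res.name}.scaled"] = res.scaled
                row[f"{res.name}.Z"] = res.z
            rows.append(row)
        return rows


def scenario_suite(
    tree: str,
    n_patterns: int,
    seed: int,
    alpha: float = 0.01,
    include_singletons: bool = True,
    beta: float = 0.1,
    events: Optional[Sequence[str]] = None,
) -> ScenarioReport:
    """Simulate every nonzero-signature event and compare classifications.

    For each event the admixture-graph model is built, ``n_patterns``
    patterns are simulated with a per-scenario substream of the master seed,
    the preferred panel is evaluated and its sign tuple is compared to the
    prediction table.
    """
    if events is None:
        events = enumerate_nonzero_events(tree)
    table = prediction_table(tree, include_singletons=include_singletons)
    ss = np.random.SeedSequence(seed)
    subseeds = ss.generate_state(len(events)).astype(np.int64) % (2**31)
    results = []
    for event, sub in zip(events, subseeds):
        model = build_scenario_model(tree, event, beta=beta)
        counts = simulate_pattern_counts(model, n_patterns, int(sub))
        panel = compute_panel(counts, tree, include_singletons=include_singletons,
                              alpha=alpha)
        predicted = table.signature_of(event)
        results.append(
            ScenarioResult(event=event, predicted=predicted,
                           observed=panel.classifications, panel=panel)
        )
    return ScenarioReport(tree=tree, n_patterns=n_patterns,
                          include_singletons=include_singletons, results=results)
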