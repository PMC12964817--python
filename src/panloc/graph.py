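"""Variation graphs: GFA I/O, path depth, node classes, differential subregions.

A variation graph is the joint coordinate system of a local pangenome:
nodes carry sequence segments, oriented edges connect them, and each
haplotype or assembly is embedded as a named path. Sample identity is the
path-name prefix before a delimiter (default ``'#'``, PanSN style), so the
two haplotype paths of one sample count once toward node depth.

Node classes follow pangenome convention: a node traversed by every sample
is *core*, by exactly one sample *private*, anything in between *variable*.
An allele of a structural variant shows up as a run of variable nodes that
share one carrier-sample set; :func:`detect_differential_subregions` groups
variable nodes by that signature and merges them along a designated
backbone path, replacing the visual inspection a graph viewer would offer
with a deterministic algorithm.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict, deque
from dataclasses import dataclass, field
from statistics import median
from typing import IO, Iterable, Mapping, NamedTuple

__all__ = [
    "VariationGraph",
    "GfaError",
    "NodeDepthTable",
    "NodeClassification",
    "SubregionCall",
    "GraphStats",
    "parse_gfa",
    "write_gfa",
    "path_node_depth",
    "classify_nodes",
    "backbone_positions",
    "detect_differential_subregions",
    "extract_subgraph",
    "graph_stats",
    "path_sequence",
]

#: An oriented path step: (node id, is_reverse).
Step = tuple[str, bool]


class GfaError(ValueError):
    pass


@dataclass
class _NodeInfo:
    length: int
    sequence: str | None = None


def _canonical_edge(a: Step, b: Step) -> tuple[Step, Step]:
    """An edge and its reverse complement are the same adjacency."""
    fwd = (a, b)
    rev = ((b[0], not b[1]), (a[0], not a[1]))
    return min(fwd, rev)


class VariationGraph:
    """Nodes with lengths/sequences, oriented edges, named haplotype paths."""

    def __init__(self) -> None:
        self.nodes: dict[str, _NodeInfo] = {}
        self.edges: set[tuple[Step, Step]] = set()
        self.paths: dict[str, list[Step]] = {}

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, sequence: str | None = None, length: int | None = None) -> None:
        if sequence is not None:
            length = len(sequence)
        if length is None or length <= 0:
            raise GfaError(f"node {node_id!r} needs a positive length or a sequence")
        self.nodes[node_id] = _NodeInfo(length=length, sequence=sequence)

    def add_edge(self, a: Step, b: Step) -> None:
        for step in (a, b):
            if step[0] not in self.nodes:
                raise GfaError(f"edge references missing node {step[0]!r}")
        self.edges.add(_canonical_edge(a, b))

    def add_path(self, name: str, steps: Iterable[Step], create_edges: bool = True) -> None:
        steps = list(steps)
        if not steps:
            raise GfaError(f"path {name!r} has no steps")
        for node_id, _ in steps:
            if node_id not in self.nodes:
                raise GfaError(f"path {name!r} references missing node {node_id!r}")
        if create_edges:
            for a, b in zip(steps, steps[1:]):
                self.edges.add(_canonical_edge(a, b))
        self.paths[name] = steps

    # -- queries ----------------------------------------------------------
    def node_length(self, node_id: str) -> int:
        return self.nodes[node_id].length

    def has_edge(self, a: Step, b: Step) -> bool:
        return _canonical_edge(a, b) in self.edges

    def neighbors(self) -> dict[str, set[str]]:
        """Orientation-blind node adjacency (for BFS over the topology)."""
        adj: dict[str, set[str]] = defaultdict(set)
        for (a, _), (b, _) in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def __repr__(self) -> str:
        return (
            f"VariationGraph({len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"{len(self.paths)} paths)"
        )


def sample_of(path_name: str, delimiter: str = "#") -> str:
    """Sample identity of a path: the prefix before the first delimiter."""
    return path_name.split(delimiter, 1)[0]


# ---------------------------------------------------------------------------
# GFA I/O

_W_STEP_RE = re.compile(r"([><])([^\s><]+)")


def _parse_p_steps(path_name: str, spec: str) -> list[Step]:
    steps: list[Step] = []
    for token in spec.split(","):
        if not token or token[-1] not in "+-":
            raise GfaError(f"path {path_name!r}: malformed step {token!r}")
        steps.append((token[:-1], token[-1] == "-"))
    return steps


def parse_gfa(stream: IO[str] | Iterable[str]) -> VariationGraph:
    """Parse GFA 1.0 S/L/P lines; GFA 1.1 W lines are converted to paths.

    A W line ``W sample hap seq start end >1<2`` becomes the path
    ``sample#hap#seq`` with the same steps, so both dialects load into the
    same in-memory graph. Edges implied by path step pairs but missing from
    the L lines are added during construction, keeping the every-step-pair-
    is-an-edge invariant true.
    """
    graph = VariationGraph()
    deferred: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        kind = cols[0]
        if kind == "S":
            if len(cols) < 3:
                raise GfaError(f"GFA line {lineno}: S line needs id and sequence")
            node_id, seq = cols[1], cols[2]
            if seq == "*":
                ln = next(
                    (int(c.split(":")[2]) for c in cols[3:] if c.startswith("LN:i:")),
                    None,
                )
                if ln is None:
                    raise GfaError(
                        f"GFA line {lineno}: node {node_id!r} has no sequence and no LN tag"
                    )
                graph.add_node(node_id, length=ln)
            else:
                graph.add_node(node_id, sequence=seq)
        elif kind in {"L", "P", "W"}:
            deferred.append((lineno, cols))
        elif kind == "H":
            continue
        else:
            continue  # other record types are not needed here
    for lineno, cols in deferred:
        kind = cols[0]
        try:
            if kind == "L":
                if len(cols) < 5:
                    raise GfaError("L line needs from/to fields")
                graph.add_edge((cols[1], cols[2] == "-"), (cols[3], cols[4] == "-"))
            elif kind == "P":
                if len(cols) < 3:
                    raise GfaError("P line needs a name and steps")
                graph.add_path(cols[1], _parse_p_steps(cols[1], cols[2]))
            else:  # W
                if len(cols) < 7:
                    raise GfaError("W line needs 6 fields and a walk")
                name = f"{cols[1]}#{cols[2]}#{cols[3]}"
                steps = [(m[1], m[0] == "<") for m in _W_STEP_RE.findall(cols[6])]
                if not steps:
                    raise GfaError(f"W line for {name!r} has an empty walk")
                graph.add_path(name, steps)
        except GfaError as exc:
            raise GfaError(f"GFA line {lineno}: {exc}") from None
    return graph


def _natural_key(node_id: str):
    return (0, int(node_id)) if node_id.isdigit() else (1, node_id)


def write_gfa(graph: VariationGraph, dest) -> None:
    from ._util import _as_handle

    handle, owned = _as_handle(dest)
    try:
        handle.write("H\tVN:Z:1.0\n")
        for node_id in sorted(graph.nodes, key=_natural_key):
            info = graph.nodes[node_id]
            if info.sequence is not None:
                handle.write(f"S\t{node_id}\t{info.sequence}\n")
            else:
                handle.write(f"S\t{node_id}\t*\tLN:i:{info.length}\n")
        for (a, ao), (b, bo) in sorted(graph.edges):
            handle.write(
                f"L\t{a}\t{'-' if ao else '+'}\t{b}\t{'-' if bo else '+'}\t0M\n"
            )
        for name, steps in graph.paths.items():
            spec = ",".join(f"{nid}{'-' if rev else '+'}" for nid, rev in steps)
            handle.write(f"P\t{name}\t{spec}\t*\n")
    finally:
        if owned:
            handle.close()


def path_sequence(graph: VariationGraph, name: str) -> str:
    """Concatenate node sequences along a path (reverse-complementing '<' steps)."""
    from ._util import revcomp

    chunks = []
    for node_id, rev in graph.paths[name]:
        seq = graph.nodes[node_id].sequence
        if seq is None:
            raise GfaError(f"node {node_id!r} has no sequence; cannot spell path {name!r}")
        chunks.append(revcomp(seq) if rev else seq)
    return "".join(chunks)


# ---------------------------------------------------------------------------
# Depth and classification


@dataclass
class NodeDepthTable:
    """Per-node traversal multiplicity per path, plus distinct-sample depth.

    ``depth[n]`` counts distinct samples whose paths traverse node ``n``
    (0 for untraversed nodes); ``multiplicity[n][p]`` counts how many times
    path ``p`` steps on ``n`` (cycles count every traversal).
    """

    multiplicity: dict[str, dict[str, int]]
    samples: dict[str, frozenset[str]]
    depth: dict[str, int]
    n_samples: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": list(self.depth),
                "depth": list(self.depth.values()),
                "max_multiplicity": [
                    max(self.multiplicity[n].values()) if self.multiplicity.get(n) else 0
                    for n in self.depth
                ],
            }
        )


def path_node_depth(graph: VariationGraph, delimiter: str = "#") -> NodeDepthTable:
    """Traversal multiplicity and distinct-sample depth for every node."""
    if not graph.paths:
        raise ValueError("graph has no paths; depth is undefined")
    multiplicity: dict[str, dict[str, int]] = defaultdict(dict)
    node_samples: dict[str, set[str]] = defaultdict(set)
    all_samples: set[str] = set()
    for name, steps in graph.paths.items():
        sample = sample_of(name, delimiter)
        all_samples.add(sample)
        counts = Counter(nid for nid, _ in steps)
        for nid, k in counts.items():
            multiplicity[nid][name] = k
            node_samples[nid].add(sample)
    depth = {nid: len(node_samples.get(nid, ())) for nid in graph.nodes}
    return NodeDepthTable(
        multiplicity=dict(multiplicity),
        samples={n: frozenset(s) for n, s in node_samples.items()},
        depth=depth,
        n_samples=len(all_samples),
    )


@dataclass
class NodeClassification:
    labels: dict[str, str]  # traversed nodes only
    counts: Counter

    def __getitem__(self, node_id: str) -> str:
        return self.labels[node_id]


def classify_nodes(depth_table: NodeDepthTable, n_samples: int | None = None) -> NodeClassification:
    """Label traversed nodes core / variable / private by distinct-sample depth."""
    if n_samples is None:
        n_samples = depth_table.n_samples
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    labels: dict[str, str] = {}
    for node, depth in depth_table.depth.items():
        if depth > n_samples:
            raise ValueError(
                f"node {node!r} has depth {depth} > n_samples {n_samples}: inconsistent input"
            )
        if depth == 0:
            continue
        if depth == n_samples:
            labels[node] = "core"
        elif depth == 1:
            labels[node] = "private"
        else:
            labels[node] = "variable"
    return NodeClassification(labels=labels, counts=Counter(labels.values()))


# ---------------------------------------------------------------------------
# Backbone ordering and differential subregions


def backbone_positions(graph: VariationGraph, backbone: str) -> dict[str, int]:
    """Order every node by a designated backbone path.

    Backbone nodes take their first-traversal index along the backbone path;
    off-backbone nodes inherit the position of the nearest positioned
    neighbor by multi-source BFS over the (orientation-blind) topology, so
    the ordering is defined even when the graph is not a DAG. Nodes in
    components disjoint from the backbone are left out.
    """
    if backbone not in graph.paths:
        raise ValueError(f"no backbone path {backbone!r} in graph")
    pos: dict[str, int] = {}
    for idx, (nid, _) in enumerate(graph.paths[backbone]):
        pos.setdefault(nid, idx)
    adj = graph.neighbors()
    queue = deque(sorted(pos, key=lambda n: pos[n]))
    while queue:
        cur = queue.popleft()
        for nxt in adj.get(cur, ()):
            if nxt not in pos:
                pos[nxt] = pos[cur]
                queue.append(nxt)
    return pos


@dataclass
class SubregionCall:
    """A candidate structural-variant allele: variable nodes sharing carriers.

    ``node_length`` is the summed length of the member nodes; when carrier
    paths traverse the members multiple times (a tandem-repeat allele
    collapsed onto shared nodes) ``inserted_length`` scales each node by the
    median carrier traversal multiplicity, estimating the inserted sequence
    length; ``copy_number`` is that typical per-allele multiplicity.
    """

    nodes: list[str]
    node_length: int
    inserted_length: int
    carriers: frozenset[str]
    anchor: int
    copy_number: float


def _sample_multiplicity(
    depth_table: NodeDepthTable, node: str, sample: str, delimiter: str
) -> int:
    return max(
        (
            k
            for path, k in depth_table.multiplicity.get(node, {}).items()
            if sample_of(path, delimiter) == sample
        ),
        default=0,
    )


def detect_differential_subregions(
    graph: VariationGraph,
    depth_table: NodeDepthTable,
    backbone: str,
    min_total_len: int = 1_000,
    min_carriers: int = 2,
    max_gap: int = 5,
    delimiter: str = "#",
) -> list[SubregionCall]:
    """Find runs of variable nodes shared by one carrier-sample set.

    Variable nodes (``1 < depth < n_samples``) are grouped by their exact
    carrier-sample set, ordered along the backbone, split where more than
    ``max_gap`` backbone positions intervene, and reported when the
    estimated inserted length reaches ``min_total_len`` with at least
    ``min_carriers`` carriers. Calls are sorted by inserted length
    descending, ties by backbone position.
    """
    pos = backbone_positions(graph, backbone)
    n = depth_table.n_samples
    groups: dict[frozenset[str], list[str]] = defaultdict(list)
    for node, depth in depth_table.depth.items():
        if 1 < depth < n:
            groups[depth_table.samples[node]].append(node)
    calls: list[SubregionCall] = []
    for carriers, nodes in groups.items():
        placed = sorted(
            (node for node in nodes if node in pos),
            key=lambda node: (pos[node], _natural_key(node)),
        )
        runs: list[list[str]] = []
        for node in placed:
            if runs and pos[node] - pos[runs[-1][-1]] - 1 <= max_gap:
                runs[-1].append(node)
            else:
                runs.append([node])
        for run in runs:
            node_length = sum(graph.node_length(node) for node in run)
            per_node_cn = [
                max(
                    1.0,
                    median(
                        _sample_multiplicity(depth_table, node, s, delimiter)
                        for s in carriers
                    ),
                )
                for node in run
            ]
            inserted = round(
                sum(graph.node_length(node) * cn for node, cn in zip(run, per_node_cn))
            )
            if inserted < min_total_len or len(carriers) < min_carriers:
                continue
            length_weights = [graph.node_length(node) for node in run]
            copy_number = sum(
                cn * w for cn, w in zip(per_node_cn, length_weights)
            ) / sum(length_weights)
            calls.append(
                SubregionCall(
                    nodes=run,
                    node_length=node_length,
                    inserted_length=inserted,
                    carriers=carriers,
                    anchor=min(pos[node] for node in run),
                    copy_number=copy_number,
                )
            )
    calls.sort(key=lambda c: (-c.inserted_length, c.anchor, c.nodes[0]))
    return calls


# ---------------------------------------------------------------------------
# Subgraph extraction and stats


def extract_subgraph(
    graph: VariationGraph, node_set: Iterable[str], flank: int = 50
) -> VariationGraph:
    """Induced subgraph over ``node_set`` plus up to ``flank`` BFS hops of context.

    Paths are trimmed to maximal sub-walks within the retained nodes; a path
    split into several parts is renamed with a ``_partN`` suffix (an intact
    path keeps its name). Applying the same extraction twice is idempotent.
    """
    node_set = set(node_set)
    if not node_set:
        raise ValueError("node set is empty")
    missing = node_set - graph.nodes.keys()
    if missing:
        raise ValueError(f"nodes absent from graph: {sorted(missing)[:5]}")
    keep = set(node_set)
    if flank > 0:
        adj = graph.neighbors()
        frontier = set(node_set)
        for _ in range(flank):
            frontier = {
                nxt for cur in frontier for nxt in adj.get(cur, ()) if nxt not in keep
            }
            if not frontier:
                break
            keep |= frontier
    sub = VariationGraph()
    for nid in keep:
        info = graph.nodes[nid]
        sub.nodes[nid] = _NodeInfo(length=info.length, sequence=info.sequence)
    for edge in graph.edges:
        (a, _), (b, _) = edge
        if a in keep and b in keep:
            sub.edges.add(edge)
    for name, steps in graph.paths.items():
        parts: list[list[Step]] = []
        current: list[Step] = []
        for step in steps:
            if step[0] in keep:
                current.append(step)
            elif current:
                parts.append(current)
                current = []
        if current:
            parts.append(current)
        if not parts:
            continue
        if len(parts) == 1:
            sub.paths[name] = parts[0]
        else:
            for i, part in enumerate(parts, start=1):
                sub.paths[f"{name}_part{i}"] = part
    return sub


class GraphStats(NamedTuple):
    n_nodes: int
    n_edges: int
    total_bp: int
    n_paths: int


def graph_stats(graph: VariationGraph) -> GraphStats:
    return GraphStats(
        n_nodes=len(graph.nodes),
        n_edges=len(graph.edges),
        total_bp=sum(info.length for info in graph.nodes.values()),
        n_paths=len(graph.paths),
    )
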