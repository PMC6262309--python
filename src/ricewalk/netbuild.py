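"""Build the functional similarity network from a protein-interaction edge list.

The background network is an undirected protein-association edge list in the
STRING "protein links" dialect (whitespace-separated ``protein1 protein2
combined_score`` rows, optional header).  Node IDs are optionally
standardized through a mapping table, and every surviving edge is weighted
by the WSF functional similarity of its endpoints
(:func:`ricewalk.annotations.shared_function_score`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .annotations import AnnotationIndex, shared_function_score
from .errors import DataError

__all__ = [
    "EdgeList",
    "BuildReport",
    "FunctionalNetwork",
    "load_edge_list",
    "load_id_map",
    "standardize_ids",
    "build_functional_network",
    "write_network",
    "load_network",
    "write_edge_list",
]


@dataclass(frozen=True)
class EdgeList:
    """Cleaned undirected edge records ``(node_a, node_b, source_score)``.

    No self-loops; each unordered pair appears once with node_a < node_b.
    """

    records: tuple[tuple[str, str, float], ...]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "EdgeList":
        """Canonicalize: drop self-loops, collapse duplicate undirected
        pairs keeping the maximum score, order deterministically."""
        best: dict[tuple[str, str], float] = {}
        for a, b, score in records:
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if score > best.get(key, float("-inf")):
                best[key] = score
        return cls(tuple((a, b, best[(a, b)]) for a, b in sorted(best)))

    def nodes(self) -> list[str]:
        seen = {n for a, b, _ in self.records for n in (a, b)}
        return sorted(seen)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class BuildReport:
    """Summary counts emitted by :func:`build_functional_network`."""

    n_nodes: int
    n_edges: int
    n_zero_weight_edges: int
    zero_weight_policy: str


@dataclass(frozen=True)
class FunctionalNetwork:
    """Undirected weighted graph with deterministic (lexicographic) node order.

    ``edges`` maps each unordered pair, stored as ``(a, b)`` with ``a < b``,
    to its WSF weight; ``source_scores`` carries the original edge-list
    scores for provenance.  No self-loops are stored: the restart term of
    the walk already lets the walker stay in place.
    """

    nodes: tuple[str, ...]
    edges: Mapping[tuple[str, str], float]
    source_scores: Mapping[tuple[str, str], float] = field(default_factory=dict)
    report: BuildReport | None = field(default=None, compare=False)

    def __post_init__(self):
        if tuple(sorted(self.nodes)) != self.nodes:
            raise DataError("FunctionalNetwork nodes must be lexicographically sorted")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, node: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for (a, b), w in self.edges.items():
            if a == node:
                out[b] = w
            elif b == node:
                out[a] = w
        return out


def load_edge_list(path: str | Path, score_threshold: float = 0.0) -> EdgeList:
    """Read a STRING protein-links file.

    Whitespace-separated columns ``protein1 protein2 combined_score`` with
    an optional header.  Self-loops are dropped, duplicate undirected pairs
    collapse to the maximum score, and records scoring below
    ``score_threshold`` are removed (default 0 keeps everything).
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise DataError(f"cannot read edge list {path}: {exc}") from exc
    records: list[tuple[str, str, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise DataError(
                f"line {lineno}: expected 'protein1 protein2 combined_score', got {line!r}"
            )
        a, b, raw_score = fields[0], fields[1], fields[2]
        try:
            score = float(raw_score)
        except ValueError:
            # a single non-numeric score in the first row is a header
            if lineno == 1 and not records:
                continue
            raise DataError(f"line {lineno}: non-numeric score {raw_score!r}") from None
        if score >= score_threshold:
            records.append((a, b, score))
    edges = EdgeList.from_records(records)
    if not edges.records:
        raise DataError(f"no surviving edges in {path} (threshold {score_threshold})")
    return edges


def load_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping raw node IDs to standardized gene IDs."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 2:
            raise DataError(f"line {lineno}: expected 'raw_id<TAB>gene_id'")
        mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def standardize_ids(
    edges: EdgeList,
    idmap: Mapping[str, str],
    policy: str = "drop_unmapped",
) -> EdgeList:
    """Replace raw node IDs with standardized gene IDs.

    ``drop_unmapped`` removes edges touching a node absent from the map;
    ``keep_raw`` passes unmapped IDs through unchanged.  Mapping collisions
    merge nodes: duplicate undirected pairs re-collapse to the maximum
    score, and pairs that become self-loops are dropped.
    """
    if policy not in ("drop_unmapped", "keep_raw"):
        raise DataError(f"unknown unmapped-node policy: {policy!r}")
    out: list[tuple[str, str, float]] = []
    for a, b, score in edges.records:
        if policy == "drop_unmapped" and (a not in idmap or b not in idmap):
            continue
        out.append((idmap.get(a, a), idmap.get(b, b), score))
    return EdgeList.from_records(out)


def build_functional_network(
    edges: EdgeList,
    index: AnnotationIndex,
    zero_weight_policy: str = "drop",
    retain_isolated: bool = False,
) -> FunctionalNetwork:
    """Assemble the WSF-weighted functional similarity network.

    Each edge ``(i, j)`` gets weight ``F(i, j)``; under the default
    ``drop`` policy, edges whose endpoints share no functions (weight 0)
    are removed — they would carry no walk probability in weighted mode.
    ``retain_isolated=True`` keeps every endpoint of the input edge list as
    a node even if all its edges were dropped.

    The returned network carries a :class:`BuildReport` in ``.report``.
    """
    if zero_weight_policy not in ("drop", "keep"):
        raise DataError(f"unknown zero-weight policy: {zero_weight_policy!r}")
    if not edges.records:
        raise DataError("cannot build a network from an empty edge list")
    weighted: dict[tuple[str, str], float] = {}
    scores: dict[tuple[str, str], float] = {}
    n_zero = 0
    for a, b, score in edges.records:
        w = shared_function_score(index, a, b)
        if w == 0.0:
            n_zero += 1
            if zero_weight_policy == "drop":
                continue
        weighted[(a, b)] = w
        scores[(a, b)] = score
    if retain_isolated:
        node_set = set(edges.nodes())
    else:
        node_set = {n for pair in weighted for n in pair}
    if not weighted:
        raise DataError(
            "all edges have zero shared-function weight; rerun with "
            "zero_weight_policy='keep' or use unweighted mode"
        )
    nodes = tuple(sorted(node_set))
    report = BuildReport(
        n_nodes=len(nodes),
        n_edges=len(weighted),
        n_zero_weight_edges=n_zero,
        zero_weight_policy=zero_weight_policy,
    )
    return FunctionalNetwork(nodes=nodes, edges=weighted, source_scores=scores, report=report)


# ---------------------------------------------------------------------------
# serialization: TSV edge list (gene_a, gene_b, weight, source_score)

_HEADER = "gene_a\tgene_b\tweight\tsource_score"


def write_network(network: FunctionalNetwork, path: str | Path) -> None:
    """Serialize to a TSV edge list; isolated nodes are listed in a trailing
    comment block so the round-trip preserves the node set exactly."""
    path = Path(path)
    lines = [_HEADER]
    connected = {n for pair in network.edges for n in pair}
    for (a, b), w in sorted(network.edges.items()):
        s = network.source_scores.get((a, b), 0.0)
        lines.append(f"{a}\t{b}\t{w!r}\t{s!r}")
    for node in network.nodes:
        if node not in connected:
            lines.append(f"#isolated\t{node}")
    path.write_text("\n".join(lines) + "\n")


def load_network(path: str | Path) -> FunctionalNetwork:
    """Load a network serialized by :func:`write_network`."""
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    scores: dict[tuple[str, str], float] = {}
    isolated: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#isolated\t"):
            isolated.append(line.split("\t", 1)[1])
            continue
        if lineno == 1 and line == _HEADER:
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise DataError(f"line {lineno}: expected 4 tab-separated columns")
        a, b = fields[0], fields[1]
        key = (a, b) if a < b else (b, a)
        try:
            edges[key] = float(fields[2])
            scores[key] = float(fields[3])
        except ValueError:
            raise DataError(f"line {lineno}: non-numeric weight or score") from None
    if not edges and not isolated:
        raise DataError(f"empty network file {path}")
    nodes = tuple(sorted({n for pair in edges for n in pair} | set(isolated)))
    return FunctionalNetwork(nodes=nodes, edges=edges, source_scores=scores)


def write_edge_list(edges: EdgeList, path: str | Path, header: bool = True) -> None:
    """Write an edge list in STRING protein-links dialect."""
    path = Path(path)
    lines = ["protein1 protein2 combined_score"] if header else []
    for a, b, score in edges.records:
        s = int(score) if float(score).is_integer() else score
        lines.append(f"{a} {b} {s}")
    path.write_text("\n".join(lines) + "\n")
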