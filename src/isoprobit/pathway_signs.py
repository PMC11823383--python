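"""Signed directed path search in a causal interaction network.

Edges carry SIGNOR-style causal annotations — up-regulation,
down-regulation, physical interaction, unknown — and a path's net
regulatory effect is the product of its edge signs: any unknown edge makes
the whole path unknown; otherwise the path is negative iff it contains an
odd number of down-regulating edges.  Physical-interaction edges are
sign-neutral (they pass the incoming sign through).

A curated fixture network connecting the deacetylases SIRT1/SIRT3 with
tubulin (the molecular targets of a SIRT1 inhibitor and of paclitaxel) is
packaged with the module; see :func:`load_fixture_graph`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "Effect",
    "Sign",
    "CausalEdge",
    "CausalGraph",
    "CausalPath",
    "EdgeListParseError",
    "MAX_PATH_LENGTH_CAP",
    "parse_edge_list",
    "load_fixture_graph",
    "compose_signs",
    "shortest_path_length",
    "enumerate_simple_paths",
]

#: Hard cap on simple-path enumeration depth (guards exponential blow-up).
MAX_PATH_LENGTH_CAP = 12


class Effect(str, enum.Enum):
    UP = "up_regulates"
    DOWN = "down_regulates"
    PHYSICAL = "physical"
    UNKNOWN = "unknown"

    @property
    def glyph(self) -> str:
        return _EFFECT_GLYPHS[self]


class Sign(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNKNOWN = "unknown"


_EFFECT_GLYPHS = {
    Effect.UP: "→",
    Effect.DOWN: "―|",
    Effect.PHYSICAL: "―[]",
    Effect.UNKNOWN: "―?",
}

#: Accepted effect tokens (plain words plus the common arrow glyphs).
EFFECT_TOKENS: dict[str, Effect] = {
    "up": Effect.UP,
    "up_regulates": Effect.UP,
    "→": Effect.UP,
    "->": Effect.UP,
    "down": Effect.DOWN,
    "down_regulates": Effect.DOWN,
    "―|": Effect.DOWN,
    "-|": Effect.DOWN,
    "physical": Effect.PHYSICAL,
    "―[]": Effect.PHYSICAL,
    "-[]": Effect.PHYSICAL,
    "unknown": Effect.UNKNOWN,
    "―?": Effect.UNKNOWN,
    "-?": Effect.UNKNOWN,
}


class EdgeListParseError(ValueError):
    """Raised on a malformed edge-list row; carries the 1-based line number."""


@dataclass(frozen=True)
class CausalEdge:
    source: str
    target: str
    effect: Effect
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.weight is not None and self.weight < 0:
            raise ValueError("edge weight must be non-negative")


class CausalGraph:
    """A signed directed interaction network.

    Thin wrapper over a :class:`networkx.MultiDiGraph` (multi-edges allow
    the same ordered pair to carry distinct causal effects).
    """

    def __init__(self, edges: Iterable[CausalEdge] = ()) -> None:
        self._g = nx.MultiDiGraph()
        for edge in edges:
            self.add_edge(edge)

    def add_edge(self, edge: CausalEdge) -> None:
        weight = 1.0 if edge.weight is None else edge.weight
        self._g.add_edge(edge.source, edge.target, effect=edge.effect, weight=weight)

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> list[CausalEdge]:
        return [
            CausalEdge(u, v, data["effect"], data.get("weight"))
            for u, v, data in self._g.edges(data=True)
        ]

    @property
    def nx_graph(self) -> nx.MultiDiGraph:
        return self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()


@dataclass(frozen=True)
class CausalPath:
    """A simple directed path with per-edge effects and its net sign."""

    node_sequence: tuple[str, ...]
    edge_effects: tuple[Effect, ...]
    net_sign: Sign

    def __post_init__(self) -> None:
        if len(self.node_sequence) != len(self.edge_effects) + 1:
            raise ValueError("node and effect counts inconsistent")
        if len(set(self.node_sequence)) != len(self.node_sequence):
            raise ValueError("path must be simple (no repeated node)")

    @property
    def length(self) -> int:
        return len(self.edge_effects)

    def pathway_string(self) -> str:
        """Render like ``SIRT1→ AKT→ S1PR1→ GNAI1→ Tubulin``."""
        parts = []
        for node, effect in zip(self.node_sequence, self.edge_effects):
            parts.append(f"{node}{effect.glyph}")
        parts.append(self.node_sequence[-1])
        return " ".join(parts)


def parse_edge_list(source) -> CausalGraph:
    """Parse a SIF-like TSV edge list ``source<TAB>effect<TAB>target``.

    ``source`` may be a path or an iterable of lines.  Blank lines and
    ``#`` comments are skipped; an optional fourth column is read as a
    non-negative edge weight.  Unknown effect tokens raise
    :class:`EdgeListParseError` naming the token and line number.
    """
    if isinstance(source, (str, Path)):
        lines: Iterable[str] = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = source
    edges: list[CausalEdge] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (3, 4):
            raise EdgeListParseError(
                f"line {lineno}: expected 3 or 4 tab-separated fields, "
                f"got {len(fields)}"
            )
        src, token, dst = (f.strip() for f in fields[:3])
        effect = EFFECT_TOKENS.get(token)
        if effect is None:
            raise EdgeListParseError(
                f"line {lineno}: unknown effect token {token!r}"
            )
        weight = None
        if len(fields) == 4:
            try:
                weight = float(fields[3])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"line {lineno}: bad weight {fields[3]!r}"
                ) from exc
        edges.append(CausalEdge(src, dst, effect, weight))
    return CausalGraph(edges)


def load_fixture_graph() -> CausalGraph:
    """The packaged SIRT1/SIRT3–tubulin causal network fixture."""
    ref = resources.files("isoprobit").joinpath("data/sirt_tubulin_edges.tsv")
    return parse_edge_list(ref.read_text(encoding="utf-8").splitlines())


def compose_signs(effects: Iterable[Effect]) -> Sign:
    """Net regulatory sign of an ordered effect sequence.

    Any unknown edge is absorbing; physical edges are neutral; otherwise
    an odd number of down-regulations flips the sign to negative.
    """
    effects = tuple(effects)
    if not effects:
        raise ValueError("effect sequence must be non-empty")
    if any(e is Effect.UNKNOWN for e in effects):
        return Sign.UNKNOWN
    downs = sum(1 for e in effects if e is Effect.DOWN)
    return Sign.NEGATIVE if downs % 2 else Sign.POSITIVE


def shortest_path_length(graph: CausalGraph, src: str, dst: str) -> int | None:
    """Minimal directed edge count from src to dst (None if unreachable)."""
    g = graph.nx_graph
    for node in (src, dst):
        if node not in g:
            raise KeyError(f"node {node!r} not in graph")
    try:
        return int(nx.shortest_path_length(g, src, dst))
    except nx.NetworkXNoPath:
        return None


def enumerate_simple_paths(
    graph: CausalGraph, src: str, dst: str, max_length: int = 8
) -> list[CausalPath]:
    """All simple directed paths of length ≤ max_length, sign-annotated.

    Multi-edges with distinct effects yield distinct paths.  The result is
    sorted by (length, node sequence, effect sequence) so enumeration is
    deterministic across runs and platforms.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    if max_length > MAX_PATH_LENGTH_CAP:
        raise ValueError(
            f"max_length {max_length} exceeds the hard cap "
            f"{MAX_PATH_LENGTH_CAP}; raise MAX_PATH_LENGTH_CAP deliberately "
            "if the graph is known to be small"
        )
    g = graph.nx_graph
    for node in (src, dst):
        if node not in g:
            raise KeyError(f"node {node!r} not in graph")
    paths: list[CausalPath] = []
    for edge_path in nx.all_simple_edge_paths(g, src, dst, cutoff=max_length):
        nodes = tuple([edge_path[0][0]] + [e[1] for e in edge_path])
        effects = tuple(g.edges[e]["effect"] for e in edge_path)
        paths.append(CausalPath(nodes, effects, compose_signs(effects)))
    paths.sort(
        key=lambda p: (p.length, p.node_sequence, tuple(e.value for e in p.edge_effects))
    )
    return paths
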