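"""Directed, optionally signed gene regulatory networks and their file formats.

A :class:`GeneNetwork` is a directed graph over named genes. Edges may carry a
regulatory sign (+1 activation, -1 repression). Six small benchmark topologies
(the branching/linear/cyclic families commonly used to benchmark GRN inference)
ship with the package as plain edge-list CSV files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "GeneNetwork",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
    "remove_edge",
    "benchmark_network",
    "BENCHMARK_NAMES",
]

_SIGN_TOKENS = {"+": 1, "-": -1, "1": 1, "-1": -1, "+1": 1}

BENCHMARK_NAMES = (
    "bifurcating",
    "bifurcating-converging",
    "trifurcating",
    "cycle",
    "linear",
    "long-linear",
)


@dataclass(frozen=True)
class GeneNetwork:
    """Directed gene regulatory network with optional edge signs.

    Parameters
    ----------
    genes
        Ordered gene identifiers; order fixes the adjacency-matrix indexing.
    edges
        Set of ordered ``(source, target)`` pairs. Self-loops are allowed.
    signs
        Optional map from edge to {+1, -1}. Edges absent from the map are
        treated as activating (+1) by consumers that care about signs.
    """

    genes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    signs: Mapping[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("duplicate gene identifiers")
        for s, t in self.edges:
            if s not in gene_set or t not in gene_set:
                raise ValueError(f"edge endpoint not a listed gene: ({s}, {t})")
        for e, sg in self.signs.items():
            if e not in self.edges:
                raise ValueError(f"sign given for non-edge {e}")
            if sg not in (1, -1):
                raise ValueError(f"sign must be +1 or -1, got {sg}")

    @property
    def m(self) -> int:
        """Number of genes."""
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency, ``A[i, j] = 1`` iff gene_i -> gene_j."""
        idx = {g: i for i, g in enumerate(self.genes)}
        A = np.zeros((self.m, self.m), dtype=np.int8)
        for s, t in self.edges:
            A[idx[s], idx[t]] = 1
        return A

    def signed_adjacency(self) -> np.ndarray:
        """Adjacency with entries in {-1, 0, +1}; missing signs default to +1."""
        idx = {g: i for i, g in enumerate(self.genes)}
        A = np.zeros((self.m, self.m), dtype=np.int8)
        for s, t in self.edges:
            A[idx[s], idx[t]] = self.signs.get((s, t), 1)
        return A

    def sign(self, source: str, target: str) -> int:
        if (source, target) not in self.edges:
            raise KeyError(f"no edge ({source}, {target})")
        return self.signs.get((source, target), 1)

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self.edges

    def non_edges(self, include_self: bool = True) -> list[tuple[str, str]]:
        """All ordered gene pairs not in the edge set, in deterministic order."""
        out = []
        for s in self.genes:
            for t in self.genes:
                if not include_self and s == t:
                    continue
                if (s, t) not in self.edges:
                    out.append((s, t))
        return out

    def with_edges(
        self,
        extra: Iterable[tuple[str, str]],
        signs: Mapping[tuple[str, str], int] | None = None,
    ) -> "GeneNetwork":
        """Return a copy with additional edges (idempotent for existing ones)."""
        new_edges = set(self.edges) | set(extra)
        new_signs = dict(self.signs)
        if signs:
            new_signs.update(signs)
        return GeneNetwork(self.genes, frozenset(new_edges), new_signs)


def read_edge_list(text_source, delimiter: str = ",") -> GeneNetwork:
    """Parse an edge-list text (``Gene1,Gene2[,Sign]`` per line).

    Gene order is the order of first appearance (sources before targets within
    a line). A header line whose first two fields look like ``Gene1/Gene2`` is
    skipped. Duplicate edge lines collapse to a single edge; conflicting signs
    for the same edge raise.
    """
    if isinstance(text_source, str):
        text_source = io.StringIO(text_source)
    genes: list[str] = []
    seen: set[str] = set()
    edges: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], int] = {}

    def note(g: str) -> None:
        if g not in seen:
            seen.add(g)
            genes.append(g)

    for lineno, raw in enumerate(text_source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split(delimiter)]
        if lineno == 1 and fields[0].lower() in ("gene1", "source", "regulator"):
            continue
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"line {lineno}: expected at least 2 fields, got {line!r}")
        s, t = fields[0], fields[1]
        sign = None
        if len(fields) >= 3 and fields[2]:
            tok = fields[2]
            if tok not in _SIGN_TOKENS:
                raise ValueError(f"line {lineno}: unknown sign token {tok!r}")
            sign = _SIGN_TOKENS[tok]
        note(s)
        note(t)
        edge = (s, t)
        if sign is not None:
            if edge in signs and signs[edge] != sign:
                raise ValueError(f"line {lineno}: conflicting signs for edge {edge}")
            signs[edge] = sign
        edges.add(edge)
    return GeneNetwork(tuple(genes), frozenset(edges), signs)


def write_edge_list(net: GeneNetwork, delimiter: str = ",") -> str:
    """Serialize deterministically (genes in stored order, targets likewise)."""
    order = {g: i for i, g in enumerate(net.genes)}
    lines = [delimiter.join(("Gene1", "Gene2", "Sign"))]
    for s, t in sorted(net.edges, key=lambda e: (order[e[0]], order[e[1]])):
        sg = net.signs.get((s, t))
        tok = "" if sg is None else ("+" if sg > 0 else "-")
        lines.append(delimiter.join((s, t, tok)))
    return "\n".join(lines) + "\n"


def read_adjacency(text_source) -> GeneNetwork:
    """Read an m x m 0/1 adjacency CSV with gene names as header row/column."""
    import pandas as pd

    df = pd.read_csv(text_source, index_col=0)
    genes = tuple(str(g) for g in df.columns)
    if tuple(str(g) for g in df.index) != genes:
        raise ValueError("adjacency row and column gene names differ")
    A = df.to_numpy()
    if not np.isin(A, (0, 1)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    edges = frozenset(
        (genes[i], genes[j]) for i, j in zip(*np.nonzero(A), strict=True)
    )
    return GeneNetwork(genes, edges)


def write_adjacency(net: GeneNetwork) -> str:
    import pandas as pd

    df = pd.DataFrame(net.adjacency(), index=net.genes, columns=net.genes)
    return df.to_csv()


def remove_edge(net: GeneNetwork, source: str, target: str) -> GeneNetwork:
    """Return a copy of ``net`` without the edge ``source -> target``.

    The input is unchanged; removing a non-edge is an error.
    """
    if (source, target) not in net.edges:
        raise ValueError(f"edge ({source}, {target}) not present in the network")
    new_edges = frozenset(e for e in net.edges if e != (source, target))
    new_signs = {e: s for e, s in net.signs.items() if e != (source, target)}
    return GeneNetwork(net.genes, new_edges, new_signs)


def benchmark_network(name: str) -> GeneNetwork:
    """Load one of the packaged benchmark topologies.

    Valid names: bifurcating, bifurcating-converging, trifurcating, cycle,
    linear, long-linear. The branching fixtures realize a toggle-switch motif
    (mutually inhibiting arms with self-activation) fed by an upstream chain,
    which is what produces the common-start-then-split trajectory geometry.
    """
    if name not in BENCHMARK_NAMES:
        raise ValueError(
            f"unknown benchmark network {name!r}; valid names: {', '.join(BENCHMARK_NAMES)}"
        )
    fname = f"{name.replace('-', '_')}.csv"
    text = resources.files("grndyn.data").joinpath(fname).read_text()
    return read_edge_list(text)
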