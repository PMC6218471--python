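"""Gene-circuit topology: data model, text I/O, and shipped benchmark circuits.

A circuit is a small directed, signed graph: nodes are genes, edges are
transcriptional interactions that either activate or inhibit the target.
The topology is the *only* required input to the whole pipeline; kinetic
parameters are randomized downstream.

The on-disk format is the three-column whitespace-delimited table used
throughout the RACIPE ecosystem::

    Source  Target  Type
    A       B       2
    B       A       2

with ``Type`` 1 for activation and 2 for inhibition.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

ACTIVATION = 1
INHIBITION = 2

_TYPE_NAMES = {ACTIVATION: "activation", INHIBITION: "inhibition"}


class Edge(NamedTuple):
    """A directed regulatory interaction ``source -> target``."""

    source: str
    target: str
    kind: int  # ACTIVATION or INHIBITION

    @property
    def is_self_loop(self) -> bool:
        return self.source == self.target


@dataclass(frozen=True)
class Circuit:
    """A gene regulatory circuit: ordered genes plus signed edges.

    Gene order is deterministic and defines the column order of every
    expression matrix produced downstream.  Self-loops are allowed
    (self-activating switches); duplicate (source, target) pairs are not.
    """

    name: str
    genes: tuple[str, ...]
    edges: tuple[Edge, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("circuit must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers in gene list")
        seen: set[tuple[str, str]] = set()
        for e in self.edges:
            if e.kind not in _TYPE_NAMES:
                raise ValueError(
                    f"unknown interaction type {e.kind!r} for edge "
                    f"{e.source}->{e.target} (expected 1=activation, 2=inhibition)"
                )
            if e.source not in self.genes or e.target not in self.genes:
                raise ValueError(f"edge {e.source}->{e.target} has endpoint outside gene list")
            key = (e.source, e.target)
            if key in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            seen.add(key)

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edge endpoints and kinds as integer arrays (source idx, target idx, kind)."""
        idx = {g: i for i, g in enumerate(self.genes)}
        src = np.array([idx[e.source] for e in self.edges], dtype=np.intp)
        tgt = np.array([idx[e.target] for e in self.edges], dtype=np.intp)
        kind = np.array([e.kind for e in self.edges], dtype=np.intp)
        return src, tgt, kind

    def self_activation_edges(self) -> list[int]:
        """Indices of self-activating edges (used by induction experiments)."""
        return [
            i for i, e in enumerate(self.edges) if e.is_self_loop and e.kind == ACTIVATION
        ]

    @classmethod
    def from_edges(cls, name: str, rows: Iterable[tuple[str, str, int]]) -> "Circuit":
        """Build a circuit from (source, target, type) rows.

        Genes are ordered by first appearance (source before target within
        a row), which fixes the downstream matrix column order.
        """
        genes: list[str] = []
        edges: list[Edge] = []
        for source, target, kind in rows:
            for g in (source, target):
                if g not in genes:
                    genes.append(g)
            edges.append(Edge(source, target, int(kind)))
        return cls(name=name, genes=tuple(genes), edges=tuple(edges))


def read_topology(path: str | os.PathLike, name: str | None = None) -> Circuit:
    """Read a circuit from a RACIPE-style three-column topology file.

    The first line is treated as a header when its third field is not an
    integer.  Raises ``ValueError`` on unknown type codes, malformed rows,
    duplicate edges, or an empty file.
    """
    rows: list[tuple[str, str, int]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"topology file {path!s} is empty")
    start = 0
    first = lines[0].split()
    if len(first) == 3 and not first[2].lstrip("+-").isdigit():
        start = 1  # header line
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split()
        if len(fields) != 3:
            raise ValueError(
                f"{path!s}:{lineno}: expected 3 whitespace-separated fields, got {len(fields)}"
            )
        source, target, raw = fields
        try:
            kind = int(raw)
        except ValueError as exc:
            raise ValueError(f"{path!s}:{lineno}: interaction type {raw!r} is not an integer") from exc
        if kind not in _TYPE_NAMES:
            raise ValueError(
                f"{path!s}:{lineno}: unknown interaction type {kind} "
                "(expected 1=activation, 2=inhibition)"
            )
        rows.append((source, target, kind))
    if not rows:
        raise ValueError(f"topology file {path!s} contains no edge rows")
    if name is None:
        name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return Circuit.from_edges(name, rows)


def write_topology(circuit: Circuit, path: str | os.PathLike) -> None:
    """Write a circuit in the three-column topology format (round-trips with
    :func:`read_topology`)."""
    if not circuit.edges:
        raise ValueError("cannot write a circuit with no edges to a topology file")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("Source\tTarget\tType\n")
        for e in circuit.edges:
            fh.write(f"{e.source}\t{e.target}\t{e.kind}\n")


# -- shipped benchmark circuits ------------------------------------------

def _five_ts_rows() -> list[tuple[str, str, int]]:
    # Five mutually-inhibiting pairs (A_i, B_i) coupled in a ring:
    # B_i additionally inhibits A_{i+1 mod 5}.
    rows: list[tuple[str, str, int]] = []
    for i in range(1, 6):
        rows.append((f"A{i}", f"B{i}", INHIBITION))
        rows.append((f"B{i}", f"A{i}", INHIBITION))
    for i in range(1, 6):
        j = i % 5 + 1
        rows.append((f"B{i}", f"A{j}", INHIBITION))
    return rows


_FIXTURES: dict[str, list[tuple[str, str, int]]] = {
    # plain toggle switch: two mutually inhibiting genes
    "TS": [("A", "B", INHIBITION), ("B", "A", INHIBITION)],
    # toggle switch with one self-activation
    "TS_SA1": [("A", "A", ACTIVATION), ("A", "B", INHIBITION), ("B", "A", INHIBITION)],
    # toggle switch with self-activation on both genes (quadrastable-capable)
    "TS_SA2": [
        ("A", "A", ACTIVATION),
        ("B", "B", ACTIVATION),
        ("A", "B", INHIBITION),
        ("B", "A", INHIBITION),
    ],
    "FIVE_TS": _five_ts_rows(),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture_circuit(name: str) -> Circuit:
    """Return one of the shipped benchmark circuits.

    ``TS``      plain toggle switch (2 genes, 2 inhibitions)
    ``TS_SA1``  toggle switch, one gene self-activating (3 edges)
    ``TS_SA2``  toggle switch, both genes self-activating (4 edges)
    ``FIVE_TS`` five coupled toggle switches in an inhibitory ring (10 genes)
    """
    key = name.upper()
    if key not in _FIXTURES:
        raise ValueError(f"unknown fixture circuit {name!r}; choose from {FIXTURE_NAMES}")
    return Circuit.from_edges(key, _FIXTURES[key])
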