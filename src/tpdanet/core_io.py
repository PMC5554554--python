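"""Domain types and I/O: expression/phenotype datasets, mixed networks, CPTs.

The central objects are :class:`ExpressionDataset` (a samples x variables
numeric table with per-variable role labels), :class:`Network` (a mixed graph
with directed trait->gene arcs and undirected gene-gene edges), and
:class:`CPTable` (a discrete conditional probability table).  Datasets are
read from plain CSV; networks round-trip through a deterministic TSV edge
list.
"""

from __future__ import annotations

import csv
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataFormatError, SizeError, StructureError, UnknownNameError

GENE = "gene"
TRAIT = "trait"

_EDGE_LIST_COLUMNS = ["source", "target", "type", "stage", "score"]


@dataclass
class ExpressionDataset:
    """Continuous samples x variables table with gene/trait role labels.

    Parameters
    ----------
    sample_ids : list of str
        One identifier per row (inbred line / sample).
    variable_names : list of str
        Unique column names, order preserved from the source.
    roles : mapping of variable name -> ``"gene"`` or ``"trait"``.
    reported : set of str
        Subset of gene variables flagged as literature-reported positives.
    values : ndarray, shape (n_samples, n_variables)
        Finite float matrix; expression in arbitrary quantification units,
        traits in phenotype units.
    """

    sample_ids: list[str]
    variable_names: list[str]
    roles: dict[str, str]
    reported: set[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.variable_names)) != len(self.variable_names):
            raise UnknownNameError("variable names are not unique")
        if self.values.ndim != 2 or self.values.shape != (
            len(self.sample_ids),
            len(self.variable_names),
        ):
            raise SizeError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variable_names)} variables"
            )
        if self.values.shape[0] < 3:
            raise SizeError("at least 3 samples are required")
        if self.values.shape[1] < 2:
            raise SizeError("at least 2 variables are required")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataFormatError(
                f"non-finite value at row {bad[0]}, column "
                f"{self.variable_names[bad[1]]!r}"
            )
        missing = [v for v in self.variable_names if v not in self.roles]
        if missing:
            raise UnknownNameError(f"no role for variables: {missing}")
        bad_roles = {v: r for v, r in self.roles.items() if r not in (GENE, TRAIT)}
        if bad_roles:
            raise DataFormatError(f"invalid roles: {bad_roles}")
        self.reported = set(self.reported)
        not_genes = [v for v in self.reported if self.roles.get(v) != GENE]
        if not_genes:
            raise UnknownNameError(
                f"reported names must be gene variables: {not_genes}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def genes(self) -> list[str]:
        return [v for v in self.variable_names if self.roles[v] == GENE]

    @property
    def traits(self) -> list[str]:
        return [v for v in self.variable_names if self.roles[v] == TRAIT]

    def index(self, name: str) -> int:
        try:
            return self.variable_names.index(name)
        except ValueError:
            raise UnknownNameError(f"unknown variable {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.index(name)]


def _canon_undirected(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class EdgeProvenance:
    """Stage that created an edge and the MI/CMI value at decision time."""

    stage: str
    score: float


class Network:
    """Mixed graph over named variables.

    Directed edges carry the trait-as-root orientation (trait -> gene);
    gene-gene dependencies stay undirected because the learner never orients
    them.  No pair may appear twice, in either edge class.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        directed_edges: Iterable[tuple[str, str]] = (),
        undirected_edges: Iterable[tuple[str, str]] = (),
        provenance: Mapping[tuple[str, str], EdgeProvenance] | None = None,
    ) -> None:
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise UnknownNameError("duplicate node names")
        self._node_set = set(self.nodes)
        self.directed_edges: list[tuple[str, str]] = []
        self.undirected_edges: list[tuple[str, str]] = []
        self.provenance: dict[tuple[str, str], EdgeProvenance] = {}
        prov = dict(provenance or {})
        for u, v in directed_edges:
            self.add_directed(u, v, *self._prov_args(prov, (u, v)))
        for u, v in undirected_edges:
            self.add_undirected(u, v, *self._prov_args(prov, _canon_undirected(u, v)))

    @staticmethod
    def _prov_args(
        prov: Mapping[tuple[str, str], EdgeProvenance], key: tuple[str, str]
    ) -> tuple[str, float]:
        p = prov.get(key)
        return (p.stage, p.score) if p else ("unknown", math.nan)

    def _check_new_edge(self, u: str, v: str) -> None:
        for n in (u, v):
            if n not in self._node_set:
                raise UnknownNameError(f"unknown node {n!r}")
        if u == v:
            raise StructureError(f"self-loop on {u!r}")
        if self.has_edge(u, v):
            raise StructureError(f"pair ({u!r}, {v!r}) already has an edge")

    def add_directed(self, u: str, v: str, stage: str = "unknown", score: float = math.nan) -> None:
        self._check_new_edge(u, v)
        self.directed_edges.append((u, v))
        self.provenance[(u, v)] = EdgeProvenance(stage, score)

    def add_undirected(self, u: str, v: str, stage: str = "unknown", score: float = math.nan) -> None:
        self._check_new_edge(u, v)
        key = _canon_undirected(u, v)
        self.undirected_edges.append(key)
        self.provenance[key] = EdgeProvenance(stage, score)

    def remove_undirected(self, u: str, v: str) -> EdgeProvenance:
        key = _canon_undirected(u, v)
        try:
            self.undirected_edges.remove(key)
        except ValueError:
            raise UnknownNameError(f"no undirected edge {key}") from None
        return self.provenance.pop(key)

    def has_edge(self, u: str, v: str) -> bool:
        """True if the pair is linked, by an arc in either direction or undirected."""
        return (
            (u, v) in self.provenance
            or (v, u) in self.provenance
            or _canon_undirected(u, v) in self.provenance
        )

    def skeleton(self):
        """The undirected view of all edges, as a networkx Graph."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed_edges)
        g.add_edges_from(self.undirected_edges)
        return g

    def skeleton_edges(self) -> set[tuple[str, str]]:
        """All edges as canonical unordered pairs."""
        out = {_canon_undirected(u, v) for u, v in self.directed_edges}
        out.update(self.undirected_edges)
        return out

    def copy(self) -> "Network":
        net = Network(self.nodes)
        net.directed_edges = list(self.directed_edges)
        net.undirected_edges = list(self.undirected_edges)
        net.provenance = dict(self.provenance)
        return net

    def validate(self, roles: Mapping[str, str] | None = None) -> None:
        """Check structural invariants; raise StructureError on violation."""
        import networkx as nx

        seen: set[tuple[str, str]] = set()
        for u, v in self.directed_edges + self.undirected_edges:
            if u == v:
                raise StructureError(f"self-loop on {u!r}")
            key = _canon_undirected(u, v)
            if key in seen:
                raise StructureError(f"duplicate pair {key}")
            seen.add(key)
        dg = nx.DiGraph(self.directed_edges)
        if not nx.is_directed_acyclic_graph(dg):
            raise StructureError("directed part contains a cycle")
        if roles is not None:
            for u, v in self.directed_edges:
                if roles.get(v) == TRAIT:
                    raise StructureError(f"trait {v!r} has an incoming arc from {u!r}")
            for u, v in self.undirected_edges:
                if TRAIT in (roles.get(u), roles.get(v)):
                    raise StructureError(
                        f"trait appears in undirected edge ({u!r}, {v!r})"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return (
            set(self.nodes) == set(other.nodes)
            and set(self.directed_edges) == set(other.directed_edges)
            and set(self.undirected_edges) == set(other.undirected_edges)
        )

    def __repr__(self) -> str:
        return (
            f"Network({len(self.nodes)} nodes, {len(self.directed_edges)} directed, "
            f"{len(self.undirected_edges)} undirected)"
        )


def load_dataset(
    path: str | Path,
    trait_names: Sequence[str],
    reported_names: Sequence[str] = (),
) -> ExpressionDataset:
    """Read a samples x variables CSV into an :class:`ExpressionDataset`.

    The CSV must have a header row of variable names and a numeric body, one
    row per sample.  ``trait_names`` and ``reported_names`` must match header
    names exactly; every other column is a gene.  If the first column is
    non-numeric it is taken as sample identifiers.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    seen: set[str] = set()
    dupes: list[str] = []
    for h in header:
        if h in seen:
            dupes.append(h)
        seen.add(h)
    if dupes:
        raise UnknownNameError(f"duplicate column names in header: {dupes}")
    try:
        raw = pd.read_csv(path, header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataFormatError(f"cannot parse {path}: {exc}") from exc

    columns = [str(c) for c in raw.columns]
    sample_ids: list[str]
    first = raw.iloc[:, 0] if raw.shape[1] else pd.Series(dtype=str)
    first_numeric = pd.to_numeric(first, errors="coerce")
    if raw.shape[1] and first_numeric.isna().any() and columns[0] not in trait_names:
        sample_ids = first.astype(str).tolist()
        raw = raw.iloc[:, 1:]
        columns = columns[1:]
    else:
        sample_ids = [str(i) for i in range(raw.shape[0])]

    for req, label in ((trait_names, "trait"), (reported_names, "reported gene")):
        missing = [n for n in req if n not in columns]
        if missing:
            raise UnknownNameError(f"{label} names not in header: {missing}")
    if len(set(trait_names)) != len(trait_names):
        raise UnknownNameError("duplicate trait names")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataFormatError(
            f"non-numeric or missing cell at row {r + 1}, column {columns[c]!r}"
        )
    if raw.shape[0] < 3:
        raise SizeError(f"need at least 3 sample rows, got {raw.shape[0]}")

    roles = {c: (TRAIT if c in set(trait_names) else GENE) for c in columns}
    return ExpressionDataset(
        sample_ids=sample_ids,
        variable_names=columns,
        roles=roles,
        reported=set(reported_names),
        values=numeric.to_numpy(dtype=float),
    )


def write_network(net: Network, path: str | Path) -> None:
    """Write a deterministic TSV edge list: source, target, type, stage, score.

    Directed edges first, then undirected; lexicographic within each class.
    Round-trips through :func:`read_network`.
    """
    rows = []
    for u, v in sorted(net.directed_edges):
        p = net.provenance[(u, v)]
        rows.append((u, v, "directed", p.stage, p.score))
    for u, v in sorted(net.undirected_edges):
        p = net.provenance[(u, v)]
        rows.append((u, v, "undirected", p.stage, p.score))
    df = pd.DataFrame(rows, columns=_EDGE_LIST_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_network(path: str | Path, nodes: Iterable[str] | None = None) -> Network:
    """Read an edge list written by :func:`write_network`.

    ``nodes`` optionally supplies the full node universe (isolated nodes are
    not stored in the file).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype={"source": str, "target": str})
    except Exception as exc:
        raise DataFormatError(f"cannot parse edge list {path}: {exc}") from exc
    if list(df.columns) != _EDGE_LIST_COLUMNS:
        raise DataFormatError(
            f"{path}: expected columns {_EDGE_LIST_COLUMNS}, got {list(df.columns)}"
        )
    edge_nodes: list[str] = []
    for name in itertools.chain(df["source"], df["target"]):
        if name not in edge_nodes:
            edge_nodes.append(name)
    all_nodes = list(nodes) if nodes is not None else edge_nodes
    missing = [n for n in edge_nodes if n not in set(all_nodes)]
    if missing:
        raise UnknownNameError(f"{path}: edge nodes not in node list: {missing}")
    net = Network(all_nodes)
    for i, row in df.iterrows():
        kind = row["type"]
        score = float(row["score"])
        if kind == "directed":
            net.add_directed(row["source"], row["target"], row["stage"], score)
        elif kind == "undirected":
            net.add_undirected(row["source"], row["target"], row["stage"], score)
        else:
            raise DataFormatError(f"{path} line {i + 2}: unknown edge type {kind!r}")
    return net


@dataclass
class CPTable:
    """Discrete conditional probability table for one node.

    ``table`` maps each observed joint parent code combination (a tuple, empty
    for root nodes) to a probability vector over the child's ``arity`` codes.
    Combinations never observed fall back to the uniform distribution.
    """

    child: str
    parents: list[str]
    arity: int
    table: dict[tuple[int, ...], np.ndarray] = field(default_factory=dict)

    def probs(self, parent_codes: tuple[int, ...]) -> np.ndarray:
        vec = self.table.get(tuple(parent_codes))
        if vec is None:
            return np.full(self.arity, 1.0 / self.arity)
        return vec

    def validate(self) -> None:
        for cfg, vec in self.table.items():
            if len(cfg) != len(self.parents):
                raise SizeError(f"config {cfg} does not match parents {self.parents}")
            if np.any(vec < 0) or abs(float(vec.sum()) - 1.0) > 1e-9:
                raise DataFormatError(
                    f"CPT row for {self.child!r} given {cfg} is not a distribution"
                )


def estimate_cpts(net: Network, data) -> list[CPTable]:
    """Estimate one CPT per node by Laplace (add-1) smoothed relative frequency.

    Parents are the directed in-neighbours only; undirected gene-gene edges
    contribute no parents.  ``data`` is a
    :class:`~tpdanet.discretize.DiscretizedDataset`.
    """
    name_set = set(data.variable_names)
    missing = [n for n in net.nodes if n not in name_set]
    if missing:
        raise UnknownNameError(f"network nodes absent from data: {missing}")
    arity = data.n_value
    cpts = []
    for node in net.nodes:
        parents = [u for u, v in net.directed_edges if v == node]
        child_codes = data.codes[:, data.index(node)]
        parent_cols = [data.codes[:, data.index(p)] for p in parents]
        counts: dict[tuple[int, ...], np.ndarray] = {}
        for i in range(data.codes.shape[0]):
            cfg = tuple(int(col[i]) for col in parent_cols)
            row = counts.setdefault(cfg, np.zeros(arity))
            row[int(child_codes[i])] += 1
        table = {
            cfg: (row + 1.0) / (row.sum() + arity) for cfg, row in counts.items()
        }
        cpts.append(CPTable(child=node, parents=parents, arity=arity, table=table))
    return cpts


def joint_probability(
    net: Network, cpts: Sequence[CPTable], assignment: Mapping[str, int]
) -> float:
    """Joint probability of a full assignment: product of P(x_i | pa(x_i))."""
    missing = [n for n in net.nodes if n not in assignment]
    if missing:
        raise UnknownNameError(f"assignment missing nodes: {missing}")
    by_child = {c.child: c for c in cpts}
    missing_cpt = [n for n in net.nodes if n not in by_child]
    if missing_cpt:
        raise UnknownNameError(f"no CPT for nodes: {missing_cpt}")
    p = 1.0
    for node in net.nodes:
        cpt = by_child[node]
        cfg = tuple(int(assignment[par]) for par in cpt.parents)
        p *= float(cpt.probs(cfg)[int(assignment[node])])
    return p
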