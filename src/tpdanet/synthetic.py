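"""Linear-Gaussian network simulator and maize-like fixture generator.

Every node is a linear function of its parents plus independent Gaussian
noise, so the population covariance is available in closed form and sampled
datasets converge to it.  :func:`generate_maize_like` emulates the layout of
a maize carotenoid study panel: a handful of trait root nodes, a few
strongly trait-linked "reported" genes, and many background genes that are
mostly pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .core_io import GENE, TRAIT, ExpressionDataset
from .errors import ParameterError, SizeError, StructureError


@dataclass
class SyntheticSpec:
    """A linear-Gaussian structural model: DAG + edge coefficients + noise scales."""

    dag: nx.DiGraph
    coefficients: dict[tuple[str, str], float]
    noise_sd: dict[str, float]
    n_samples: int = 500
    seed: int = 0
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise StructureError("dag contains a cycle")
        for e in self.dag.edges:
            if e not in self.coefficients:
                raise ParameterError(f"edge {e} has no coefficient")
        for node in self.dag.nodes:
            sd = self.noise_sd.get(node)
            if sd is None or sd <= 0:
                raise ParameterError(f"node {node!r} needs noise_sd > 0")
        if self.n_samples < 3:
            raise SizeError("n_samples must be at least 3")

    @property
    def node_order(self) -> list[str]:
        return sorted(self.dag.nodes)

    def role_of(self, node: str) -> str:
        return self.roles.get(node, GENE)


def make_spec(
    edges: Iterable[tuple[str, str, float]],
    noise_sd: Mapping[str, float] | float = 1.0,
    n_samples: int = 500,
    seed: int = 0,
    extra_nodes: Iterable[str] = (),
    roles: Mapping[str, str] | None = None,
) -> SyntheticSpec:
    """Convenience constructor from (parent, child, coefficient) triples."""
    dag = nx.DiGraph()
    coeffs = {}
    for u, v, w in edges:
        dag.add_edge(u, v)
        coeffs[(u, v)] = float(w)
    dag.add_nodes_from(extra_nodes)
    if isinstance(noise_sd, Mapping):
        sds = dict(noise_sd)
    else:
        sds = {n: float(noise_sd) for n in dag.nodes}
    return SyntheticSpec(
        dag=dag,
        coefficients=coeffs,
        noise_sd=sds,
        n_samples=n_samples,
        seed=seed,
        roles=dict(roles or {}),
    )


def analytic_covariance(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    """Population covariance implied by the coefficients and noise scales.

    With x = A x + e (A[child, parent] = coefficient) the covariance is
    (I - A)^{-1} D (I - A)^{-T}, D = diag(noise variances).
    """
    names = spec.node_order
    idx = {n: i for i, n in enumerate(names)}
    k = len(names)
    a = np.zeros((k, k))
    for (u, v), w in spec.coefficients.items():
        a[idx[v], idx[u]] = w
    d = np.diag([spec.noise_sd[n] ** 2 for n in names])
    inv = np.linalg.inv(np.eye(k) - a)
    return names, inv @ d @ inv.T


def _to_dataset(
    names: list[str],
    values: np.ndarray,
    roles: Mapping[str, str],
    reported: Iterable[str] = (),
) -> ExpressionDataset:
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        variable_names=list(names),
        roles={n: roles.get(n, GENE) for n in names},
        reported=set(reported),
        values=values,
    )


def sample_linear_gaussian(spec: SyntheticSpec) -> ExpressionDataset:
    """Draw ``spec.n_samples`` rows in topological order; reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    names = spec.node_order
    idx = {n: i for i, n in enumerate(names)}
    values = np.zeros((spec.n_samples, len(names)))
    for node in nx.topological_sort(spec.dag):
        col = rng.normal(0.0, spec.noise_sd[node], size=spec.n_samples)
        for parent in spec.dag.predecessors(node):
            col = col + spec.coefficients[(parent, node)] * values[:, idx[parent]]
        values[:, idx[node]] = col
    return _to_dataset(names, values, spec.roles)


def dataset_from_covariance(
    names: list[str],
    cov: np.ndarray,
    n_samples: int,
    seed: int = 0,
    roles: Mapping[str, str] | None = None,
    reported: Iterable[str] = (),
) -> ExpressionDataset:
    """A dataset whose *sample* covariance equals ``cov`` exactly.

    Random draws are centred and whitened empirically, then coloured with the
    Cholesky factor of the target, so the unbiased sample covariance matches
    the target to machine precision.  Requires n_samples > len(names).
    """
    cov = np.asarray(cov, dtype=float)
    k = len(names)
    if cov.shape != (k, k):
        raise SizeError(f"covariance shape {cov.shape} for {k} names")
    if n_samples <= k:
        raise SizeError("need n_samples > number of variables for exact whitening")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, k))
    z -= z.mean(axis=0)
    s = np.cov(z, rowvar=False, ddof=1)
    z = z @ np.linalg.inv(np.linalg.cholesky(s).T)
    values = z @ np.linalg.cholesky(cov).T
    return _to_dataset(names, values, dict(roles or {}), reported)


#: default trait names mirroring the five carotenoid components
DEFAULT_TRAITS = ("AC", "BC", "LUT", "ZEA", "Bcry")


def generate_maize_like(
    n_lines: int = 527,
    n_background: int = 100,
    n_reported: int = 4,
    n_traits: int = 5,
    effect: float = 0.5,
    seed: int = 0,
    weak_fraction: float = 0.05,
) -> tuple[ExpressionDataset, set[tuple[str, str]]]:
    """Maize-like panel: trait roots, trait-linked reported genes, noisy background.

    Each reported gene is a child of one trait with population correlation
    ``effect``; a ``weak_fraction`` of background genes is weakly trait-linked
    at half that effect (real panels contain undocumented true signal), the
    rest are independent noise.  Returns the dataset and the ground-truth
    (trait, gene) edge set for scoring.
    """
    if min(n_lines, n_background, n_reported, n_traits) < 1:
        raise ParameterError("all counts must be >= 1")
    if not 0 < effect < 1:
        raise ParameterError(f"effect must be in (0, 1), got {effect}")
    if not 0 <= weak_fraction <= 1:
        raise ParameterError(f"weak_fraction must be in [0, 1], got {weak_fraction}")

    traits = [DEFAULT_TRAITS[i] if i < len(DEFAULT_TRAITS) else f"T{i + 1}" for i in range(n_traits)]
    reported = [f"RG{i + 1}" for i in range(n_reported)]
    width = len(str(n_background))
    background = [f"BG{i + 1:0{width}d}" for i in range(n_background)]

    rng = np.random.default_rng(seed)
    n_weak = int(round(weak_fraction * n_background))
    weak = list(rng.choice(n_background, size=n_weak, replace=False)) if n_weak else []

    edges: list[tuple[str, str, float]] = []
    truth: set[tuple[str, str]] = set()
    # corr(t, g) = b / sqrt(b^2 + s^2); with s^2 = 1 - b^2 the child has unit
    # variance and the correlation equals b exactly
    noise: dict[str, float] = {t: 1.0 for t in traits}
    for i, g in enumerate(reported):
        t = traits[i % n_traits]
        edges.append((t, g, effect))
        noise[g] = float(np.sqrt(1.0 - effect**2))
        truth.add((t, g))
    weak_effect = effect / 2.0
    for i, g in enumerate(background):
        if i in weak:
            t = traits[int(rng.integers(n_traits))]
            edges.append((t, g, weak_effect))
            noise[g] = float(np.sqrt(1.0 - weak_effect**2))
            truth.add((t, g))
        else:
            noise[g] = 1.0

    roles = {t: TRAIT for t in traits}
    spec = make_spec(
        edges,
        noise_sd=noise,
        n_samples=n_lines,
        seed=int(rng.integers(2**31 - 1)),
        extra_nodes=traits + reported + background,
        roles=roles,
    )
    ds = sample_linear_gaussian(spec)
    ds.reported = set(reported)
    return ds, truth


def small_dag_catalogue(n_samples: int = 200) -> list[SyntheticSpec]:
    """Fixed catalogue of 20 small (<= 5 node) linear-Gaussian benchmark models.

    Coefficients are chosen so every edge carries population correlation of
    magnitude at least 0.3; used by the exact-covariance skeleton-recovery
    checks.
    """
    b = 0.8  # strong enough that even collider-diluted edges stay above |r| = 0.3
    specs: list[tuple[str, list[tuple[str, str, float]], list[str]]] = [
        ("single-edge", [("a", "b", b)], []),
        ("chain-3", [("a", "b", b), ("b", "c", b)], []),
        ("fork-3", [("a", "b", b), ("a", "c", b)], []),
        ("collider-3", [("a", "c", b), ("b", "c", b)], []),
        ("chain-4", [("a", "b", b), ("b", "c", b), ("c", "d", b)], []),
        ("star-4", [("a", "b", b), ("a", "c", b), ("a", "d", b)], []),
        ("diamond", [("a", "b", b), ("a", "c", b), ("b", "d", b), ("c", "d", b)], []),
        ("collider-4", [("a", "d", b), ("b", "d", b), ("c", "d", b)], []),
        ("chain-5", [("a", "b", b), ("b", "c", b), ("c", "d", b), ("d", "e", b)], []),
        ("tree-5", [("a", "b", b), ("a", "c", b), ("b", "d", b), ("b", "e", b)], []),
        ("fork-collider", [("a", "b", b), ("a", "c", b), ("b", "d", b), ("c", "d", b), ("a", "e", b)], []),
        ("m-structure", [("a", "c", b), ("b", "c", b), ("b", "e", b), ("d", "e", b)], []),
        ("two-components", [("a", "b", b), ("c", "d", b)], ["e"]),
        ("isolated-node", [("a", "b", b), ("b", "c", b)], ["d"]),
        ("chain-neg", [("a", "b", -b), ("b", "c", b)], []),
        ("fork-neg", [("a", "b", -b), ("a", "c", -b)], []),
        ("wide-collider-chain", [("a", "c", b), ("b", "c", b), ("c", "d", b)], []),
        ("double-fork", [("a", "b", b), ("a", "c", b), ("d", "e", b)], []),
        ("chain-4-neg", [("a", "b", b), ("b", "c", -b), ("c", "d", b)], []),
        ("y-structure", [("a", "c", b), ("b", "c", b), ("c", "e", b), ("c", "d", b)], []),
    ]
    out = []
    for i, (_name, edges, extra) in enumerate(specs):
        out.append(make_spec(edges, noise_sd=1.0, n_samples=n_samples, seed=100 + i, extra_nodes=extra))
    return out
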