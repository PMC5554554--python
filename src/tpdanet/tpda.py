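"""Three-phase dependency analysis (TPDA) structure learner.

The learner builds a gene-trait network in three stages over a discretized
dataset:

* **Drafting** — rank all variable pairs by Gaussian-entropy mutual
  information; walk the ranking, adding an edge whenever the pair is not yet
  connected by an open path, otherwise deferring the pair (the classic S and
  R edge sets).
* **Thickening** — for each deferred pair, find a small cut set that
  d-separates the pair in the current skeleton; if the conditional mutual
  information given that cut set still exceeds the threshold, the dependence
  is not explained away and the edge is inserted (I-map stage).
* **Thinning** — re-examine every edge that has an alternative open path:
  remove it temporarily, recompute a cut set, and delete it for good if the
  pair is conditionally independent given that cut set (p-map stage).

A final orientation pass applies the trait-as-root constraint: every
trait-gene edge is directed trait -> gene, gene-gene edges stay undirected,
and trait-trait edges are dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .core_io import GENE, TRAIT, ExpressionDataset, Network
from .discretize import DiscretizedDataset, discretize_dataset
from .errors import ParameterError, SizeError, StructureError, UnknownNameError
from .information import cmi_from_covariance

logger = logging.getLogger(__name__)

MI_ON_CODES = "codes"
MI_ON_RAW = "raw"


@dataclass(frozen=True)
class ThresholdTriple:
    """Information thresholds (nats) for the drafting/thickening/thinning stages."""

    draft_eps: float = 0.01
    thicken_eps: float = 0.01
    thin_eps: float = 0.01

    def __post_init__(self) -> None:
        for name in ("draft_eps", "thicken_eps", "thin_eps"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class CandidateList:
    """Ranked MI candidates: ``pairs`` is the paper's set S, ``deferred`` its set R."""

    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    deferred: list[tuple[str, str, float]] = field(default_factory=list)


@dataclass
class CutSet:
    """Node set whose removal d-separates a target pair in the skeleton."""

    nodes: set[str] = field(default_factory=set)


@dataclass
class LearnRecord:
    """Full trace of a learn run: per-stage networks and the candidate lists."""

    candidates: CandidateList
    draft_network: Network
    thicken_network: Network
    thin_network: Network
    network: Network  # after orientation
    stage_log: list[dict] = field(default_factory=list)


def _mi_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise Gaussian-entropy MI for every column pair.

    For 1-D pairs MI = -1/2 ln(1 - r^2), so one correlation matrix gives the
    whole ranking; constant columns carry zero information.
    """
    values = np.asarray(values, dtype=float)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    r = np.atleast_2d(r)
    r2 = np.clip(r * r, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        mi = -0.5 * np.log1p(-r2)
    mi[~np.isfinite(r2)] = 0.0
    mi[sd == 0, :] = 0.0
    mi[:, sd == 0] = 0.0
    np.fill_diagonal(mi, 0.0)
    return mi


def _learning_values(data: DiscretizedDataset, mi_on: str) -> np.ndarray:
    if mi_on == MI_ON_CODES:
        return data.codes.astype(float)
    if mi_on == MI_ON_RAW:
        if data.raw_values is None:
            raise ParameterError("mi_on='raw' requires raw_values on the dataset")
        return data.raw_values
    raise ParameterError(f"mi_on must be 'codes' or 'raw', got {mi_on!r}")


def rank_pairs(
    data: DiscretizedDataset, eps: float, *, mi_on: str = MI_ON_CODES
) -> CandidateList:
    """All unordered pairs with MI > eps, sorted by MI descending.

    Ties are broken lexicographically by (u, v) so the ranking is a total
    order and runs are reproducible.
    """
    if eps <= 0:
        raise ParameterError(f"draft threshold must be positive, got {eps}")
    names = data.variable_names
    if len(names) < 2:
        raise SizeError("need at least 2 variables to rank pairs")
    mi = _mi_matrix(_learning_values(data, mi_on))
    entries = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            u, v = sorted((names[i], names[j]))
            if mi[i, j] > eps:
                entries.append((u, v, float(mi[i, j])))
    entries.sort(key=lambda t: (-t[2], t[0], t[1]))
    return CandidateList(pairs=entries)


def open_path_exists(
    net: Network, a: str, b: str, exclude: tuple[str, str] | None = None
) -> bool:
    """True iff a and b are connected in the skeleton, optionally ignoring one edge."""
    if a == b:
        raise ParameterError("endpoints must differ")
    for n in (a, b):
        if n not in set(net.nodes):
            raise UnknownNameError(f"unknown node {n!r}")
    g = net.skeleton()
    if exclude is not None and g.has_edge(*exclude):
        g.remove_edge(*exclude)
    return nx.has_path(g, a, b)


def draft(
    data: DiscretizedDataset,
    eps: float,
    *,
    mi_on: str = MI_ON_CODES,
    candidates: CandidateList | None = None,
) -> tuple[Network, CandidateList]:
    """Drafting stage: greedy edge insertion with deferral of already-connected pairs."""
    if candidates is None:
        candidates = rank_pairs(data, eps, mi_on=mi_on)
    net = Network(data.variable_names)
    g = nx.Graph()
    g.add_nodes_from(data.variable_names)
    deferred: list[tuple[str, str, float]] = []
    for u, v, mi in candidates.pairs:
        if nx.has_path(g, u, v):
            deferred.append((u, v, mi))
        else:
            net.add_undirected(u, v, stage="draft", score=mi)
            g.add_edge(u, v)
    candidates.deferred = deferred
    return net, candidates


def find_cut_set(net: Network, a: str, b: str) -> CutSet:
    """Heuristic minimum cut set d-separating a and b in the skeleton.

    Take the neighbours of a that lie on at least one simple path to b, the
    analogous set for b, and return the smaller (ties favour a's side).
    Removing the returned nodes disconnects a from b.
    """
    g = net.skeleton()
    if g.has_edge(a, b):
        raise StructureError(
            f"{a!r} and {b!r} are adjacent; remove the edge before cutting"
        )
    if not nx.has_path(g, a, b):
        raise StructureError(f"no open path between {a!r} and {b!r}")

    def side(src: str, dst: str) -> set[str]:
        reduced = g.copy()
        reduced.remove_node(src)
        out = set()
        for nbr in g[src]:
            if nbr == dst or nx.has_path(reduced, nbr, dst):
                out.add(nbr)
        return out

    n_a = side(a, b)
    n_b = side(b, a)
    return CutSet(nodes=n_a if len(n_a) <= len(n_b) else n_b)


def _cmi(
    values: np.ndarray,
    index: Mapping[str, int],
    u: str,
    v: str,
    cut: Sequence[str],
) -> float:
    cols = [u, v, *cut]
    sub = values[:, [index[c] for c in cols]]
    cov = np.cov(sub, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    return cmi_from_covariance(cov, 0, 1, list(range(2, len(cols))))


def _refined_cmi(
    values: np.ndarray,
    index: Mapping[str, int],
    u: str,
    v: str,
    cut: CutSet,
    eps: float,
) -> tuple[float, list[str]]:
    """Greedy cut-set refinement for the conditional-independence decision.

    Conditioning on every neighbour can open a collider path and inflate the
    CMI, so the full cut set alone over-connects v-structures.  Starting from
    the heuristic cut set, repeatedly drop the member whose removal lowers
    the CMI the most, stopping when no removal helps (or the value already
    sits at or below the threshold).  Returns the smallest CMI found and the
    conditioning set that achieved it.
    """
    current = sorted(cut.nodes)
    best = _cmi(values, index, u, v, current)
    while len(current) > 1 and best > eps:
        trials = [
            (_cmi(values, index, u, v, reduced), reduced)
            for reduced in ([c for c in current if c != drop] for drop in current)
        ]
        cand_cmi, cand_cut = min(trials, key=lambda t: t[0])
        if cand_cmi < best:
            best, current = cand_cmi, cand_cut
        else:
            break
    return best, current


def thicken(
    net: Network,
    deferred: CandidateList | Sequence[tuple[str, str, float]],
    data: DiscretizedDataset,
    eps: float,
    *,
    mi_on: str = MI_ON_CODES,
    stage_log: list[dict] | None = None,
) -> Network:
    """Thickening stage: insert deferred edges whose dependence survives conditioning."""
    if eps <= 0:
        raise ParameterError(f"thicken threshold must be positive, got {eps}")
    pairs = deferred.deferred if isinstance(deferred, CandidateList) else list(deferred)
    values = _learning_values(data, mi_on)
    index = {n: i for i, n in enumerate(data.variable_names)}
    net = net.copy()
    for u, v, _mi in pairs:
        cut = find_cut_set(net, u, v)
        cmi, used = _refined_cmi(values, index, u, v, cut, eps)
        dependent = cmi > eps
        if dependent:
            net.add_undirected(u, v, stage="thicken", score=cmi)
        if stage_log is not None:
            stage_log.append(
                {
                    "stage": "thicken",
                    "pair": [u, v],
                    "cutset": used,
                    "statistic": cmi,
                    "threshold": eps,
                    "action": "insert" if dependent else "keep-out",
                }
            )
        logger.debug(
            "thicken (%s,%s) | %s: CMI=%.5f eps=%.5f -> %s",
            u, v, used, cmi, eps,
            "dependent" if dependent else "independent",
        )
    return net


def thin(
    net: Network,
    data: DiscretizedDataset,
    eps: float,
    *,
    mi_on: str = MI_ON_CODES,
    stage_log: list[dict] | None = None,
) -> Network:
    """Thinning stage: delete edges whose endpoints are conditionally independent.

    Each edge with an alternative open path is removed temporarily, a cut set
    is computed on the reduced skeleton, and the edge is deleted permanently
    iff CMI <= eps; otherwise it is restored with its original provenance.
    """
    if eps <= 0:
        raise ParameterError(f"thin threshold must be positive, got {eps}")
    values = _learning_values(data, mi_on)
    index = {n: i for i, n in enumerate(data.variable_names)}
    net = net.copy()
    for u, v in list(net.undirected_edges):  # snapshot in insertion order
        if not open_path_exists(net, u, v, exclude=(u, v)):
            continue
        prov = net.remove_undirected(u, v)
        cut = find_cut_set(net, u, v)
        cmi, used = _refined_cmi(values, index, u, v, cut, eps)
        independent = cmi <= eps
        if not independent:
            net.add_undirected(u, v, stage=prov.stage, score=prov.score)
        if stage_log is not None:
            stage_log.append(
                {
                    "stage": "thin",
                    "pair": [u, v],
                    "cutset": used,
                    "statistic": cmi,
                    "threshold": eps,
                    "action": "delete" if independent else "restore",
                }
            )
        logger.debug(
            "thin (%s,%s) | %s: CMI=%.5f eps=%.5f -> %s",
            u, v, used, cmi, eps,
            "delete" if independent else "restore",
        )
    return net


def orient(net: Network, roles: Mapping[str, str]) -> Network:
    """Apply the trait-as-root constraint to a learned skeleton.

    Trait-gene edges become directed trait -> gene; gene-gene edges stay
    undirected; trait-trait edges violate the root constraint in one
    direction and are dropped with a warning.
    """
    out = Network(net.nodes)
    for u, v in net.undirected_edges:
        prov = net.provenance[(u, v)]
        ru, rv = roles.get(u, GENE), roles.get(v, GENE)
        if ru == TRAIT and rv == TRAIT:
            logger.warning("dropping trait-trait edge (%s, %s): traits are roots", u, v)
            continue
        if ru == TRAIT:
            out.add_directed(u, v, prov.stage, prov.score)
        elif rv == TRAIT:
            out.add_directed(v, u, prov.stage, prov.score)
        else:
            out.add_undirected(u, v, prov.stage, prov.score)
    for u, v in net.directed_edges:  # already-oriented input edges pass through
        prov = net.provenance[(u, v)]
        out.add_directed(u, v, prov.stage, prov.score)
    return out


def learn_stages(
    ds: ExpressionDataset | DiscretizedDataset,
    method: str = "quantile",
    n: int = 5,
    thresholds: ThresholdTriple = ThresholdTriple(),
    *,
    mi_on: str = MI_ON_CODES,
) -> LearnRecord:
    """Run the full pipeline and keep every intermediate stage.

    ``ds`` may be a continuous dataset (discretized here with ``method``/``n``)
    or an already-discretized one (``method``/``n`` ignored).
    """
    if isinstance(ds, DiscretizedDataset):
        data = ds
    else:
        data = discretize_dataset(ds, method=method, n=n)
    stage_log: list[dict] = []
    net0, cands = draft(data, thresholds.draft_eps, mi_on=mi_on)
    logger.info(
        "draft: %d candidate pairs, %d edges, %d deferred",
        len(cands.pairs), len(net0.undirected_edges), len(cands.deferred),
    )
    net1 = thicken(net0, cands, data, thresholds.thicken_eps, mi_on=mi_on, stage_log=stage_log)
    logger.info("thicken: %d edges", len(net1.undirected_edges))
    net2 = thin(net1, data, thresholds.thin_eps, mi_on=mi_on, stage_log=stage_log)
    logger.info("thin: %d edges", len(net2.undirected_edges))
    final = orient(net2, data.roles)
    final.validate(data.roles)
    return LearnRecord(
        candidates=cands,
        draft_network=net0,
        thicken_network=net1,
        thin_network=net2,
        network=final,
        stage_log=stage_log,
    )


def learn(
    ds: ExpressionDataset | DiscretizedDataset,
    method: str = "quantile",
    n: int = 5,
    thresholds: ThresholdTriple = ThresholdTriple(),
    *,
    mi_on: str = MI_ON_CODES,
) -> Network:
    """Discretize, draft, thicken, thin and orient; deterministic for fixed inputs."""
    return learn_stages(ds, method, n, thresholds, mi_on=mi_on).network
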