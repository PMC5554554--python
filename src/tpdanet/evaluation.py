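"""Learning-effect metrics: trait-gene edge counts (A/B), ratios, and
structure-recovery scores against a known truth.

A counts the edges linking literature-reported genes to traits, B the edges
linking any other gene to traits; both are direction-blind.  The ratios
A / #reported and B / #other summarize how strongly a learner concentrates
trait edges on the genes with prior support.  For synthetic data with a
known generating network the module also computes skeleton precision,
recall and structural Hamming distance.

External learners are compared by reading their edge lists from files in
the :func:`~tpdanet.core_io.write_network` format.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_io import Network, read_network
from .errors import ParameterError, UnknownNameError


@dataclass
class EvaluationResult:
    """A/B counts and ratios, plus optional recovery metrics vs a known truth."""

    A: int
    B: int
    ratio_reported: float
    ratio_other: float
    shd: int | None = None
    precision: float | None = None
    recall: float | None = None


def _canon(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


def count_trait_gene_edges(
    net: Network, reported: Iterable[str], traits: Iterable[str]
) -> tuple[int, int]:
    """Count trait-gene edges by gene class, in either orientation or undirected.

    Returns (A, B): A for reported genes, B for all other genes.  Gene-gene
    and trait-trait edges are ignored.
    """
    reported = set(reported)
    traits = set(traits)
    nodes = set(net.nodes)
    unknown = (reported | traits) - nodes
    if unknown:
        raise UnknownNameError(f"names not in network: {sorted(unknown)}")
    a = b = 0
    for u, v in net.skeleton_edges():
        if u in traits and v in traits:
            continue
        if u in traits:
            gene = v
        elif v in traits:
            gene = u
        else:
            continue
        if gene in reported:
            a += 1
        else:
            b += 1
    return a, b


def ratios(a: int, b: int, n_reported: int, n_other: int) -> tuple[float, float]:
    """Exact (unrounded) A / #reported and B / #other ratios."""
    if n_reported < 1 or n_other < 1:
        raise ParameterError("denominators must be >= 1")
    return a / n_reported, b / n_other


def structural_metrics(
    learned: Network, truth: Iterable[tuple[str, str]]
) -> tuple[int, float, float]:
    """Skeleton SHD, precision and recall against a true edge set.

    All quantities are direction-blind.  Precision with zero learned edges is
    defined as 1 (nothing asserted, nothing wrong).
    """
    truth_set = {_canon(u, v) for u, v in truth}
    nodes = set(learned.nodes)
    stray = {n for e in truth_set for n in e} - nodes
    if stray:
        raise UnknownNameError(f"truth nodes not in network: {sorted(stray)}")
    learned_set = learned.skeleton_edges()
    tp = len(learned_set & truth_set)
    shd = len(learned_set ^ truth_set)
    precision = tp / len(learned_set) if learned_set else 1.0
    recall = tp / len(truth_set) if truth_set else 1.0
    return shd, precision, recall


def evaluate_network(
    net: Network,
    reported: Iterable[str],
    traits: Iterable[str],
    truth: Iterable[tuple[str, str]] | None = None,
) -> EvaluationResult:
    """Full evaluation of one network: A/B, ratios, and truth metrics if given."""
    reported = set(reported)
    traits = set(traits)
    a, b = count_trait_gene_edges(net, reported, traits)
    n_other = len([n for n in net.nodes if n not in traits and n not in reported])
    rr, ro = ratios(a, b, max(len(reported), 1), max(n_other, 1))
    result = EvaluationResult(A=a, B=b, ratio_reported=rr, ratio_other=ro)
    if truth is not None:
        result.shd, result.precision, result.recall = structural_metrics(net, truth)
    return result


def compare_learners(
    edge_list_files: Sequence[str | Path],
    reported: Iterable[str],
    traits: Iterable[str],
    truth: Iterable[tuple[str, str]] | None = None,
    nodes: Iterable[str] | None = None,
    extra: dict[str, Network] | None = None,
) -> pd.DataFrame:
    """One evaluation row per edge-list file (plus any in-memory networks).

    Row order follows the input order; ``extra`` maps a label (e.g. "TPDA")
    to an already-learned network appended after the files.
    """
    truth_list = list(truth) if truth is not None else None
    node_list = list(nodes) if nodes is not None else None
    rows = []
    entries: list[tuple[str, Network]] = [
        (str(p), read_network(p, nodes=node_list)) for p in edge_list_files
    ]
    entries.extend((extra or {}).items())
    for label, net in entries:
        res = evaluate_network(net, reported, traits, truth_list)
        rows.append(
            {
                "learner": label,
                "A": res.A,
                "B": res.B,
                "ratio_reported": res.ratio_reported,
                "ratio_other": res.ratio_other,
                "shd": res.shd,
                "precision": res.precision,
                "recall": res.recall,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "learner", "A", "B", "ratio_reported", "ratio_other",
            "shd", "precision", "recall",
        ],
    )
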