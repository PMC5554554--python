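"""Equal-width (Interval) and equal-frequency (Quantile) N-value discretization.

Both methods code a continuous column into integer levels 0..N-1.  Interval
splits [min, max] into N equal-width half-open bins (the last bin closed at
the max); Quantile cuts at the linear-interpolation empirical quantiles
q_{k/N}, assigning values equal to a cut point to the lower bin so that ties
always share a code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import ExpressionDataset
from .errors import ParameterError

INTERVAL = "interval"
QUANTILE = "quantile"
METHODS = (INTERVAL, QUANTILE)


@dataclass
class DiscretizedDataset:
    """Integer-coded copy of a dataset plus bin-edge bookkeeping.

    ``codes`` entries lie in [0, n_value - 1]; ``bin_edges`` records the
    ordered interior cut points used per variable.  Identifiers and roles are
    carried over from the source dataset unchanged, and the raw values are
    kept for estimators that want to see the continuous data.
    """

    sample_ids: list[str]
    variable_names: list[str]
    roles: dict[str, str]
    reported: set[str]
    codes: np.ndarray
    bin_edges: dict[str, np.ndarray]
    method: str
    n_value: int
    raw_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) > self.n_value - 1:
            raise ParameterError("codes outside [0, n_value - 1]")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def genes(self) -> list[str]:
        return [v for v in self.variable_names if self.roles[v] == "gene"]

    @property
    def traits(self) -> list[str]:
        return [v for v in self.variable_names if self.roles[v] == "trait"]

    def index(self, name: str) -> int:
        from .errors import UnknownNameError

        try:
            return self.variable_names.index(name)
        except ValueError:
            raise UnknownNameError(f"unknown variable {name!r}") from None

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self.index(name)]


def _check_n(n: int) -> None:
    if int(n) != n or n < 1:
        raise ParameterError(f"bin count must be an integer >= 1, got {n!r}")


def discretize_interval(x: np.ndarray, n: int) -> np.ndarray:
    """Equal-width codes over [min(x), max(x)].

    code(v) = floor((v - min) / w) with w = (max - min)/n, clamped so the
    maximum maps to n - 1.  A constant vector codes to all zeros.
    """
    _check_n(n)
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros(x.shape[0], dtype=int)
    w = (hi - lo) / n
    codes = np.floor((x - lo) / w).astype(int)
    return np.clip(codes, 0, n - 1)


def interval_edges(x: np.ndarray, n: int) -> np.ndarray:
    """Interior cut points of the equal-width binning (n - 1 values)."""
    _check_n(n)
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros(0)
    return lo + (hi - lo) / n * np.arange(1, n)


def quantile_edges(x: np.ndarray, n: int) -> np.ndarray:
    """Interior cut points at the empirical quantiles k/n, k = 1..n-1."""
    _check_n(n)
    x = np.asarray(x, dtype=float)
    if n == 1:
        return np.zeros(0)
    return np.quantile(x, np.arange(1, n) / n)  # linear interpolation


def discretize_quantile(x: np.ndarray, n: int) -> np.ndarray:
    """Equal-frequency codes: count of cut points strictly below each value.

    Values equal to a cut point go to the lower bin, so tied values always
    receive identical codes.
    """
    x = np.asarray(x, dtype=float)
    cuts = quantile_edges(x, n)
    return np.searchsorted(cuts, x, side="left").astype(int)


def discretize_dataset(
    ds: ExpressionDataset, method: str = QUANTILE, n: int = 5
) -> DiscretizedDataset:
    """Apply one discretizer column-wise to every variable, genes and traits alike."""
    if method not in METHODS:
        raise ParameterError(f"method must be one of {METHODS}, got {method!r}")
    if int(n) != n or n < 2:
        raise ParameterError(f"dataset discretization needs n >= 2, got {n!r}")
    codes = np.empty_like(ds.values, dtype=int)
    edges: dict[str, np.ndarray] = {}
    for j, name in enumerate(ds.variable_names):
        col = ds.values[:, j]
        if method == INTERVAL:
            codes[:, j] = discretize_interval(col, n)
            edges[name] = interval_edges(col, n)
        else:
            codes[:, j] = discretize_quantile(col, n)
            edges[name] = quantile_edges(col, n)
    return DiscretizedDataset(
        sample_ids=list(ds.sample_ids),
        variable_names=list(ds.variable_names),
        roles=dict(ds.roles),
        reported=set(ds.reported),
        codes=codes,
        bin_edges=edges,
        method=method,
        n_value=int(n),
        raw_values=ds.values.copy(),
    )
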