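"""In-memory containers for scans, connectivity matrices and edge series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognized connectivity measures: static FC as Pearson r (``sfc_r``) or
#: Fisher z (``sfc_z``), dynamic FC as the variance of the DCC correlation
#: series (``dfc_var``), entropic FC as its histogram differential entropy in
#: nats (``efc_H``).
MEASURES = ("sfc_r", "sfc_z", "dfc_var", "efc_H")


@dataclass
class ScanTimeseries:
    """One scan's T x N region timeseries.

    ``meta`` carries at least participant, drug and half for scans that belong
    to a study design cell.
    """

    data: np.ndarray
    node_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("scan data must be a T x N matrix")
        if self.data.shape[1] != len(self.node_ids):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.node_ids)} node ids"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scan data contains missing or non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """N x N symmetric matrix of one connectivity measure for one scan.

    The diagonal is 1 for ``sfc_r`` and NaN (undefined) for every other
    measure. Flagged (unestimable) edges are NaN.
    """

    values: np.ndarray
    measure: str
    node_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}; expected one of {MEASURES}")
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n} x {n}")
        off = ~np.eye(n, dtype=bool)
        vals = self.values[off]
        ok = np.isfinite(vals)
        if not np.allclose(self.values[off], self.values.T[off], equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        if self.measure == "sfc_r" and np.any(np.abs(vals[ok]) > 1 + 1e-12):
            raise ValueError("sfc_r entries must lie in [-1, 1]")
        if self.measure == "dfc_var" and np.any(vals[ok] < 0):
            raise ValueError("dfc_var entries must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def upper_values(self) -> np.ndarray:
        """Row-major upper-triangle (i < j) vectorization — the edge order
        shared by feature matrices and long-format tables."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        return self.values[iu, ju]

    def n_flagged(self) -> int:
        return int(np.isnan(self.upper_values()).sum())


@dataclass
class EdgeCorrelationSeries:
    """Time-resolved conditional correlation for one edge.

    ``params`` holds the fitted DCC parameters ``(a, b)`` and per-node
    GARCH(1,1) parameters ``(omega, alpha, beta)``. ``flagged`` is True when
    quasi-maximum-likelihood estimation failed and the series comes from the
    exponentially-weighted-moving-correlation fallback.
    """

    series: np.ndarray
    edge: tuple[str, str]
    params: dict = field(default_factory=dict)
    flagged: bool = False

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 1:
            raise ValueError("correlation series must be one-dimensional")
        if np.any(np.abs(self.series) >= 1):
            raise ValueError("conditional correlations must lie strictly in (-1, 1)")
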