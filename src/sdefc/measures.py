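"""Per-scan connectivity measures: static, dynamic and entropic FC.

Static FC is the Pearson correlation between two regions' timeseries,
analyzed on the Fisher-z scale. Dynamic FC is the variance over time of an
edge's DCC conditional-correlation series; entropic FC is the histogram
approximation to that series' differential entropy,

    H(X) = - sum_i f(x_i) * ln( f(x_i) / w(x_i) )

with f the empirical bin proportions and w the bin width, so that for
uniform-width bins H equals the Shannon entropy of the proportions plus
ln(w). Entropy is reported in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ConnectivityMatrix, EdgeCorrelationSeries, ScanTimeseries
from .dcc import dcc_all_edges

#: Default histogram sweep for entropic FC (results reported at 60 bins).
DEFAULT_BIN_SWEEP = (15, 30, 45, 60, 75, 90, 105, 120)


class DegenerateSeriesError(ValueError):
    """Raised when an entropy histogram cannot be formed (zero-width range)."""


def split_halves(scan: ScanTimeseries) -> tuple[ScanTimeseries, ScanTimeseries]:
    """Split a scan into first/second temporal halves.

    First half = rows 0..floor(T/2), second = the rest, so concatenating the
    halves restores the original scan. Requires T >= 60 so each half supports
    DCC estimation.
    """
    T = scan.n_timepoints
    if T < 60:
        raise ValueError(f"scan too short to split (T={T} < 60)")
    mid = T // 2
    mk = lambda d, half: ScanTimeseries(
        data=d, node_ids=list(scan.node_ids), meta={**scan.meta, "half": half}
    )
    return mk(scan.data[:mid], "first"), mk(scan.data[mid:], "second")


def static_fc(scan: ScanTimeseries) -> ConnectivityMatrix:
    """Pearson correlation between all node pairs (measure ``sfc_r``)."""
    data = scan.data
    if data.shape[0] < 3:
        raise ValueError("static FC requires at least 3 timepoints")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = [scan.node_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant timeseries for node(s) {bad}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, measure="sfc_r", node_ids=list(scan.node_ids),
                              meta=dict(scan.meta))


def fisher_z(r):
    """Fisher z-transform, z = arctanh(r); strictly increasing and odd.

    Accepts scalars or arrays with every entry strictly inside (-1, 1).
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def to_fisher_z(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """``sfc_r`` matrix -> ``sfc_z`` matrix (diagonal becomes NaN)."""
    if cm.measure != "sfc_r":
        raise ValueError(f"expected an sfc_r matrix, got {cm.measure}")
    vals = cm.values.copy()
    np.fill_diagonal(vals, 0.0)
    if np.any(np.abs(vals) >= 1.0):
        raise ValueError("off-diagonal |r| = 1: Fisher z undefined")
    z = np.arctanh(vals)
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(values=z, measure="sfc_z", node_ids=list(cm.node_ids),
                              meta=dict(cm.meta))


@dataclass(frozen=True)
class EntropyConfig:
    """Histogram settings for entropic FC.

    ``bin_range='data'`` spans each series' own min..max; ``'fixed'`` uses
    [-1, 1], the support of a correlation series. Natural logarithm (nats).
    """

    n_bins: int = 60
    bin_range: str = "data"

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if self.bin_range not in ("data", "fixed"):
            raise ValueError("bin_range must be 'data' or 'fixed'")


def entropy_hist(series: np.ndarray, config: EntropyConfig = EntropyConfig()) -> float:
    """Histogram (plug-in) differential entropy of a series, in nats.

    Empty bins contribute 0 (the x*ln(x) -> 0 limit). A constant series with
    data-range binning has no defined bin width and raises
    :class:`DegenerateSeriesError`.
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) == 0:
        raise ValueError("empty series")
    if len(x) < config.n_bins:
        warnings.warn(
            f"series length {len(x)} < n_bins {config.n_bins}; entropy estimate is coarse",
            stacklevel=2,
        )
    if config.bin_range == "fixed":
        lo, hi = -1.0, 1.0
    else:
        lo, hi = float(x.min()), float(x.max())
        if hi - lo <= 0:
            raise DegenerateSeriesError("constant series: zero-width histogram range")
    counts, _ = np.histogram(x, bins=config.n_bins, range=(lo, hi))
    f = counts / counts.sum()
    w = (hi - lo) / config.n_bins
    nz = f > 0
    return float(-np.sum(f[nz] * np.log(f[nz] / w)))


def dynamic_fc(
    series_set: dict[tuple[str, str], EdgeCorrelationSeries],
    node_ids: list[str],
    meta: dict | None = None,
) -> ConnectivityMatrix:
    """Edge-wise sample variance (T-1 denominator) of the correlation
    series (measure ``dfc_var``)."""
    vals = _edge_map(series_set, node_ids, lambda s: float(np.var(s.series, ddof=1)))
    return ConnectivityMatrix(values=vals, measure="dfc_var", node_ids=list(node_ids),
                              meta=dict(meta or {}))


def entropic_fc(
    series_set: dict[tuple[str, str], EdgeCorrelationSeries],
    node_ids: list[str],
    config: EntropyConfig = EntropyConfig(),
    meta: dict | None = None,
) -> ConnectivityMatrix:
    """Edge-wise histogram differential entropy of the correlation series
    (measure ``efc_H``). Degenerate edges propagate as NaN; more than 1%
    flagged edges triggers a warning."""

    def h(s: EdgeCorrelationSeries) -> float:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return entropy_hist(s.series, config)
        except DegenerateSeriesError:
            return np.nan

    vals = _edge_map(series_set, node_ids, h)
    cm = ConnectivityMatrix(values=vals, measure="efc_H", node_ids=list(node_ids),
                            meta=dict(meta or {}))
    n_edges = len(series_set)
    if n_edges and cm.n_flagged() / n_edges > 0.01:
        warnings.warn(
            f"{cm.n_flagged()} of {n_edges} edges had degenerate entropy histograms",
            stacklevel=2,
        )
    return cm


def entropic_fc_sweep(
    series_set: dict[tuple[str, str], EdgeCorrelationSeries],
    node_ids: list[str],
    n_bins_sweep: tuple[int, ...] = DEFAULT_BIN_SWEEP,
    bin_range: str = "data",
    meta: dict | None = None,
) -> dict[int, ConnectivityMatrix]:
    """Entropic FC over a sweep of bin counts (default 15..120 step 15)."""
    return {
        nb: entropic_fc(series_set, node_ids,
                        EntropyConfig(n_bins=nb, bin_range=bin_range), meta=meta)
        for nb in n_bins_sweep
    }


def _edge_map(series_set, node_ids, fn) -> np.ndarray:
    n = len(node_ids)
    idx = {nid: k for k, nid in enumerate(node_ids)}
    vals = np.full((n, n), np.nan)
    for (a, b), s in series_set.items():
        i, j = idx[a], idx[b]
        vals[i, j] = vals[j, i] = fn(s)
    return vals


def scan_connectivity(
    scan: ScanTimeseries,
    measures: tuple[str, ...] = ("sfc", "dfc", "efc"),
    entropy_config: EntropyConfig = EntropyConfig(),
) -> dict[str, ConnectivityMatrix]:
    """All requested measures for one scan.

    Returns matrices keyed ``sfc_r``, ``sfc_z`` (when ``sfc`` requested) and
    ``dfc_var`` / ``efc_H`` (sharing one set of per-edge DCC fits).
    """
    out: dict[str, ConnectivityMatrix] = {}
    if "sfc" in measures:
        r = static_fc(scan)
        out["sfc_r"] = r
        out["sfc_z"] = to_fisher_z(r)
    if "dfc" in measures or "efc" in measures:
        series = dcc_all_edges(scan)
        if "dfc" in measures:
            out["dfc_var"] = dynamic_fc(series, scan.node_ids, meta=scan.meta)
        if "efc" in measures:
            out["efc_H"] = entropic_fc(series, scan.node_ids, entropy_config, meta=scan.meta)
    return out


def split_half_reliability(first: ConnectivityMatrix, second: ConnectivityMatrix) -> float:
    """Pearson correlation between two matrices' vectorized upper triangles
    (NaN edges dropped pairwise) — the split-half reliability of a measure."""
    if first.measure != second.measure:
        raise ValueError("matrices measure different quantities")
    if first.node_ids != second.node_ids:
        raise ValueError("matrices cover different node sets")
    a, b = first.upper_values(), second.upper_values()
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
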