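"""Synthetic multi-participant FC study generator with known ground truth.

Generates BOLD-like region timeseries: correlated Gaussian innovations with a
block (network) correlation structure, passed through a node-wise AR(1) filter
for temporal smoothness. Condition effects shift within-/between-network
correlations in chosen design cells, and optional correlation *regimes* make
the true coupling time-varying — the structure the dynamic/entropic measures
are designed to detect.

Because the AR(1) coefficient is shared across nodes, the stationary
cross-correlation of the filtered series equals the innovation correlation,
so the target matrix is recovered exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .containers import ScanTimeseries
from .design import CELLS, NetworkScheme, StudyDesign

#: Rows of AR(1) warm-up discarded so scans start at stationarity.
_WARMUP = 100


def nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-8, max_iter: int = 50) -> np.ndarray:
    """Project a symmetric matrix to a unit-diagonal PSD correlation matrix.

    Alternates eigenvalue clipping at ``eig_floor`` with re-normalization to
    unit diagonal until the smallest eigenvalue is non-negative.
    """
    a = np.asarray(mat, dtype=float)
    a = (a + a.T) / 2.0
    for _ in range(max_iter):
        w, v = np.linalg.eigh(a)
        if w.min() >= 0:
            break
        w = np.clip(w, eig_floor, None)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def make_network_covariance(
    scheme: NetworkScheme,
    within_rho: float | dict[str, float],
    between_rho: float | dict[tuple[str, str], float],
    max_block_deviation: float = 0.1,
) -> np.ndarray:
    """Block correlation matrix from per-network / per-pair correlations.

    Entry (i, j) equals the requested rho for the (network_i, network_j)
    block; the filled matrix is repaired to the nearest PSD correlation
    matrix. If the repair moves any block mean by more than
    ``max_block_deviation`` the block request is considered contradictory.
    """
    nodes = scheme.node_ids
    labels = scheme.labels_for(nodes)
    n = len(nodes)

    def _w(net: str) -> float:
        r = within_rho[net] if isinstance(within_rho, dict) else within_rho
        return float(r)

    def _b(a: str, b: str) -> float:
        if isinstance(between_rho, dict):
            r = between_rho.get((a, b), between_rho.get((b, a)))
            if r is None:
                raise KeyError(f"no between_rho for pair ({a}, {b})")
        else:
            r = between_rho
        return float(r)

    target = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            rho = _w(a) if a == b else _b(a, b)
            if not -1.0 < rho < 1.0:
                raise ValueError(f"correlation {rho} for block ({a}, {b}) outside (-1, 1)")
            target[i, j] = target[j, i] = rho

    repaired = nearest_correlation(target)
    # verify the repair stayed close to the requested block values
    bad: list[tuple[str, str, float]] = []
    for key, idx in scheme.edge_interaction_index(nodes).items():
        if idx.size == 0:
            continue
        iu, ju = np.triu_indices(n, k=1)
        dev = np.abs(repaired[iu[idx], ju[idx]] - target[iu[idx], ju[idx]]).max()
        if dev > max_block_deviation:
            blocks = key[1:] if key[0] == "between" else (key[1], key[1])
            bad.append((*blocks, float(dev)))
    if bad:
        raise ValueError(
            "requested block correlations are not jointly PSD-repairable; "
            f"offending blocks (net_a, net_b, deviation): {bad}"
        )
    return repaired


@dataclass
class GroundTruth:
    """Generative truth for one design cell.

    Parameters
    ----------
    static_corr
        Target N x N correlation matrix (symmetric, unit diagonal, PSD).
    regimes
        Optional list of ``(start, end, corr)`` blocks whose half-open
        intervals ``[start, end)`` (0-based) partition ``[0, T)``; within each
        block the innovations follow that block's correlation.
    ar_coefficient
        Lag-1 autocorrelation phi in [0, 0.95] applied node-wise.
    noise_sd
        Innovation standard deviation (scale only; correlations unaffected).
    """

    static_corr: np.ndarray
    regimes: list[tuple[int, int, np.ndarray]] | None = None
    ar_coefficient: float = 0.4
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coefficient <= 0.95:
            raise ValueError("ar_coefficient must lie in [0, 0.95]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.static_corr = _check_corr(self.static_corr)
        if self.regimes is not None:
            self.regimes = [(int(s), int(e), _check_corr(c)) for s, e, c in self.regimes]

    def _validate_regimes(self, T: int) -> None:
        assert self.regimes is not None
        spans = sorted((s, e) for s, e, _ in self.regimes)
        cursor = 0
        for s, e in spans:
            if s != cursor or e <= s:
                raise ValueError(f"regimes must partition [0, {T}); got spans {spans}")
            cursor = e
        if cursor != T:
            raise ValueError(f"regimes must partition [0, {T}); got spans {spans}")


def _check_corr(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -1e-8:
        raise ValueError(
            f"correlation matrix is not PSD (min eigenvalue {w.min():.3g}); "
            "repair it with nearest_correlation first"
        )
    return mat


def _chol_psd(corr: np.ndarray) -> np.ndarray:
    # tolerate numerically semidefinite targets
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_scan(
    truth: GroundTruth,
    T: int,
    seed: int | np.random.Generator,
    node_ids: list[str] | None = None,
    meta: dict | None = None,
) -> ScanTimeseries:
    """Simulate one T x N scan from a :class:`GroundTruth`.

    Identical ``(truth, T, seed)`` give bit-identical output. When regimes are
    present, innovations inside each regime follow that regime's correlation
    matrix; the AR(1) warm-up uses the first regime.
    """
    if T < 30:
        raise ValueError("T must be >= 30")
    n = truth.static_corr.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    z = rng.standard_normal((T + _WARMUP, n))
    if truth.regimes is None:
        e = z @ _chol_psd(truth.static_corr).T
    else:
        truth._validate_regimes(T)
        e = np.empty_like(z)
        first = min(truth.regimes, key=lambda r: r[0])
        e[:_WARMUP] = z[:_WARMUP] @ _chol_psd(first[2]).T
        for s, t_end, corr in truth.regimes:
            sl = slice(_WARMUP + s, _WARMUP + t_end)
            e[sl] = z[sl] @ _chol_psd(corr).T
    e *= truth.noise_sd

    phi = truth.ar_coefficient
    x = lfilter([1.0], [1.0, -phi], e, axis=0) if phi > 0 else e
    data = x[_WARMUP:]

    if node_ids is None:
        node_ids = [f"node_{i + 1:03d}" for i in range(n)]
    return ScanTimeseries(data=data, node_ids=list(node_ids), meta=dict(meta or {}))


@dataclass
class ConditionEffect:
    """Shift of block correlations in selected design cells.

    ``within`` / ``between`` are additive shifts on the correlation scale,
    applied to the base block correlations in every cell listed in ``cells``.
    The default emulates an acute drug effect confined to the first scan half:
    within-network coupling drops and between-network coupling rises.
    """

    within: dict[str, float] = field(default_factory=dict)
    between: dict[tuple[str, str], float] = field(default_factory=dict)
    between_all: float = 0.0
    within_all: float = 0.0
    cells: tuple[tuple[str, str], ...] = (("drug", "first"),)

    @classmethod
    def null(cls) -> "ConditionEffect":
        return cls(cells=())

    @classmethod
    def default_drug_effect(cls) -> "ConditionEffect":
        """Reduced within-network, raised between-network coupling in the
        drug-first-half cell."""
        return cls(within_all=-0.10, between_all=0.05)

    def applies_to(self, cell: tuple[str, str]) -> bool:
        return cell in self.cells

    def shifted(
        self,
        cell: tuple[str, str],
        within_rho: dict[str, float],
        between_rho: dict[tuple[str, str], float],
    ) -> tuple[dict[str, float], dict[tuple[str, str], float]]:
        if not self.applies_to(cell):
            return dict(within_rho), dict(between_rho)
        w = {
            net: r + self.within_all + self.within.get(net, 0.0)
            for net, r in within_rho.items()
        }
        b = {
            pair: r
            + self.between_all
            + self.between.get(pair, self.between.get(pair[::-1], 0.0))
            for pair, r in between_rho.items()
        }
        return w, b


def _clip_rho(d: dict, lo: float = -0.9, hi: float = 0.9) -> dict:
    return {k: float(np.clip(v, lo, hi)) for k, v in d.items()}


def simulate_study(
    design: StudyDesign,
    scheme: NetworkScheme,
    effect: ConditionEffect | None = None,
    base_within: float | dict[str, float] = 0.4,
    base_between: float | dict[tuple[str, str], float] = 0.1,
    ar_coefficient: float = 0.4,
    participant_jitter: float = 0.05,
    regimes_by_cell: dict[tuple[str, str], list[tuple[int, int, np.ndarray]]] | None = None,
    seed: int | None = None,
) -> dict[tuple[str, str, str], ScanTimeseries]:
    """Simulate the full study: 4 scans per participant, keyed
    (participant, drug, half).

    Participant heterogeneity is a per-participant uniform(-jitter, +jitter)
    shift on every block correlation, shared across that participant's four
    cells so it cancels in within-subject contrasts. Each participant draws
    from an independent child stream of the study seed.
    """
    effect = effect if effect is not None else ConditionEffect.null()
    if seed is None:
        seed = design.seed
    for d, h in effect.cells:
        if (d, h) not in CELLS:
            raise ValueError(f"effect names unknown design cell ({d}, {h})")
    unknown = set(effect.within) - set(scheme.networks)
    if unknown:
        raise ValueError(f"effect names networks absent from the scheme: {sorted(unknown)}")

    within0 = {
        n: (base_within[n] if isinstance(base_within, dict) else float(base_within))
        for n in scheme.networks
    }
    between0 = {
        p: (
            base_between.get(p, base_between.get(p[::-1]))
            if isinstance(base_between, dict)
            else float(base_between)
        )
        for p in scheme.between_pairs
    }

    node_ids = scheme.node_ids
    root = np.random.SeedSequence(seed)
    scans: dict[tuple[str, str, str], ScanTimeseries] = {}
    for pid, pseq in zip(design.participants, root.spawn(design.n_participants)):
        jit_seq, *cell_seqs = pseq.spawn(1 + len(CELLS))
        jrng = np.random.default_rng(jit_seq)
        jw = {n: jrng.uniform(-participant_jitter, participant_jitter) for n in scheme.networks}
        jb = {p: jrng.uniform(-participant_jitter, participant_jitter) for p in scheme.between_pairs}
        for cell, cseq in zip(CELLS, cell_seqs):
            w, b = effect.shifted(cell, within0, between0)
            w = _clip_rho({n: r + jw[n] for n, r in w.items()})
            b = _clip_rho({p: r + jb[p] for p, r in b.items()})
            corr = make_network_covariance(scheme, w, b)
            regimes = None
            if regimes_by_cell is not None and cell in regimes_by_cell:
                regimes = regimes_by_cell[cell]
            truth = GroundTruth(static_corr=corr, regimes=regimes, ar_coefficient=ar_coefficient)
            drug, half = cell
            scans[(pid, drug, half)] = simulate_scan(
                truth,
                design.timepoints_per_half,
                np.random.default_rng(cseq),
                node_ids=node_ids,
                meta={"participant": pid, "drug": drug, "half": half},
            )
    return scans


def alternating_regimes(
    T: int, period: int, corr_a: np.ndarray, corr_b: np.ndarray
) -> list[tuple[int, int, np.ndarray]]:
    """Regime list alternating between two correlation targets every
    ``period`` timepoints, partitioning [0, T)."""
    out: list[tuple[int, int, np.ndarray]] = []
    start, use_a = 0, True
    while start < T:
        end = min(start + period, T)
        out.append((start, end, corr_a if use_a else corr_b))
        start, use_a = end, not use_a
    return out


def write_study(
    scans: dict[tuple[str, str, str], ScanTimeseries],
    scheme: NetworkScheme,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write scans as TSV (one file per participant x drug x half) plus the
    design table and the network map. Returns the design table."""
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for (pid, drug, half), scan in sorted(scans.items()):
        fname = f"{pid}_{drug}_{half}.tsv"
        sio.write_scan_tsv(scan, out / fname)
        rows.append({"participant": pid, "drug": drug, "half": half, "filename": fname})
    table = pd.DataFrame(rows)
    table.to_csv(out / "design_table.tsv", sep="\t", index=False)
    scheme.to_tsv(out / "network_map.tsv")
    return table
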