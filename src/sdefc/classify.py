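"""Connectome-based classification of design cells.

A PLS discriminant-analysis model (PLS regression of one-hot cell labels on
standardized edge features) is trained under leave-two-participant-out
cross-validation: for each of the C(n, 2) participant pairs, the model trains
on the remaining participants and classifies the held-out pair's four cells
each. Pooled predictions give a 4x4 confusion matrix (chance = 25%), and
discrimination of the drug-first-half cell is summarized as
d' = Phi^-1(hit rate) - Phi^-1(false-alarm rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cross_decomposition import PLSRegression

from .containers import ConnectivityMatrix
from .design import CELL_LABELS, CELLS, NetworkScheme, cell_label

#: The design cell the discrimination score targets by default.
TARGET_CELL = cell_label("drug", "first")


@dataclass
class ConnectomeFeatures:
    """Vectorized connectomes: one row per (participant, design cell).

    ``X`` columns are upper-triangle edges (row-major, i < j) of one measure;
    standardization happens inside each training fold, never here.
    """

    X: np.ndarray
    labels: np.ndarray
    participants: np.ndarray
    measure: str = ""
    mask_name: str = "whole-brain"

    def subset(self, columns: np.ndarray, mask_name: str) -> "ConnectomeFeatures":
        return ConnectomeFeatures(X=self.X[:, columns], labels=self.labels,
                                  participants=self.participants,
                                  measure=self.measure, mask_name=mask_name)


def connectome_features(
    matrices: dict[tuple[str, str, str], ConnectivityMatrix],
    measure: str,
) -> ConnectomeFeatures:
    """Build the feature matrix from per-cell connectivity matrices.

    Edges that are NaN (flagged) in any scan are dropped from the feature
    set so every fold sees a complete matrix.
    """
    participants = sorted({k[0] for k in matrices})
    rows, labels, pids = [], [], []
    for pid in participants:
        for drug, half in CELLS:
            cm = matrices[(pid, drug, half)]
            if cm.measure != measure:
                raise ValueError(f"matrix for {(pid, drug, half)} is {cm.measure}, not {measure}")
            rows.append(cm.upper_values())
            labels.append(cell_label(drug, half))
            pids.append(pid)
    X = np.vstack(rows)
    keep = np.all(np.isfinite(X), axis=0)
    return ConnectomeFeatures(X=X[:, keep], labels=np.array(labels),
                              participants=np.array(pids), measure=measure)


def enumerate_folds(participants) -> list[tuple[list, tuple]]:
    """All leave-two-participant-out folds: C(n, 2) (train ids, test pair)
    combinations — 66 cycles for 12 participants."""
    participants = list(participants)
    if len(participants) < 3:
        raise ValueError("need at least 3 participants")
    folds = []
    for pair in combinations(participants, 2):
        train = [p for p in participants if p not in pair]
        folds.append((train, pair))
    return folds


@dataclass
class PLSDAModel:
    """PLS-DA: PLS2 regression of one-hot labels on standardized features."""

    pls: PLSRegression
    mean: np.ndarray
    scale: np.ndarray
    keep: np.ndarray
    classes: tuple[str, ...]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted label = argmax of predicted one-hot responses; ties go
        to the earliest label in the fixed cell order."""
        Xs = (np.asarray(X, float)[:, self.keep] - self.mean) / self.scale
        scores = self.pls.predict(Xs)
        return np.array([self.classes[i] for i in np.argmax(scores, axis=1)])


def pls_da_fit(
    X: np.ndarray,
    labels: np.ndarray,
    n_components: int = 3,
    classes: tuple[str, ...] = CELL_LABELS,
) -> PLSDAModel:
    """Fit PLS-DA on training rows only.

    Features are standardized with training means/scales; zero-variance
    columns are dropped. ``n_components`` is capped by the training size.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.any(keep):
        raise ValueError("all features are constant in the training set")
    mean, scale = X[:, keep].mean(axis=0), sd[keep]
    Xs = (X[:, keep] - mean) / scale
    Y = np.column_stack([(labels == c).astype(float) for c in classes])
    ncomp = int(min(n_components, Xs.shape[1], Xs.shape[0] - 1))
    pls = PLSRegression(n_components=ncomp, scale=False, max_iter=2000)
    pls.fit(Xs, Y)
    return PLSDAModel(pls=pls, mean=mean, scale=scale, keep=keep, classes=tuple(classes))


@dataclass
class ClassificationReport:
    """Pooled cross-validation outcome.

    ``confusion`` rows are true cells, columns predicted cells (counts);
    ``fold_log`` has one row per classified observation.
    """

    confusion: pd.DataFrame
    n_folds: int
    classes: tuple[str, ...]
    fold_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def total(self) -> int:
        return int(self.confusion.to_numpy().sum())

    def accuracy(self) -> float:
        return float(np.trace(self.confusion.to_numpy()) / self.total)

    def proportions(self) -> pd.DataFrame:
        counts = self.confusion.to_numpy(dtype=float)
        return pd.DataFrame(counts / counts.sum(axis=1, keepdims=True),
                            index=self.confusion.index, columns=self.confusion.columns)

    def rates(self, target: str = TARGET_CELL) -> tuple[float, float, int, int]:
        """(hit rate, false-alarm rate, n_target, n_nontarget) for one cell."""
        c = self.confusion.to_numpy(dtype=float)
        k = list(self.classes).index(target)
        n_t = c[k].sum()
        n_nt = c.sum() - n_t
        hit = c[k, k] / n_t
        fa = (c[:, k].sum() - c[k, k]) / n_nt
        return float(hit), float(fa), int(n_t), int(n_nt)


def run_cv(
    features: ConnectomeFeatures,
    n_components: int = 3,
    classes: tuple[str, ...] = CELL_LABELS,
) -> ClassificationReport:
    """Leave-two-participant-out cross-validation of PLS-DA.

    Each fold classifies 8 rows (2 held-out participants x 4 cells); the
    confusion matrix pools predictions over all folds.
    """
    participants = sorted(set(features.participants))
    folds = enumerate_folds(participants)
    conf = pd.DataFrame(0, index=list(classes), columns=list(classes))
    log_rows = []
    for fold_id, (train, pair) in enumerate(folds):
        tr = np.isin(features.participants, train)
        te = ~tr
        model = pls_da_fit(features.X[tr], features.labels[tr],
                           n_components=n_components, classes=classes)
        pred = model.predict(features.X[te])
        for pid, true, hat in zip(features.participants[te], features.labels[te], pred):
            conf.loc[true, hat] += 1
            log_rows.append({"fold": fold_id, "test_pair": "+".join(pair),
                             "participant": pid, "true": true, "predicted": hat})
    return ClassificationReport(confusion=conf, n_folds=len(folds), classes=tuple(classes),
                                fold_log=pd.DataFrame(log_rows))


def d_prime(report: ClassificationReport, target: str = TARGET_CELL) -> dict:
    """Signal-detection discrimination of one design cell.

    d' = Phi^-1(hit) - Phi^-1(fa), with extreme rates corrected by the
    standard 1/(2n) rule (0 -> 1/(2n), 1 -> 1 - 1/(2n), n the rate's
    denominator) so the score stays finite.
    """
    hit, fa, n_t, n_nt = report.rates(target)

    def correct(rate: float, n: int) -> float:
        if rate <= 0.0:
            return 1.0 / (2 * n)
        if rate >= 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate

    h, f = correct(hit, n_t), correct(fa, n_nt)
    return {"d_prime": float(norm.ppf(h) - norm.ppf(f)),
            "hit": hit, "fa": fa, "hit_corrected": h, "fa_corrected": f}


def network_model_sweep(
    matrices_by_measure: dict[str, dict[tuple[str, str, str], ConnectivityMatrix]],
    scheme: NetworkScheme,
    n_components: int = 3,
    target: str = TARGET_CELL,
) -> pd.DataFrame:
    """Classification restricted to each network interaction's edges.

    For every measure and each of the K + K(K-1)/2 interactions, runs the
    full cross-validation on that interaction's feature columns and scores d'
    for the target cell. Below-chance d' is floored at 0 in
    ``d_prime_floored`` for display; raw values are retained. Interactions
    with fewer than 2 usable features are skipped.
    """
    rows = []
    for measure, matrices in matrices_by_measure.items():
        feats = connectome_features(matrices, measure)
        node_ids = matrices[sorted(matrices)[0]].node_ids
        # map surviving feature columns back to edge interaction indices
        full = np.vstack([matrices[k].upper_values() for k in sorted(matrices)])
        kept = np.flatnonzero(np.all(np.isfinite(full), axis=0))
        col_of_edge = {e: c for c, e in enumerate(kept)}
        for key, idx in scheme.edge_interaction_index(node_ids).items():
            cols = np.array([col_of_edge[e] for e in idx if e in col_of_edge], dtype=int)
            label = _sweep_label(key)
            if cols.size < 2:
                continue
            rep = run_cv(feats.subset(cols, label), n_components=n_components)
            dp = d_prime(rep, target=target)
            rows.append({
                "measure": measure, "interaction": label,
                "kind": key[0], "n_features": int(cols.size),
                "d_prime_raw": dp["d_prime"],
                "d_prime_floored": max(dp["d_prime"], 0.0),
                "hit": dp["hit"], "fa": dp["fa"],
                "accuracy": rep.accuracy(),
            })
    return pd.DataFrame(rows)


def _sweep_label(key: tuple[str, ...]) -> str:
    return f"within:{key[1]}" if key[0] == "within" else f"between:{key[1]}-{key[2]}"
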