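"""Network-level aggregation and the drug-by-time statistics.

Edges are averaged into the K within-network interactions and K(K-1)/2
between-network pairings (36 for the default 8-network scheme); each
interaction then enters a 2x2 within-subject (drug x scan-half) ANOVA, with
Holm-Bonferroni correction across interactions. Static FC is aggregated and
tested on the Fisher-z scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConnectivityMatrix
from .design import CELLS, NetworkScheme


@dataclass
class StatResult:
    """One test: statistic, degrees of freedom, p, effect size.

    ``effect_size`` is partial eta squared for ANOVA effects and Cohen's d
    for paired contrasts; ``ci`` is the 95% CI of the mean difference where
    defined. ``corrected_p`` is filled by Holm-Bonferroni when the result is
    part of a family.
    """

    effect: str
    statistic: float
    df: tuple
    p: float
    effect_size: float
    ci: tuple[float, float] | None = None
    corrected_p: float | None = None


def aggregate_networks(cm: ConnectivityMatrix, scheme: NetworkScheme) -> pd.Series:
    """Mean edge value per network interaction.

    Returns a Series indexed by interaction label (``within:NET`` /
    ``between:A-B``); NaN (flagged) edges are excluded from their mean.
    Static FC must be supplied on the Fisher-z scale.
    """
    if cm.measure == "sfc_r":
        raise ValueError("aggregate static FC on the Fisher-z scale (sfc_z), not raw r")
    index = scheme.edge_interaction_index(cm.node_ids)
    edges = cm.upper_values()
    out: dict[str, float] = {}
    for key, idx in index.items():
        if key[0] == "within" and idx.size < 1:
            raise ValueError(f"network {key[1]} has no within-network edges")
        vals = edges[idx]
        out[interaction_label(key)] = float(np.nanmean(vals)) if idx.size else np.nan
    return pd.Series(out, name=cm.measure)


def interaction_label(key: tuple[str, ...]) -> str:
    return f"within:{key[1]}" if key[0] == "within" else f"between:{key[1]}-{key[2]}"


def network_summary_table(
    matrices: dict[tuple[str, str, str], ConnectivityMatrix],
    scheme: NetworkScheme,
) -> pd.DataFrame:
    """Long table of interaction means: one row per
    (participant, drug, half, interaction)."""
    rows = []
    for (pid, drug, half), cm in sorted(matrices.items()):
        means = aggregate_networks(cm, scheme)
        for interaction, value in means.items():
            rows.append(
                {"participant": pid, "drug": drug, "half": half,
                 "interaction": interaction, "measure": cm.measure, "value": value}
            )
    return pd.DataFrame(rows)


def rm_anova_2x2(cell_values: pd.DataFrame | np.ndarray) -> dict[str, StatResult]:
    """Within-subject 2x2 (drug x half) ANOVA from per-participant cell means.

    Input: one row per participant, columns ordered as
    (placebo,first), (placebo,second), (drug,first), (drug,second).
    Each effect is the paired t-test on its per-participant contrast score
    (F = t^2 on (1, n-1) df); partial eta^2 = F / (F + df_error).
    """
    arr = np.asarray(cell_values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError("expected an n_participants x 4 cell-means array")
    n = arr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    pl_f, pl_s, dr_f, dr_s = arr.T
    scores = {
        "drug": (dr_f + dr_s) / 2 - (pl_f + pl_s) / 2,
        "time": (pl_f + dr_f) / 2 - (pl_s + dr_s) / 2,
        "interaction": (dr_f - dr_s) - (pl_f - pl_s),
    }
    out: dict[str, StatResult] = {}
    for name, sc in scores.items():
        sd = sc.std(ddof=1)
        df_err = n - 1
        if sd == 0:
            if np.all(sc == 0):
                # no effect and no variability: F = 0 by convention
                out[name] = StatResult(effect=name, statistic=0.0, df=(1, df_err),
                                       p=1.0, effect_size=0.0)
                continue
            raise ValueError(f"zero-variance contrast for effect {name!r}")
        t = sc.mean() / (sd / np.sqrt(n))
        F = t * t
        p = float(stats.f.sf(F, 1, df_err))
        out[name] = StatResult(
            effect=name, statistic=float(F), df=(1, df_err), p=p,
            effect_size=float(F / (F + df_err)),
        )
    return out


def paired_contrast(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Paired t-test of a vs b with Cohen's d and 95% CI of the mean diff.

    t = mean(d)/(sd(d)/sqrt(n)), d = mean(d)/sd(d), two-sided p on n-1 df.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("paired contrast needs two equal-length vectors, n >= 3")
    diff = a - b
    n = len(diff)
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    se = sd / np.sqrt(n)
    t = diff.mean() / se
    p = float(2 * stats.t.sf(abs(t), n - 1))
    half = stats.t.ppf(0.975, n - 1) * se
    return StatResult(
        effect="paired-contrast", statistic=float(t), df=(n - 1,), p=p,
        effect_size=float(diff.mean() / sd),
        ci=(float(diff.mean() - half), float(diff.mean() + half)),
    )


def holm_bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Bonferroni correction.

    Returns (reject flags, corrected p); rejections are always a superset of
    plain Bonferroni's.
    """
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, corrected, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject, corrected


def anova_table(
    summary: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Drug-by-time ANOVA for every interaction in a network summary table,
    Holm-corrected per effect family across interactions."""
    interactions = list(pd.unique(summary["interaction"]))
    participants = sorted(summary["participant"].unique())
    rows = []
    for interaction in interactions:
        sub = summary[summary["interaction"] == interaction]
        cells = np.column_stack([
            sub[(sub["drug"] == d) & (sub["half"] == h)]
            .set_index("participant").loc[participants, "value"].to_numpy()
            for d, h in CELLS
        ])
        for name, res in rm_anova_2x2(cells).items():
            rows.append({"interaction": interaction, "effect": name,
                         "F": res.statistic, "df1": res.df[0], "df2": res.df[1],
                         "p": res.p, "partial_eta_sq": res.effect_size})
    table = pd.DataFrame(rows)
    table["corrected_p"] = np.nan
    table["significant"] = False
    for name in table["effect"].unique():
        mask = table["effect"] == name
        rej, corr = holm_bonferroni(table.loc[mask, "p"].to_numpy(), alpha=alpha)
        table.loc[mask, "corrected_p"] = corr
        table.loc[mask, "significant"] = rej
    return table


def contrast_t_matrix(
    summary: pd.DataFrame,
    scheme: NetworkScheme,
    half: str,
) -> pd.DataFrame:
    """K x K matrix of paired t-values (drug - placebo) for one scan half:
    within-network interactions on the diagonal, between-pairs off it."""
    participants = sorted(summary["participant"].unique())
    K = len(scheme.networks)
    mat = pd.DataFrame(np.full((K, K), np.nan), index=scheme.networks,
                       columns=scheme.networks)

    def tval(interaction: str) -> float:
        sub = summary[(summary["interaction"] == interaction) & (summary["half"] == half)]
        get = lambda drug: (sub[sub["drug"] == drug].set_index("participant")
                            .loc[participants, "value"].to_numpy())
        return paired_contrast(get("drug"), get("placebo")).statistic

    for net in scheme.networks:
        mat.loc[net, net] = tval(f"within:{net}")
    for a, b in scheme.between_pairs:
        t = tval(f"between:{a}-{b}")
        mat.loc[a, b] = mat.loc[b, a] = t
    return mat


def edge_threshold_contrast(
    z_matrices: dict[tuple[str, str, str], ConnectivityMatrix],
    alpha: float = 0.05,
) -> dict:
    """Two-stage edge-wise static-FC contrast.

    Stage 1: per design cell, one-sample t of Fisher-z values against zero
    across participants; an edge survives if its Bonferroni-corrected p
    (two-sided, alpha / n_edges) falls below threshold in ANY cell. Stage 2:
    on the surviving union, paired t (drug - placebo) per scan half at the
    uncorrected alpha.

    Returns the survivor indices, per-half stage-2 survivor tables
    (node_i, node_j, t, p, direction) and the Bonferroni threshold used.
    """
    keys = sorted(z_matrices)
    participants = sorted({k[0] for k in keys})
    node_ids = z_matrices[keys[0]].node_ids
    iu, ju = np.triu_indices(len(node_ids), k=1)
    E = len(iu)
    thresh = alpha / E

    def stack(drug: str, half: str) -> np.ndarray:
        return np.vstack([z_matrices[(p, drug, half)].upper_values() for p in participants])

    cells = {(d, h): stack(d, h) for d, h in CELLS}
    survive_any = np.zeros(E, dtype=bool)
    for arr in cells.values():
        t, p = stats.ttest_1samp(arr, 0.0, axis=0)
        survive_any |= p < thresh
    union = np.flatnonzero(survive_any)

    stage2 = {}
    for half in ("first", "second"):
        if union.size:
            t, p = stats.ttest_rel(cells[("drug", half)][:, union],
                                   cells[("placebo", half)][:, union], axis=0)
            sig = p < alpha
            stage2[half] = pd.DataFrame({
                "node_i": np.array(node_ids)[iu[union[sig]]],
                "node_j": np.array(node_ids)[ju[union[sig]]],
                "t": t[sig], "p": p[sig],
                "direction": np.where(t[sig] > 0, "drug>placebo", "drug<placebo"),
            })
        else:
            stage2[half] = pd.DataFrame(columns=["node_i", "node_j", "t", "p", "direction"])
    return {"stage1_union": union, "stage2": stage2,
            "bonferroni_threshold": thresh, "n_edges": E}


def auc_drug_strength(times, ratings, t_max: float = 20.0) -> float:
    """Trapezoidal area under a drug-strength rating curve up to ``t_max``
    minutes. The curve is linearly interpolated at ``t_max`` if ratings
    bracket it; nothing is extrapolated before the first rating."""
    times = np.asarray(times, float)
    ratings = np.asarray(ratings, float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("rating times must be strictly increasing")
    if np.any((ratings < 0) | (ratings > 10)):
        raise ValueError("ratings must lie in [0, 10]")
    keep = times <= t_max
    if keep.sum() < 2:
        raise ValueError("need at least 2 ratings at or before t_max")
    t, r = times[keep], ratings[keep]
    if t[-1] < t_max and keep.sum() < len(times):
        r_at = np.interp(t_max, times, ratings)
        t, r = np.append(t, t_max), np.append(r, r_at)
    return float(np.trapezoid(r, t))


def change_vs_auc(delta_conn, auc) -> StatResult:
    """Pearson correlation (two-sided p) between a per-participant
    connectivity change and per-participant drug-strength AUC."""
    delta_conn = np.asarray(delta_conn, float)
    auc = np.asarray(auc, float)
    if delta_conn.shape != auc.shape or len(delta_conn) < 4:
        raise ValueError("need equal-length vectors with n >= 4")
    if delta_conn.std() == 0 or auc.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(delta_conn, auc)
    n = len(auc)
    return StatResult(effect="correlation", statistic=float(res.statistic),
                      df=(n - 2,), p=float(res.pvalue),
                      effect_size=float(res.statistic))
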