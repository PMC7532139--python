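"""Stage orchestration behind the CLI: simulate -> connectivity ->
network statistics -> classification -> report.

Each stage reads and writes the TSV formats in :mod:`sdefc.io`, is
deterministic given its config + inputs, and logs one structured line."""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .classify import connectome_features, d_prime, network_model_sweep, run_cv
from .config import RunConfig
from .design import DEFAULT_NETWORKS, NetworkScheme, StudyDesign
from .measures import EntropyConfig, scan_connectivity
from .netstats import anova_table, contrast_t_matrix, edge_threshold_contrast, network_summary_table
from .synthetic import ConditionEffect, simulate_study, write_study

log = logging.getLogger("sdefc")


def _hash_dir(path: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(path.glob("*.tsv")):
        h.update(f.name.encode())
        h.update(f.read_bytes())
    return h.hexdigest()[:12]


def stage_simulate(cfg: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    out = Path(out_dir)
    scheme = NetworkScheme.balanced(cfg.nodes_per_network, DEFAULT_NETWORKS[: cfg.n_networks])
    design = StudyDesign(
        participants=tuple(f"sub-{i + 1:02d}" for i in range(cfg.n_participants)),
        timepoints_per_half=cfg.timepoints_per_half,
        seed=cfg.seed,
    )
    effect = ConditionEffect.default_drug_effect() if cfg.effect == "drug" else ConditionEffect.null()
    scans = simulate_study(
        design, scheme, effect,
        base_within=cfg.base_within, base_between=cfg.base_between,
        ar_coefficient=cfg.ar_coefficient, participant_jitter=cfg.participant_jitter,
        seed=cfg.seed,
    )
    table = write_study(scans, scheme, out)
    cfg.to_yaml(out / "run_config.yaml")
    log.info("simulate: %d scans -> %s (hash %s)", len(scans), out, _hash_dir(out))
    return table


def stage_connectivity(cfg: RunConfig, data_dir: str | Path, out_dir: str | Path) -> None:
    data_dir, out = Path(data_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scans = sio.read_study(data_dir)
    econf = EntropyConfig(n_bins=cfg.entropy_bins, bin_range=cfg.entropy_range)
    by_measure: dict[str, dict] = {}
    flagged = 0
    for key, scan in sorted(scans.items()):
        mats = scan_connectivity(scan, measures=cfg.measures, entropy_config=econf)
        for mname, cm in mats.items():
            by_measure.setdefault(mname, {})[key] = cm
            flagged += cm.n_flagged() if mname == "efc_H" else 0
            sio.write_matrix_tsv(cm, out / sio.matrix_filename(*key, mname))
    for mname, mats in by_measure.items():
        sio.write_edge_table(mats, out / f"edges_{mname}.tsv")
    pd.read_csv(data_dir / "design_table.tsv", sep="\t").to_csv(
        out / "design_table.tsv", sep="\t", index=False)
    cfg.to_yaml(out / "run_config.yaml")
    log.info("connectivity: %d scans, measures=%s, flagged_edges=%d (input hash %s)",
             len(scans), ",".join(by_measure), flagged, _hash_dir(data_dir))


def stage_networks(
    cfg: RunConfig, conn_dir: str | Path, scheme_path: str | Path, out_dir: str | Path
) -> pd.DataFrame:
    conn_dir, out = Path(conn_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = sio.read_design_table(conn_dir / "design_table.tsv")
    scheme = NetworkScheme.from_tsv(scheme_path)
    stats_rows = []
    measure_names = {"sfc": "sfc_z", "dfc": "dfc_var", "efc": "efc_H"}
    for short in cfg.measures:
        mname = measure_names[short]
        mats = sio.read_measure_matrices(conn_dir, design, mname)
        summary = network_summary_table(mats, scheme)
        summary.to_csv(out / f"network_summary_{mname}.tsv", sep="\t", index=False)
        table = anova_table(summary, alpha=cfg.alpha)
        table.insert(0, "measure", mname)
        stats_rows.append(table)
        for half in ("first", "second"):
            tm = contrast_t_matrix(summary, scheme, half)
            tm.to_csv(out / f"tmatrix_{mname}_{half}.tsv", sep="\t",
                      index_label="network")
        if short == "sfc":
            res = edge_threshold_contrast(mats, alpha=cfg.alpha)
            for half, df in res["stage2"].items():
                df.to_csv(out / f"edge_survivors_{half}.tsv", sep="\t", index=False)
            log.info("edge threshold: %d of %d edges survive stage 1 "
                     "(bonferroni p < %.3g)", res["stage1_union"].size,
                     res["n_edges"], res["bonferroni_threshold"])
    stats = pd.concat(stats_rows, ignore_index=True)
    stats.to_csv(out / "network_anova.tsv", sep="\t", index=False)
    cfg.to_yaml(out / "run_config.yaml")
    log.info("networks: %d tests (alpha=%g)", len(stats), cfg.alpha)
    return stats


def stage_classify(
    cfg: RunConfig, conn_dir: str | Path, scheme_path: str | Path, out_dir: str | Path
) -> pd.DataFrame:
    conn_dir, out = Path(conn_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = sio.read_design_table(conn_dir / "design_table.tsv")
    scheme = NetworkScheme.from_tsv(scheme_path)
    measure_names = {"sfc": "sfc_z", "dfc": "dfc_var", "efc": "efc_H"}
    by_measure = {}
    rows = []
    for short in cfg.measures:
        mname = measure_names[short]
        mats = sio.read_measure_matrices(conn_dir, design, mname)
        feats = connectome_features(mats, mname)
        try:
            rep = run_cv(feats, n_components=cfg.n_components)
        except ValueError as exc:
            # e.g. entropic FC when nearly all edges were flagged degenerate
            log.warning("classify %s skipped: %s", mname, exc)
            continue
        by_measure[mname] = mats
        dp = d_prime(rep)
        rep.confusion.to_csv(out / f"confusion_{mname}_counts.tsv", sep="\t",
                             index_label="true\\predicted")
        rep.proportions().to_csv(out / f"confusion_{mname}_proportions.tsv", sep="\t",
                                 index_label="true\\predicted",
                                 float_format="%.4f")
        rep.fold_log.to_csv(out / f"fold_log_{mname}.tsv", sep="\t", index=False)
        rows.append({"measure": mname, "interaction": "whole-brain", "kind": "whole",
                     "n_features": feats.X.shape[1],
                     "d_prime_raw": dp["d_prime"], "d_prime_floored": max(dp["d_prime"], 0),
                     "hit": dp["hit"], "fa": dp["fa"], "accuracy": rep.accuracy()})
        log.info("classify %s: accuracy=%.3f d'=%.3f over %d folds",
                 mname, rep.accuracy(), dp["d_prime"], rep.n_folds)
    table = pd.DataFrame(rows)
    if cfg.sweep:
        sweep = network_model_sweep(by_measure, scheme, n_components=cfg.n_components)
        table = pd.concat([table, sweep], ignore_index=True)
    table.to_csv(out / "d_prime.tsv", sep="\t", index=False)
    cfg.to_yaml(out / "run_config.yaml")
    return table


def stage_report(net_dir: str | Path, cls_dir: str | Path, out_path: str | Path) -> str:
    """Assemble the network ANOVA table, edge survivor counts, confusion
    matrices and d' table into one plain-text summary."""
    net_dir, cls_dir = Path(net_dir), Path(cls_dir)
    parts = ["# sdefc pipeline summary\n"]
    anova = pd.read_csv(net_dir / "network_anova.tsv", sep="\t")
    sig = anova[anova["significant"] == True]  # noqa: E712
    parts.append(f"## Network drug-by-time ANOVA ({len(anova)} tests, "
                 f"{len(sig)} significant after Holm-Bonferroni)\n")
    if len(sig):
        parts.append(sig.to_string(index=False) + "\n")
    for half in ("first", "second"):
        f = net_dir / f"edge_survivors_{half}.tsv"
        if f.exists():
            n = len(pd.read_csv(f, sep="\t"))
            parts.append(f"Edge survivors ({half} half, paired drug vs placebo): {n}\n")
    dp = pd.read_csv(cls_dir / "d_prime.tsv", sep="\t")
    parts.append("## Classification (leave-two-participant-out PLS-DA)\n")
    parts.append(dp[dp["kind"] == "whole"][
        ["measure", "accuracy", "d_prime_raw", "hit", "fa"]].to_string(index=False) + "\n")
    sweep = dp[dp["kind"] != "whole"]
    if len(sweep):
        best = sweep.sort_values("d_prime_raw", ascending=False).groupby("measure").head(3)
        parts.append("Top network-interaction models by d':\n")
        parts.append(best[["measure", "interaction", "d_prime_raw", "accuracy"]]
                     .to_string(index=False) + "\n")
    text = "\n".join(parts)
    Path(out_path).write_text(text)
    return text
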