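"""End-to-end study pipeline: events + covariates -> full report.

Execution order mirrors the study's analysis plan: aggregate events into
four networks (agonistic/affiliative x pre/post); extract the network
parameter panels; compute balance-index hierarchies, ranks and pre/post
rank deltas; compare every variable across periods with paired Wilcoxon
tests; fit one logistic model per period for the dichotomous rank outcome;
run the Spearman correlation between rank delta and inflammation only if
the inflammation term is significant; contrast post-period ADG between
delta-sign groups with an unpaired Wilcoxon test; and fit a joint
standardized PCA over both periods.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ethogram import AGONISTIC, AFFILIATIVE, EventLog, aggregate_counts
from .hierarchy import (
    balance_index,
    balance_inputs_from_counts,
    censor_floor,
    delta_rank,
    rank_by_balance,
)
from .inference import (
    LogisticFit,
    PCAResult,
    SpearmanResult,
    WilcoxonResult,
    fit_logistic,
    group_summary,
    pca_standardized,
    spearman_corr,
    wilcoxon_paired,
    wilcoxon_unpaired,
)
from .network import DEFAULT_DISTANCE_MODE, NetworkPanel, network_panel

COVARIATE_COLUMNS = (
    "id",
    "period",
    "weight_kg",
    "adg_kg_day",
    "testosterone_pg_ml",
    "inflammation_score",
    "surgery_order",
)

#: Node metrics carried into the per-period variable table (suffixed _ag/_af).
NODE_METRICS = (
    "betweenness",
    "closeness",
    "degree_all",
    "degree_in",
    "degree_out",
    "hub_score",
    "authority_score",
)


@dataclass(frozen=True)
class StudyConfig:
    alpha: float = 0.05
    distance_mode: str = DEFAULT_DISTANCE_MODE
    testosterone_floor: float = 3.9
    force_spearman: bool = False  # run Spearman even if the gate fails
    run_pca: bool = True
    pca_scaling: str = "correlation"

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class StudyReport:
    table1: pd.DataFrame  # graph-level panel, params x (category, period)
    table2: pd.DataFrame  # per-variable medians (min; max) + Wilcoxon p
    table3: dict[str, LogisticFit]  # "pre" and "post" models
    delta_table: pd.DataFrame  # rank_pre/rank_post/delta/delta_sign + covariates
    spearman: SpearmanResult | None  # delta vs inflammation (gated)
    spearman_gate_passed: bool
    adg_by_delta_sign: dict
    pca: PCAResult | None
    panels: dict[tuple[str, str], NetworkPanel]
    variables: pd.DataFrame  # animal x period variable table used downstream
    log: list[str]
    provenance: dict


def _node_table(panel: NetworkPanel, roster: tuple[str, ...]) -> pd.DataFrame:
    """Panel node metrics over the full roster; inactive animals get zeros."""
    return panel.nodes.reindex(list(roster)).fillna(0.0)


def _check_covariates(covariates: pd.DataFrame, roster: tuple[str, ...]) -> pd.DataFrame:
    cov = pd.DataFrame(covariates)
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in cov.columns]
    if missing_cols:
        raise ValueError(f"covariate table is missing column(s) {missing_cols}")
    for period in ("pre", "post"):
        have = set(cov.loc[cov["period"] == period, "id"])
        gap = sorted(set(roster) - have)
        if gap:
            raise ValueError(
                f"covariates missing for animal(s) {gap} in period {period!r}"
            )
    return cov


def run_study(
    events: EventLog,
    covariates: pd.DataFrame,
    config: StudyConfig = StudyConfig(),
) -> StudyReport:
    """Run the full pre/post analysis and return every table of the report."""
    log_lines: list[str] = [
        f"sociorank {__version__}; alpha={config.alpha}; "
        f"distance_mode={config.distance_mode}; "
        f"delta convention: delta = rank_pre - rank_post (positive = ascension); "
        f"outcome coding: 1 = downgraded; PCA scaling: {config.pca_scaling}"
    ]
    periods = ("pre", "post")
    for period in periods:
        if not any(e.period == period for e in events.events):
            raise ValueError(f"event log contains no {period!r}-period events")
    roster = events.roster
    cov = _check_covariates(covariates, roster)

    # --- networks -----------------------------------------------------------
    counts = {
        (cat, per): aggregate_counts(events, cat, per)
        for cat in (AGONISTIC, AFFILIATIVE)
        for per in periods
    }
    panels = {
        key: network_panel(cm, distance_mode=config.distance_mode)
        for key, cm in counts.items()
    }
    table1 = pd.DataFrame(
        {
            f"{cat}_{per}": panels[(cat, per)].graph_row()
            for cat in (AGONISTIC, AFFILIATIVE)
            for per in periods
        }
    )

    # --- hierarchy ----------------------------------------------------------
    bi, ranks = {}, {}
    for per in periods:
        inputs = balance_inputs_from_counts(
            counts[(AGONISTIC, per)], counts[(AFFILIATIVE, per)]
        )
        bi[per] = {a: balance_index(b) for a, b in inputs.items()}
        ranks[per], tied = rank_by_balance(bi[per])
        if tied:
            log_lines.append(f"balance-index ties present in period {per!r}")
    delta = delta_rank(ranks["pre"], ranks["post"])
    if (delta["delta"] == 0).any():
        log_lines.append(
            "delta = 0 occurred; grouped with the negative sign (did not ascend)"
        )

    # --- per-animal x period variable table ---------------------------------
    frames = []
    for per in periods:
        block = pd.DataFrame(index=pd.Index(roster, name="animal"))
        for cat, suffix in ((AGONISTIC, "ag"), (AFFILIATIVE, "af")):
            nodes = _node_table(panels[(cat, per)], roster)
            for metric in NODE_METRICS:
                block[f"{metric}_{suffix}"] = nodes[metric]
        cov_p = cov[cov["period"] == per].set_index("id").loc[list(roster)]
        block["testosterone"] = censor_floor(
            cov_p["testosterone_pg_ml"], config.testosterone_floor
        ).to_numpy()
        block["weight"] = cov_p["weight_kg"].to_numpy(dtype=float)
        block["adg"] = cov_p["adg_kg_day"].to_numpy(dtype=float)
        block["bi"] = [bi[per][a] for a in roster]
        block["rank"] = [ranks[per][a] for a in roster]
        block["period"] = per
        frames.append(block)
    variables = pd.concat(frames).reset_index().set_index(["animal", "period"])

    # --- period comparisons (paired Wilcoxon) -------------------------------
    compare_vars = [c for c in variables.columns if c != "period"]
    rows = []
    for var in compare_vars:
        x = variables.xs("pre", level="period")[var].loc[list(roster)]
        y = variables.xs("post", level="period")[var].loc[list(roster)]
        res = wilcoxon_paired(x.to_numpy(), y.to_numpy())
        pre_s, post_s = group_summary(x), group_summary(y)
        rows.append(
            {
                "variable": var,
                "median_pre": pre_s["median"],
                "min_pre": pre_s["min"],
                "max_pre": pre_s["max"],
                "median_post": post_s["median"],
                "min_post": post_s["min"],
                "max_post": post_s["max"],
                "wilcoxon_p": res.p_value,
                "method": res.method,
                "different": res.p_value < config.alpha,
            }
        )
    table2 = pd.DataFrame(rows).set_index("variable")

    # --- logistic models ----------------------------------------------------
    study_cov = cov[cov["period"] == "post"].set_index("id").loc[list(roster)]
    y = (delta.loc[list(roster), "delta_sign"] == "non_positive").astype(float)
    predictors = {
        "pre": ["weight", "adg", "testosterone"],
        "post": ["weight", "adg", "inflammation_score", "surgery_order"],
    }
    table3: dict[str, LogisticFit] = {}
    for per in periods:
        X = pd.DataFrame({"intercept": 1.0}, index=list(roster))
        for term in predictors[per]:
            if term in ("inflammation_score", "surgery_order"):
                X[term] = study_cov[term].to_numpy(dtype=float)
            else:
                X[term] = variables.xs(per, level="period")[term].loc[list(roster)].to_numpy()
        fit = fit_logistic(X, y.to_numpy())
        if fit.separated:
            log_lines.append(f"{per}-period logistic model: separation detected")
        table3[per] = fit

    # --- conditional Spearman: delta vs inflammation ------------------------
    inflammation_p = table3["post"].term("inflammation_score")["p_value"]
    gate = bool(np.isfinite(inflammation_p) and inflammation_p < config.alpha)
    spearman = None
    if gate or config.force_spearman:
        spearman = spearman_corr(
            delta.loc[list(roster), "delta"].to_numpy(dtype=float),
            study_cov["inflammation_score"].to_numpy(dtype=float),
        )
        if not gate:
            log_lines.append("Spearman forced despite non-significant inflammation term")
    else:
        log_lines.append(
            f"Spearman gate: inflammation term p={inflammation_p:.4f} >= "
            f"alpha={config.alpha}; correlation not run"
        )

    # --- post-ADG by delta sign (unpaired Wilcoxon) -------------------------
    adg_post = variables.xs("post", level="period")["adg"]
    pos = delta.index[delta["delta_sign"] == "positive"]
    neg = delta.index[delta["delta_sign"] == "non_positive"]
    adg_cmp: dict = {"n_positive": len(pos), "n_non_positive": len(neg)}
    if len(pos) and len(neg):
        res = wilcoxon_unpaired(adg_post.loc[neg].to_numpy(), adg_post.loc[pos].to_numpy())
        adg_cmp.update(
            p_value=res.p_value,
            method=res.method,
            non_positive=group_summary(adg_post.loc[neg]),
            positive=group_summary(adg_post.loc[pos]),
        )
    else:
        log_lines.append("post-ADG contrast skipped: one delta-sign group is empty")

    # --- PCA ----------------------------------------------------------------
    pca = None
    if config.run_pca:
        pca_table = variables.drop(columns=["period"], errors="ignore").copy()
        constant = [
            c for c in pca_table.columns if pca_table[c].nunique(dropna=True) <= 1
        ]
        if constant:
            log_lines.append(f"PCA: dropped zero-variance column(s) {constant}")
            pca_table = pca_table.drop(columns=constant)
        pca = pca_standardized(pca_table, scaling=config.pca_scaling)
    else:
        log_lines.append("PCA disabled by configuration; exports omitted")

    delta_out = delta.join(study_cov[["inflammation_score", "surgery_order"]])
    provenance = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "config": asdict(config),
        "n_events": len(events),
        "n_animals": len(roster),
    }
    return StudyReport(
        table1=table1,
        table2=table2,
        table3=table3,
        delta_table=delta_out,
        spearman=spearman,
        spearman_gate_passed=gate,
        adg_by_delta_sign=adg_cmp,
        pca=pca,
        panels=panels,
        variables=variables,
        log=log_lines,
        provenance=provenance,
    )


def render_tables(report: StudyReport, outdir: str | Path) -> list[Path]:
    """Write the report as CSV files (+ run log); returns the paths written.

    Graph/summary tables round to 2 decimals, model estimates to 5 — the
    precisions at which such panels are conventionally reported.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame, decimals: int | None) -> None:
        path = outdir / name
        out = df.round(decimals) if decimals is not None else df
        out.to_csv(path)
        written.append(path)

    emit("table1.csv", report.table1, 2)
    emit("table2.csv", report.table2, 4)
    t3 = pd.concat(
        {per: fit.to_frame() for per, fit in report.table3.items()}, names=["model", "term"]
    )
    emit("table3.csv", t3, 5)
    emit("delta.csv", report.delta_table, None)
    emit("variables.csv", report.variables.drop(columns=["period"], errors="ignore"), 4)

    for (cat, per), panel in report.panels.items():
        emit(f"nodes_{cat}_{per}.csv", panel.nodes, 4)

    if report.pca is not None:
        comp = [f"PC{i + 1}" for i in range(len(report.pca.eigenvalues))]
        emit(
            "pca_loadings.csv",
            pd.DataFrame(report.pca.loadings, index=list(report.pca.variables), columns=comp),
            4,
        )
        emit(
            "pca_scores.csv",
            pd.DataFrame(report.pca.scores, index=report.variables.index, columns=comp),
            4,
        )
        emit(
            "pca_eigenvalues.csv",
            pd.DataFrame(
                {"eigenvalue": report.pca.eigenvalues, "proportion": report.pca.proportion},
                index=comp,
            ),
            4,
        )

    summary = {
        "spearman": (
            {"rho": report.spearman.rho, "p_value": report.spearman.p_value}
            if report.spearman is not None
            else None
        ),
        "spearman_gate_passed": report.spearman_gate_passed,
        "adg_by_delta_sign": report.adg_by_delta_sign,
        "provenance": report.provenance,
    }
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, default=float))
    written.append(path)

    log_path = outdir / "run_log.txt"
    log_path.write_text("\n".join(report.log) + "\n")
    written.append(log_path)
    return written
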