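"""End-to-end orchestration of the two cohort analyses.

The neoadjuvant workflow takes an expression matrix plus a clinical
table, derives (or accepts) the lymphocyte signature, clusters cases
into TIL-high/intermediate/low, merges to a binary TIL call, and runs
the response-association battery: overall and stratified Fisher/OR
analyses, a single-gene upper-quartile panel, and multivariate logistic
regression.  The adjuvant workflow takes IHC core measurements plus
survival follow-up: density normalization, core selection, marker
dichotomization, stratified Kaplan-Meier/log-rank analyses with
Mantel-Haenszel hazard ratios, a treatment trend test, and 5-year DFS
comparisons.  Both produce a machine-readable report that records every
parameter, every dropped sample, and a config hash so results can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import classify_cases
from .ihc import read_ihc_csv, selected_densities
from .io import (
    collapse_probes_by_iqr,
    read_annotation_tsv,
    read_clinical_csv,
    read_expression_tsv,
    z_normalize_rows,
)
from .signature import (
    CANONICAL_SIGNATURE,
    GeneSignature,
    SignatureConfig,
    anchor_filter,
    refine_signature,
    signature_score,
)
from .stats import (
    AssociationResult,
    associate,
    build_table,
    fit_logistic_irls,
    predictive_metrics,
    upper_quartile_gene_analysis,
)
from .survival import (
    dichotomize,
    five_year_dfs,
    km_estimate,
    logrank_test,
    logrank_trend,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisReport", "run_neoadjuvant", "run_adjuvant"]


@dataclass
class PipelineConfig:
    expression_path: str | None = None
    annotation_path: str | None = None
    clinical_path: str | None = None
    ihc_path: str | None = None
    candidate_genes: tuple[str, ...] | None = None
    anchor_genes: tuple[str, ...] = ("CD247", "MS4A1")
    correlation_threshold: float = 0.7
    refinement_alpha: float = 0.05
    fixed_signature: tuple[str, ...] | None = None
    n_clusters: int = 3
    min_fraction: float = 0.05
    merge_alpha: float = 0.05
    ci_level: float = 0.95
    trend_scores: dict = field(
        default_factory=lambda: {"none": 0.0, "CMF": 1.0, "anthracycline": 2.0}
    )
    five_year_horizon: float = 60.0
    marker_rules: dict = field(
        default_factory=lambda: {"TIA1": "upper_quartile"}
    )  # default rule is the median
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be ≥ 2")

    def hash(self) -> str:
        raw = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(raw.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Per-stage record of inputs, parameters, drops and statistics."""

    kind: str
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        blob = json.dumps(
            {
                "kind": self.kind,
                "config_hash": self.config_hash,
                "version": self.version,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
            default=_jsonify,
        )
        if path is not None:
            Path(path).write_text(blob)
        return blob


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _assoc_dict(result: AssociationResult) -> dict:
    return {
        "odds_ratio": result.odds_ratio,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "p": result.p_two_sided,
        "haldane_corrected": result.haldane_corrected,
    }


def _til_association(clinical: pd.DataFrame, binary: pd.Series) -> dict | None:
    """TIL-high vs TIL-low pCR association on one (sub)cohort."""
    merged = clinical.set_index("sample_id").join(binary.rename("til"))
    merged = merged[merged["til"].isin(["TIL-high", "TIL-low"])]
    try:
        table = build_table(merged["til"], merged["outcome"], "TIL-high", "pCR")
    except ValueError as exc:
        logger.warning("TIL association skipped: %s", exc)
        return None
    result = associate(table)
    metrics = predictive_metrics(table)
    return {
        "table": [table.a, table.b, table.c, table.d],
        **_assoc_dict(result),
        "ppv": metrics.ppv,
        "npv": metrics.npv,
        "accuracy": metrics.accuracy,
    }


_COVARIATE_CODING = {
    "size_T3": ("size_class", {"T3": 1, "T2": 0, "T1": 0}),
    "grade_3": ("grade", {"high": 1, "low": 0}),
    "node_pos": ("nodal", {"1": 1, "0": 0, 1: 1, 0: 0}),
    "age_ge50": ("age_class", {">=50": 1, "<50": 0}),
    "her2_pos": ("her2", {"pos": 1, "neg": 0}),
}


def _logistic_design(clinical: pd.DataFrame, binary: pd.Series):
    """Code covariates the way the response model tabulates them:
    size T3 vs T1/T2, grade 3 vs 1-2, node positive vs negative, age ≥50
    vs <50, Her2 amplified vs normal, regimen, TIL high vs low."""
    merged = clinical.set_index("sample_id").join(binary.rename("til"))
    merged = merged[merged["til"].isin(["TIL-high", "TIL-low"])]
    design = pd.DataFrame(index=merged.index)
    for name, (col, mapping) in _COVARIATE_CODING.items():
        design[name] = merged[col].map(mapping)
    if merged["treatment"].isin(["FEC", "TET"]).any():
        design["regimen_FEC"] = merged["treatment"].map({"FEC": 1, "TET": 0})
    design["til_high"] = (merged["til"] == "TIL-high").astype(int)
    y = (merged["outcome"] == "pCR").astype(float)
    keep = design.notna().all(axis=1) & merged["outcome"].notna()
    dropped = int((~keep).sum())
    return design[keep].astype(float), y[keep], dropped


def run_neoadjuvant(
    config: PipelineConfig,
    expression=None,
    clinical: pd.DataFrame | None = None,
    annotation=None,
) -> AnalysisReport:
    """Signature → clustering → response-association workflow."""
    report = AnalysisReport(
        kind="neoadjuvant", config_hash=config.hash(), version=__version__
    )
    if expression is None:
        if config.expression_path is None:
            raise ValueError("neoadjuvant stage requires an expression matrix")
        expression = read_expression_tsv(config.expression_path)
    if clinical is None:
        if config.clinical_path is None:
            raise ValueError("neoadjuvant stage requires a clinical table")
        clinical = read_clinical_csv(config.clinical_path)
    if annotation is None and config.annotation_path:
        annotation = read_annotation_tsv(config.annotation_path)

    if annotation is not None:
        expression = collapse_probes_by_iqr(expression, annotation)
    n_rows_before = expression.shape[0]
    matrix = z_normalize_rows(expression)
    report.stages["normalize"] = {
        "rows_in": n_rows_before,
        "rows_kept": matrix.shape[0],
        "samples": matrix.shape[1],
    }

    outcomes = clinical.set_index("sample_id")["outcome"]
    if config.fixed_signature is not None:
        signature = GeneSignature(
            genes=tuple(config.fixed_signature), provenance={"source": "fixed"}
        )
        report.stages["signature"] = {"source": "fixed", "genes": list(signature.genes)}
    else:
        candidates = config.candidate_genes
        if candidates is None:
            candidates = tuple(g for g in matrix.row_ids)
        sig_config = SignatureConfig(
            candidate_genes=tuple(candidates),
            anchor_genes=config.anchor_genes,
            correlation_threshold=config.correlation_threshold,
            refinement_alpha=config.refinement_alpha,
        )
        anchored = anchor_filter(matrix, sig_config)
        signature = refine_signature(
            matrix, anchored, outcomes, alpha=config.refinement_alpha
        )
        report.stages["signature"] = {
            "source": "derived",
            "candidates": len(sig_config.candidate_genes),
            "after_anchor_filter": len(anchored),
            "genes": list(signature.genes),
        }

    classification = classify_cases(
        matrix,
        signature,
        outcomes,
        n_primary=config.n_clusters,
        min_fraction=config.min_fraction,
        merge_alpha=config.merge_alpha,
    )
    table = classification.table
    report.stages["clustering"] = {
        "n_outliers": int(table["outlier"].sum()),
        "cluster_means": classification.cluster_means,
        "merge_p": classification.merge_p,
        "merge_performed": classification.merge_performed,
        "cluster_sizes": table[~table["outlier"]]["ordered_label"]
        .value_counts()
        .to_dict(),
    }

    binary = table["binary_label"]
    associations: dict = {}
    associations["overall"] = _til_association(clinical, binary)
    for arm in sorted(clinical["treatment"].dropna().unique()):
        sub = clinical[clinical["treatment"] == arm]
        associations[f"arm_{arm}"] = _til_association(sub, binary)
    her2 = clinical[clinical["her2"] == "pos"]
    associations["her2_positive"] = (
        _til_association(her2, binary) if len(her2) else None
    )
    tn = clinical[(clinical["her2"] == "neg") & (clinical["pr"] == "neg")]
    associations["triple_negative"] = (
        _til_association(tn, binary) if len(tn) else None
    )
    report.stages["associations"] = associations

    panel = {}
    for gene in signature.genes:
        try:
            panel[gene] = _assoc_dict(
                upper_quartile_gene_analysis(matrix, gene, outcomes)
            )
        except ValueError as exc:
            panel[gene] = {"error": str(exc)}
    scores = signature_score(matrix, signature)
    q3 = float(np.percentile(scores.to_numpy(), 75, method="linear"))
    exposure = (scores > q3).map({True: "high", False: "low"})
    panel["TIL_mean"] = _assoc_dict(
        associate(build_table(exposure, outcomes, "high", "pCR"))
    )
    report.stages["upper_quartile_panel"] = panel

    design, y, dropped = _logistic_design(clinical, binary)
    if design["til_high"].nunique() < 2:
        # the intermediate/low merge was withheld, so there is no binary
        # TIL contrast to model; record the skip instead of failing
        report.stages["logistic"] = {
            "skipped": "binary TIL call withheld; no TIL-low group to contrast"
        }
    else:
        model = fit_logistic_irls(
            design, y, coding={k: v[0] for k, v in _COVARIATE_CODING.items()}
        )
        report.stages["logistic"] = {
            "n": int(len(y)),
            "dropped_incomplete": dropped,
            "converged": model.converged,
            "iterations": model.n_iter,
            "summary": model.summary().to_dict(orient="index"),
        }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        classification.to_tsv(out / "classification.tsv")
        signature.to_file(out / "signature.tsv")
        report.to_json(out / "neoadjuvant_report.json")
    return report


def _marker_survival(records: pd.DataFrame, trend_scores: dict, horizon: float) -> dict:
    """KM / log-rank / trend / 5-year DFS battery within one marker stratum."""
    out: dict = {"n": int(len(records))}
    present = [g for g in trend_scores if (records["group"] == g).any()]
    out["km"] = {
        g: km_estimate(records[records["group"] == g]).survival_at(horizon)
        for g in present
    }
    for arm in present:
        if arm == "none" or "none" not in present:
            continue
        pair = records[records["group"].isin([arm, "none"])]
        try:
            res = logrank_test(pair, groups=(arm, "none"))
        except ValueError as exc:
            out[f"logrank_{arm}_vs_none"] = {"error": str(exc)}
            continue
        out[f"logrank_{arm}_vs_none"] = {
            "chi_square": res.chi_square,
            "p": res.p_two_sided,
            "hazard_ratio": res.hazard_ratio,
            "hr_ci": [res.hr_ci_low, res.hr_ci_high],
        }
    if len(present) >= 2:
        trend = logrank_trend(records, {g: trend_scores[g] for g in present})
        out["trend"] = {"chi_square": trend.chi_square, "p": trend.p_two_sided}
    dfs5 = {}
    for arm in present:
        try:
            r = five_year_dfs(records[records["group"] == arm], horizon)
            dfs5[arm] = {
                "proportion": r.proportion,
                "event_free": r.event_free,
                "evaluable": r.evaluable,
                "excluded_censored_early": r.excluded_censored_early,
            }
        except ValueError as exc:
            dfs5[arm] = {"error": str(exc)}
    out["five_year_dfs"] = dfs5
    if (
        "none" in dfs5
        and "anthracycline" in dfs5
        and "error" not in dfs5["none"]
        and "error" not in dfs5["anthracycline"]
    ):
        a = dfs5["anthracycline"]
        c = dfs5["none"]
        try:
            tab = build_table(
                pd.Series(
                    ["anthracycline"] * a["evaluable"] + ["none"] * c["evaluable"],
                    index=range(a["evaluable"] + c["evaluable"]),
                ),
                pd.Series(
                    ["free"] * a["event_free"]
                    + ["event"] * (a["evaluable"] - a["event_free"])
                    + ["free"] * c["event_free"]
                    + ["event"] * (c["evaluable"] - c["event_free"]),
                    index=range(a["evaluable"] + c["evaluable"]),
                ),
                "anthracycline",
                "free",
            )
            out["five_year_fisher_anthracycline_vs_none"] = _assoc_dict(associate(tab))
        except ValueError as exc:
            out["five_year_fisher_anthracycline_vs_none"] = {"error": str(exc)}
    return out


def run_adjuvant(
    config: PipelineConfig,
    ihc_cores=None,
    clinical: pd.DataFrame | None = None,
) -> AnalysisReport:
    """IHC density → dichotomization → survival workflow."""
    report = AnalysisReport(
        kind="adjuvant", config_hash=config.hash(), version=__version__
    )
    if ihc_cores is None:
        if config.ihc_path is None:
            raise ValueError("adjuvant stage requires IHC core measurements")
        ihc_cores = read_ihc_csv(config.ihc_path)
    if clinical is None:
        if config.clinical_path is None:
            raise ValueError("adjuvant stage requires a clinical table")
        clinical = read_clinical_csv(config.clinical_path)
    if clinical["dfs_months"].isna().all():
        raise ValueError("clinical table has no disease-free-survival follow-up")

    densities = selected_densities(ihc_cores)
    clin = clinical.set_index("sample_id")
    markers: dict = {}
    for marker in sorted(densities["marker"].unique()):
        sub = densities[densities["marker"] == marker].set_index("sample_id")
        rule = config.marker_rules.get(marker, "median")
        try:
            labels, cut = dichotomize(sub["normalized_count"], rule)
        except ValueError as exc:
            raise ValueError(f"marker {marker}: {exc}") from exc
        marker_report: dict = {"rule": rule, "cut": cut, "n_scored": int(len(labels))}
        for level in ("high", "low"):
            ids = labels.index[labels == level]
            rows = clin.loc[clin.index.intersection(ids)]
            rows = rows[rows["dfs_months"].notna()]
            records = pd.DataFrame(
                {
                    "sample_id": rows.index,
                    "time_months": rows["dfs_months"].to_numpy(),
                    "event": rows["dfs_event"].astype(int).to_numpy(),
                    "group": rows["treatment"].to_numpy(),
                }
            )
            marker_report[level] = _marker_survival(
                records, config.trend_scores, config.five_year_horizon
            )
        markers[marker] = marker_report
    report.stages["markers"] = markers

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        densities.to_csv(out / "densities.tsv", sep="\t", index=False)
        report.to_json(out / "adjuvant_report.json")
    return report
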