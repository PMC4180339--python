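"""End-to-end orchestration of the five analysis steps.

Step 1 descriptives, step 2 assumption screens, step 3 GRM calibration
with category diagnostics, step 4 DIF screening, step 5 the post-hoc CAT
comparison.  Everything is driven by one seeded config; two runs with
the same config and data produce identical JSON (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cat import CATConfig, compare_stopping_rules, export_decision_tree
from .classical import (
    cfa_one_factor,
    descriptives,
    local_independence_flags,
    mokken_scalability,
    pca_screen,
)
from .core import ItemBank, PipelineConfig, ResponseMatrix
from .dif import dif_screen_all
from .grm import fit_grm_mml, mean_theta_by_response

__all__ = ["run_pipeline", "render_report"]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="table", index=True))
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_jsonable(asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    bank: ItemBank,
    matrix: ResponseMatrix,
    run_dif: bool = True,
    tree_depth: int = 3,
) -> dict:
    """Execute steps 1-5 and return a JSON-ready report dictionary."""
    report: dict[str, Any] = {
        "provenance": {
            "package": "catgrm",
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "n_persons": matrix.n_persons,
            "n_items": matrix.n_items,
        }
    }

    # step 1: descriptives
    desc = descriptives(matrix)
    report["step1_descriptives"] = {
        "cronbach_alpha": desc.cronbach_alpha,
        "alpha_pass": desc.cronbach_alpha >= config.cronbach_alpha_floor,
        "total_mean": desc.total_mean,
        "total_sd": desc.total_sd,
        "items": _jsonable(desc.items.reset_index()),
    }

    # step 2: assumptions
    pca = pca_screen(matrix, config.pca_prop_var_min, config.pca_ratio_min)
    cfa = cfa_one_factor(matrix)
    li_flags = local_independence_flags(cfa.residuals, config.residual_corr_flag)
    mok = mokken_scalability(matrix, config.scalability_flag)
    report["step2_assumptions"] = {
        "pca": {
            "eigenvalues": _jsonable(pca.eigenvalues),
            "prop_var_first": pca.prop_var_first,
            "ratio_first_second": pca.ratio_first_second,
            "pass_20pct": pca.pass_20pct,
            "pass_ratio4": pca.pass_ratio4,
        },
        "cfa": {
            "chi2": cfa.chi2, "df": cfa.df, "p_value": cfa.p_value,
            "cfi": cfa.cfi, "tli": cfa.tli,
            "rmsea": cfa.rmsea, "rmsea_ci90": list(cfa.rmsea_ci90),
            "srmr": cfa.srmr, "heywood": cfa.heywood,
            "loadings": _jsonable(cfa.loadings),
        },
        "local_independence": {
            "flagged_pairs": [
                {"item_a": a, "item_b": b, "residual_r": r} for a, b, r in li_flags
            ],
            "pass": not li_flags,
        },
        "scalability": {
            "item_h": _jsonable(mok.item_h),
            "overall_h": mok.overall_h,
            "flagged_items": mok.flagged_items,
            "excluded_items": mok.excluded_items,
        },
    }

    # step 3: GRM calibration + category diagnostics
    fit = fit_grm_mml(matrix, n_nodes=config.quadrature_nodes)
    theta_table = mean_theta_by_response(matrix, fit)
    report["step3_grm"] = {
        "parameters": _jsonable(fit.bank.to_frame()),
        "standard_errors": _jsonable(fit.standard_errors.reset_index()),
        "log_likelihood": fit.log_likelihood,
        "n_iterations": fit.n_iterations,
        "converged": fit.converged,
        "quadrature": fit.quadrature_spec,
        "warnings": fit.warnings,
        "mean_theta_by_response": _jsonable(theta_table),
        "flagged_items": sorted(
            theta_table.loc[theta_table["overlap_flag"], "item"].unique().tolist()
        ),
    }

    # step 4: DIF
    if run_dif and matrix.covariates is not None and len(matrix.covariates.columns):
        dif_table = dif_screen_all(matrix, fit.bank, alpha=config.dif_alpha)
        flagged = dif_table[dif_table["flag"]] if len(dif_table) else dif_table
        report["step4_dif"] = {
            "alpha": config.dif_alpha,
            "n_tests": int(len(dif_table)),
            "n_flagged": int(len(flagged)),
            "flags": _jsonable(flagged.reset_index(drop=True)) if len(dif_table) else [],
            "all_negligible": bool(
                (flagged["delta_mcfadden_r2"] < config.mcfadden_negligible).all()
            ) if len(flagged) else True,
            "table": _jsonable(dif_table),
        }
    else:
        report["step4_dif"] = {"skipped": True, "reason": "no covariates available"}

    # step 5: CAT comparison on the calibrated bank
    cat_cfg = CATConfig(**config.cat) if config.cat else CATConfig()
    comparison = compare_stopping_rules(fit.bank, matrix, base=cat_cfg)
    tree = export_decision_tree(
        fit.bank, CATConfig(
            entry_theta=cat_cfg.entry_theta, estimator=cat_cfg.estimator,
            cutoff_theta=cat_cfg.cutoff_theta, confidence=cat_cfg.confidence,
            min_items=1, max_items=cat_cfg.max_items,
        ), max_depth=min(tree_depth, cat_cfg.max_items),
    )
    report["step5_cat"] = {
        "config": asdict(cat_cfg),
        "stopping_rule_comparison": _jsonable(comparison),
        "decision_tree": tree,
    }
    return report


def _markdown_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    def fmt(v):
        if isinstance(v, float):
            return floatfmt.format(v)
        return str(v)

    header = "| " + " | ".join(df.columns) + " |"
    sep = "| " + " | ".join("---" for _ in df.columns) + " |"
    rows = ["| " + " | ".join(fmt(v) for v in row) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *rows])


def render_report(report: dict, fmt: str = "json") -> str:
    """Render a pipeline report as JSON or markdown."""
    if fmt == "json":
        return json.dumps(_jsonable(report), indent=2, sort_keys=True)
    if fmt != "markdown":
        raise ValueError(f"unknown format {fmt!r}; supported: json, markdown")

    lines = ["# Psychometric pipeline report", ""]
    prov = report.get("provenance", {})
    if prov:
        lines += [f"- seed: {prov.get('seed')}  config: {prov.get('config_hash')}",
                  f"- n_persons: {prov.get('n_persons')}  n_items: {prov.get('n_items')}", ""]

    s1 = report.get("step1_descriptives")
    if s1:
        lines += ["## Step 1 — Descriptives",
                  f"Cronbach alpha: {s1['cronbach_alpha']:.3f} "
                  f"({'pass' if s1['alpha_pass'] else 'below floor'})",
                  f"Total score mean (SD): {s1['total_mean']:.2f} ({s1['total_sd']:.2f})", ""]
        items = pd.DataFrame(s1["items"]["data"]) if isinstance(s1["items"], dict) else None
        if items is not None and len(items):
            cols = [c for c in items.columns if c != "index"]
            lines += [_markdown_table(items[cols].round(3)), ""]

    s2 = report.get("step2_assumptions")
    if s2:
        pca, cfa = s2["pca"], s2["cfa"]
        lines += ["## Step 2 — IRT assumptions",
                  f"PCA: first factor {100 * pca['prop_var_first']:.1f}% of variance "
                  f"(rule >= 20%: {'pass' if pca['pass_20pct'] else 'fail'}); "
                  f"ratio first/second {pca['ratio_first_second']:.1f} "
                  f"(rule >= 4: {'pass' if pca['pass_ratio4'] else 'fail'})",
                  f"CFA: chi2({cfa['df']}) = {cfa['chi2']:.1f}, CFI {cfa['cfi']:.3f}, "
                  f"TLI {cfa['tli']:.3f}, RMSEA {cfa['rmsea']:.3f} "
                  f"(90% CI {cfa['rmsea_ci90'][0]:.3f}-{cfa['rmsea_ci90'][1]:.3f}), "
                  f"SRMR {cfa['srmr']:.3f}",
                  f"Local independence: {len(s2['local_independence']['flagged_pairs'])} "
                  f"flagged pair(s)",
                  f"Scalability: overall H {s2['scalability']['overall_h']:.3f}, "
                  f"flagged items {s2['scalability']['flagged_items'] or 'none'}", ""]

    s3 = report.get("step3_grm")
    if s3:
        lines += ["## Step 3 — Graded response model",
                  f"Converged: {s3['converged']} after {s3['n_iterations']} iterations; "
                  f"log-likelihood {s3['log_likelihood']:.1f}",
                  f"Items flagged by category-overlap diagnostic: "
                  f"{s3['flagged_items'] or 'none'}", ""]
        params = pd.DataFrame(s3["parameters"]["data"]) if isinstance(s3["parameters"], dict) else None
        if params is not None and len(params):
            cols = [c for c in params.columns if c != "index"]
            lines += [_markdown_table(params[cols].round(3)), ""]

    s4 = report.get("step4_dif")
    if s4:
        lines.append("## Step 4 — Differential item functioning")
        if s4.get("skipped"):
            lines += [f"Skipped: {s4.get('reason')}", ""]
        else:
            lines += [f"{s4['n_flagged']} of {s4['n_tests']} tests flagged at "
                      f"alpha = {s4['alpha']}; all flagged effects negligible: "
                      f"{s4['all_negligible']}", ""]

    s5 = report.get("step5_cat")
    if s5:
        lines.append("## Step 5 — CAT stopping-rule comparison")
        comp = s5["stopping_rule_comparison"]
        comp_df = pd.DataFrame(comp["data"]) if isinstance(comp, dict) else pd.DataFrame(comp)
        if len(comp_df):
            cols = [c for c in comp_df.columns if c != "index"]
            lines += [_markdown_table(comp_df[cols]), ""]
        lines += [f"Decision-tree root: item {s5['decision_tree']['item']}", ""]

    return "\n".join(lines)


def write_report(report: dict, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "markdown" if path.suffix in (".md", ".markdown") else "json"
    path.write_text(render_report(report, fmt))
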