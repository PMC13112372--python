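"""Config-driven orchestration of the full analysis.

Stages: ``simulate`` (or load from files) -> ``express`` (filter, size
factors, VST, DE, DEG calls, PCA) -> ``score`` (surrogate indices +
hub correlations) -> ``consensus`` (TF over-representation and top-k
intersection) -> ``cohort`` (indices, summaries, logistic models, RCS,
ROC) -> ``mouse`` (group stats and Pearson correlations).

Outputs are TSV tables with explicit headers plus a JSON run report;
derived result tables serialize floats at 10 significant digits so reruns
diff cleanly, while simulated input files keep full precision so any
stage can be re-run from its persisted inputs with identical results.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import cohort as cohort_mod
from . import expression, scores, simulate, tf_consensus

FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT,
              index=index_label is not None, index_label=index_label)


def read_counts_tsv(path) -> expression.CountMatrix:
    """Read a gene x sample TSV (first column = gene symbol) plus a
    sidecar ``<name>.groups.tsv`` mapping sample -> group."""
    path = Path(path)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    groups_path = path.with_suffix(".groups.tsv")
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return expression.CountMatrix(counts, groups)


def write_counts_tsv(cm: expression.CountMatrix, path) -> None:
    path = Path(path)
    cm.counts.to_csv(path, sep="\t", index_label="gene")
    cm.groups.rename("group").to_csv(path.with_suffix(".groups.tsv"), sep="\t",
                                     index_label="sample")


def _default_config(seed: int) -> dict:
    return {
        "seed": seed,
        "outdir": "neuroimmune_run",
        "stages": ["express", "score", "consensus", "cohort", "mouse"],
        "expression": {"simulate": {}},
        "regulons": {"simulate": {}},
        "cohort": {"simulate": {}},
        "mouse": {"simulate": {}},
    }


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def run(config: dict | None = None, seed: int = 0, outdir=None) -> dict:
    """Execute the enabled stages in dependency order; returns the run report."""
    cfg = _default_config(seed)
    if config:
        for k, v in config.items():
            cfg[k] = v
    seed = int(cfg["seed"])
    outdir = Path(outdir or cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    report: dict = {"seed": seed, "stages": {}, "outdir": str(outdir)}

    if "simulate" in stages:
        # materialize every configured synthetic input, no analysis
        expr_sim = simulate.ExpressionSimConfig(
            **{"seed": seed, **cfg.get("expression", {}).get("simulate", {})}
        )
        cm, _ = simulate.simulate_counts(expr_sim)
        write_counts_tsv(cm, outdir / "counts.tsv")
        reg_sim = simulate.RegulonSimConfig(
            **{"seed": seed + 1, **cfg.get("regulons", {}).get("simulate", {})}
        )
        libraries, planted = simulate.simulate_regulon_libraries(reg_sim)
        for lib in libraries:
            tf_consensus.write_gmt(lib, outdir / f"{lib.name}.gmt")
        (outdir / "planted_query.txt").write_text("\n".join(planted.query_genes) + "\n")
        co_sim = simulate.CohortSimConfig(
            **{"seed": seed + 2, **cfg.get("cohort", {}).get("simulate", {})}
        )
        simulate.simulate_clinical_cohort(co_sim).to_csv(
            outdir / "cohort.csv", index=False
        )
        mo_sim = simulate.MouseSimConfig(
            **{"seed": seed + 3, **cfg.get("mouse", {}).get("simulate", {})}
        )
        simulate.simulate_mouse_phenotypes(mo_sim).to_csv(
            outdir / "mouse.csv", index=False
        )
        report["stages"]["simulate"] = {
            "n_genes": expr_sim.n_genes,
            "n_libraries": reg_sim.n_libraries,
            "n_cohort": co_sim.n_control + co_sim.n_case,
            "n_mice": 2 * mo_sim.n_per_group,
        }

    # ---- expression arm -------------------------------------------------
    counts = truth = None
    need_expr = any(s in stages for s in ("express", "score", "consensus"))
    if need_expr:
        expr_cfg = cfg.get("expression", {})
        if "counts_tsv" in expr_cfg:
            counts = read_counts_tsv(expr_cfg["counts_tsv"])
        elif "simulate" in expr_cfg:
            sim = simulate.ExpressionSimConfig(**{"seed": seed, **expr_cfg["simulate"]})
            counts, truth = simulate.simulate_counts(sim)
            write_counts_tsv(counts, outdir / "counts.tsv")
        else:
            raise ValueError("expression stage enabled but no counts source configured")

    de = norm = None
    if "express" in stages:
        filtered = expression.filter_low_counts(counts)
        factors = expression.size_factors(filtered)
        norm = expression.vst_normalize(filtered, factors)
        de = expression.differential_expression(filtered, factors)
        up, down = expression.call_degs(de)
        pca_res = expression.pca(norm)
        _write_tsv(de.table, outdir / "de_table.tsv", index_label="gene")
        (outdir / "degs_up.txt").write_text("\n".join(up) + "\n")
        (outdir / "degs_down.txt").write_text("\n".join(down) + "\n")
        _write_tsv(pca_res.scores, outdir / "pca_scores.tsv", index_label="sample")
        report["stages"]["express"] = {
            "n_genes_filtered": int(len(filtered.genes)),
            "n_deg_up": len(up),
            "n_deg_down": len(down),
            "pc1_variance_fraction": float(pca_res.variance_fraction[0]),
        }

    if "score" in stages:
        if norm is None:
            raise ValueError("score stage requires the express stage (no VST matrix)")
        panel = scores.MarkerPanel(**cfg.get("panel", {}))
        ss = scores.score_samples(norm, panel)
        corr = scores.correlate_hub_with_indices(ss)
        _write_tsv(ss.table, outdir / "surrogate_scores.tsv", index_label="sample")
        corr_rows = pd.DataFrame(
            {
                idx: {
                    "weighted_r": c.weighted_r, "slope": c.slope, "p": c.p,
                    "robust_t": c.robust_t, "n": c.n,
                }
                for idx, c in corr.items()
            }
        ).T
        _write_tsv(corr_rows, outdir / "hub_correlations.tsv", index_label="index")
        report["stages"]["score"] = {
            k: {"weighted_r": float(c.weighted_r), "p": float(c.p)}
            for k, c in corr.items()
        }

    if "consensus" in stages:
        if de is None:
            raise ValueError("consensus stage requires the express stage (no DEG set)")
        reg_cfg = cfg.get("regulons", {})
        if "gmt_paths" in reg_cfg:
            libraries = [tf_consensus.read_gmt(p) for p in reg_cfg["gmt_paths"]]
            universe = {str(g).upper() for g in de.table.index[de.table["tested"]]}
            query = {g.upper() for g in de.up_genes()}
        elif "simulate" in reg_cfg:
            sim = simulate.RegulonSimConfig(**{"seed": seed + 1, **reg_cfg["simulate"]})
            libraries, planted = simulate.simulate_regulon_libraries(sim)
            universe = {g.upper() for g in planted.universe}
            query = {g.upper() for g in planted.query_genes}
        else:
            raise ValueError("consensus stage enabled but no regulon source configured")
        results = [tf_consensus.enrich_tfs(query, lib, universe) for lib in libraries]
        hubs = tf_consensus.consensus_hubs(results, top_k=int(cfg.get("top_k", 20)))
        for res in results:
            _write_tsv(res.table, outdir / f"enrichment_{res.library}.tsv",
                       index_label="tf")
        (outdir / "consensus_hubs.txt").write_text(
            "\n".join(sorted(hubs.intersection)) + "\n"
        )
        report["stages"]["consensus"] = {
            "consensus": sorted(hubs.intersection),
            "n_libraries": len(results),
        }

    # ---- clinical arm ---------------------------------------------------
    if "cohort" in stages:
        co_cfg = cfg.get("cohort", {})
        if "csv" in co_cfg:
            table = pd.read_csv(co_cfg["csv"])
        elif "simulate" in co_cfg:
            sim = simulate.CohortSimConfig(**{"seed": seed + 2, **co_cfg["simulate"]})
            table = simulate.simulate_clinical_cohort(sim)
            table.to_csv(outdir / "cohort.csv", index=False)
        else:
            raise ValueError("cohort stage enabled but no cohort source configured")
        gated = cohort_mod.apply_gating(table)
        indices = cohort_mod.compute_indices(gated.table)
        indices["dre"] = (indices["group"] == "DRE").astype(int)
        summary = cohort_mod.summarize_cohort(indices)
        fits = {}
        for marker in ("nlr", "sii", "crp"):
            fit = cohort_mod.fit_logistic(indices, "dre", f"z_{marker}")
            fits[marker] = fit
        model_rows = pd.concat(
            {m: f.table.loc[[f"z_{m}"]] for m, f in fits.items()}, names=["marker"]
        ).reset_index(level=1, drop=True)
        _write_tsv(model_rows, outdir / "logistic_models.tsv", index_label="marker")
        rocs = {
            m: cohort_mod.roc_auc(indices[m].to_numpy(), indices["dre"].to_numpy())
            for m in ("nlr", "sii", "crp")
        }
        panel_roc = cohort_mod.combined_panel(indices, "dre")
        roc_tab = pd.DataFrame(
            {
                "auc": {**{m: r.auc for m, r in rocs.items()}, "panel": panel_roc.auc}
            }
        )
        _write_tsv(roc_tab, outdir / "roc_auc.tsv", index_label="marker")
        summary_rows = pd.DataFrame(
            [
                {"variable": v, "kind": s.kind, "test": s.test, "p": s.p}
                for v, s in summary.items()
            ]
        )
        _write_tsv(summary_rows, outdir / "cohort_summary.tsv")
        report["stages"]["cohort"] = {
            "n_records": int(len(indices)),
            "removed": gated.removed,
            "or": {m: float(f.table.loc[f"z_{m}", "or_"]) for m, f in fits.items()},
            "auc": {m: float(r.auc) for m, r in rocs.items()},
            "panel_auc": float(panel_roc.auc),
        }

    if "mouse" in stages:
        mo_cfg = cfg.get("mouse", {})
        if "csv" in mo_cfg:
            mtable = pd.read_csv(mo_cfg["csv"])
        elif "simulate" in mo_cfg:
            sim = simulate.MouseSimConfig(**{"seed": seed + 3, **mo_cfg["simulate"]})
            mtable = simulate.simulate_mouse_phenotypes(sim)
            mtable.to_csv(outdir / "mouse.csv", index=False)
        else:
            raise ValueError("mouse stage enabled but no phenotype source configured")
        stats_tab = cohort_mod.mouse_group_stats(mtable)
        _write_tsv(stats_tab, outdir / "mouse_group_stats.tsv", index_label="marker")
        corr = {}
        for m in ("nlr", "crp", "il6"):
            r, p = cohort_mod.pearson_correlation(
                mtable["pstat3"].to_numpy(), mtable[m].to_numpy()
            )
            corr[m] = {"r": float(r), "p": float(p)}
        _write_tsv(pd.DataFrame(corr).T, outdir / "mouse_correlations.tsv",
                   index_label="marker")
        report["stages"]["mouse"] = {"n_animals": int(len(mtable)),
                                     "correlations": corr}

    report["completed"] = stages
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
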