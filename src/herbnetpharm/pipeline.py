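"""End-to-end pipeline: filter -> networks -> screen -> modules -> enrichment.

Driven by one YAML config naming the five inputs (or a ``simulation``
block), the pipeline writes every intermediate artifact plus a
machine-readable ``report.json``. Identical config and seed produce a
byte-identical report. A stage failure is logged with its stage name and
recorded in the report; downstream stages are skipped.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .adme import AdmeThresholds, filter_active_compounds, screen_summary
from .centrality import centrality_table, screen_key_nodes
from .enrichment import enrich_gene_set, select_top_terms
from .errors import ConfigurationError, HerbNetPharmError, ParseError
from .io import (
    read_compound_table,
    read_edge_list,
    read_gene_list,
    read_gmt,
    read_target_associations,
    write_compound_table,
    write_graph,
)
from .mcode import McodeParams, mcode_find_modules
from .network import (
    build_compound_target_network,
    induced_ppi_subgraph,
    merge_target_networks,
    shared_targets,
)
from .simulate import SimulationConfig, simulate_study

__all__ = ["run_pipeline", "validate_config", "PipelineError"]

log = logging.getLogger("herbnetpharm")

_INPUT_KEYS = ("compounds", "associations", "disease_genes", "background_ppi", "go_gmt")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "adme": {"ob_min": 30.0, "dl_min": 0.18, "inclusive": True},
    "screen": {"strict": True},
    "mcode": {"vwp": 0.2, "haircut": True, "fluff": False,
              "fluff_density": 0.1, "min_size": 3},
    "enrichment": {"alpha": 0.05, "top_go": 10, "top_kegg": 20,
                   "ease": False, "adjust": "none"},
}


class PipelineError(HerbNetPharmError):
    pass


def _load_config(path: str | Path) -> dict:
    try:
        with open(path, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def validate_config(config: str | Path | dict) -> list[str]:
    """Check a pipeline config; returns a list of problems (empty = valid)."""
    cfg = _load_config(config) if not isinstance(config, dict) else config
    problems: list[str] = []

    if "output_dir" not in cfg:
        problems.append("missing 'output_dir'")

    sim = cfg.get("simulation")
    inputs = cfg.get("inputs")
    if sim is None and inputs is None:
        problems.append("config needs an 'inputs' or a 'simulation' section")
    if sim is not None:
        try:
            SimulationConfig(seed=int(cfg.get("seed", 0)), **sim)
        except (HerbNetPharmError, TypeError) as exc:
            problems.append(f"simulation: {exc}")
    elif inputs is not None:
        for key in _INPUT_KEYS:
            if key not in inputs:
                problems.append(f"inputs: missing '{key}'")
            elif not Path(inputs[key]).is_file():
                problems.append(f"inputs: '{key}' file not found: {inputs[key]}")

    adme = {**_DEFAULTS["adme"], **cfg.get("adme", {})}
    if adme["ob_min"] < 0:
        problems.append("adme: ob_min out of range (must be >= 0)")
    if not 0 <= adme["dl_min"] <= 1:
        problems.append("adme: dl_min out of range (must be in [0, 1])")

    mcode = {**_DEFAULTS["mcode"], **cfg.get("mcode", {})}
    if not 0 <= mcode["vwp"] < 1:
        problems.append("mcode: vwp out of range (must be in [0, 1))")
    if mcode["min_size"] < 2:
        problems.append("mcode: min_size out of range (must be >= 2)")

    enr = {**_DEFAULTS["enrichment"], **cfg.get("enrichment", {})}
    if not 0 < enr["alpha"] <= 1:
        problems.append("enrichment: alpha out of range (must be in (0, 1])")
    for key in ("top_go", "top_kegg"):
        if enr[key] < 1:
            problems.append(f"enrichment: {key} out of range (must be >= 1)")
    return problems


def _write_enrichment_tsv(results, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\tdescription\tk\tn\tK\tM\tratio\tp_raw\tp_adj\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.description}\t{r.k}\t{r.n}\t{r.K}\t{r.M}\t"
                f"{r.enrichment_ratio:.6g}\t{r.p_raw:.6g}\t{r.p_adj:.6g}\n"
            )


def run_pipeline(
    config: str | Path | dict, seed: int | None = None, quiet: bool = False
) -> dict:
    """Run the full analysis described by ``config``; returns the report.

    ``seed`` overrides the config's seed (relevant only with a
    ``simulation`` block, since the analysis itself is deterministic).
    """
    logging.basicConfig(level=logging.WARNING if quiet else logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")
    cfg = _load_config(config) if not isinstance(config, dict) else config
    problems = validate_config(cfg)
    if problems:
        raise ConfigurationError("invalid config: " + "; ".join(problems))

    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    effective_seed = int(seed if seed is not None else cfg.get("seed", 0))

    adme_cfg = {**_DEFAULTS["adme"], **cfg.get("adme", {})}
    screen_cfg = {**_DEFAULTS["screen"], **cfg.get("screen", {})}
    mcode_cfg = {**_DEFAULTS["mcode"], **cfg.get("mcode", {})}
    enr_cfg = {**_DEFAULTS["enrichment"], **cfg.get("enrichment", {})}

    report: dict[str, Any] = {
        "version": __version__,
        "seed": effective_seed,
        "thresholds": {"adme": adme_cfg, "screen": screen_cfg,
                       "mcode": mcode_cfg, "enrichment": enr_cfg},
        "stages": {},
        "networks": {},
    }

    def _run_stage(name, fn):
        log.info("stage %s", name)
        try:
            fn()
            report["stages"][name] = "ok"
            return True
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            log.error("stage %s failed: %s", name, exc)
            report["stages"][name] = f"failed: {exc}"
            return False

    state: dict[str, Any] = {}

    def stage_inputs():
        if "simulation" in cfg and cfg["simulation"] is not None:
            sim_cfg = SimulationConfig(seed=effective_seed, **cfg["simulation"])
            bundle = simulate_study(sim_cfg, outdir / "sim")
            state["paths"] = {
                "compounds": bundle.compounds,
                "associations": bundle.associations,
                "disease_genes": bundle.disease_genes,
                "background_ppi": bundle.background_ppi,
                "go_gmt": bundle.annotations,
                "kegg_gmt": bundle.annotations,
            }
        else:
            paths = dict(cfg["inputs"])
            paths.setdefault("kegg_gmt", paths["go_gmt"])
            state["paths"] = paths
        p = state["paths"]
        state["compounds"] = read_compound_table(p["compounds"])
        state["assoc"] = read_target_associations(p["associations"])
        state["disease"] = read_gene_list(p["disease_genes"], label="disease")
        state["background"] = read_edge_list(p["background_ppi"]).graph
        state["go"] = read_gmt(p["go_gmt"])
        state["kegg"] = read_gmt(p["kegg_gmt"])

    def stage_adme():
        thr = AdmeThresholds(**adme_cfg)
        active, rep = filter_active_compounds(state["compounds"], thr)
        state["active"] = active
        summary = screen_summary(rep)
        report["adme"] = {
            "n_total": summary.n_total, "n_active": summary.n_active,
            "n_failed_ob": summary.n_failed_ob, "n_failed_dl": summary.n_failed_dl,
            "n_failed_both": summary.n_failed_both,
        }
        write_compound_table(state["compounds"], outdir / "active_compounds.tsv")

    def stage_compound_target():
        build = build_compound_target_network(state["active"], state["assoc"])
        g = build.graph
        state["ct_graph"] = g
        state["compound_targets"] = {
            n for n in g.nodes if g.node_kind.get(n) == "gene"
        }
        n_compounds = sum(1 for n in g.nodes if g.node_kind.get(n) == "compound")
        report["networks"]["compound_target"] = {
            "n_nodes": g.n_nodes, "n_edges": g.n_edges,
            "n_compounds": n_compounds,
            "n_targets": g.n_nodes - n_compounds,
            "n_dropped_associations": build.n_dropped_associations,
        }
        write_graph(g, outdir / "compound_target.sif", format="sif")

    def stage_disease_ppi():
        induced = induced_ppi_subgraph(
            state["background"], state["disease"].genes, drop_isolated=True
        )
        state["disease_ppi"] = induced.graph
        report["networks"]["disease_ppi"] = {
            "n_nodes": induced.graph.n_nodes, "n_edges": induced.graph.n_edges,
            "n_seeds": len(state["disease"].genes),
            "n_missing_seeds": len(induced.missing_seeds),
        }
        write_graph(induced.graph, outdir / "disease_ppi.sif", format="sif")

    def stage_modules():
        params = McodeParams(**mcode_cfg)
        modules = mcode_find_modules(state["disease_ppi"], params)
        state["modules"] = modules
        report["modules"] = {
            "n_modules": len(modules),
            "top_score": round(modules[0].score, 6) if modules else None,
            "top_size": modules[0].n if modules else None,
        }
        payload = [
            {"nodes": sorted(m.nodes), "n_edges": m.n_edges,
             "density": round(m.density, 6), "score": round(m.score, 6),
             "seed": m.seed}
            for m in modules
        ]
        with open(outdir / "modules.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def stage_merge():
        merged = merge_target_networks(
            state["compound_targets"], state["disease"].genes, state["background"]
        )
        state["merged"] = merged
        shared = shared_targets(state["compound_targets"], state["disease"].genes)
        report["shared_targets"] = sorted(shared)
        prov_counts = {"compound": 0, "disease": 0, "shared": 0}
        for v in merged.provenance.values():
            prov_counts[v] += 1
        report["networks"]["merged"] = {
            "n_nodes": merged.graph.n_nodes, "n_edges": merged.graph.n_edges,
            "provenance": prov_counts,
        }
        write_graph(merged.graph, outdir / "merged_ppi.sif", format="sif")

    def stage_screen():
        table = centrality_table(state["merged"].graph)
        screening = screen_key_nodes(
            table, state["merged"].graph, strict=bool(screen_cfg["strict"])
        )
        state["screening"] = screening
        tsv = table.values.copy()
        tsv["passes_all"] = screening.passes.all(axis=1)
        tsv.to_csv(outdir / "centrality.tsv", sep="\t", float_format="%.10g")
        with open(outdir / "key_targets.txt", "w", encoding="utf-8") as fh:
            for n in screening.key_nodes:
                fh.write(n + "\n")
        write_graph(screening.central, outdir / "central.sif", format="sif")
        report["networks"]["central"] = {
            "n_nodes": screening.central.n_nodes,
            "n_edges": screening.central.n_edges,
        }
        report["key_targets"] = {
            "count": len(screening.key_nodes),
            "ec_converged": table.ec_converged,
        }

    def stage_enrichment():
        query = set(state["screening"].key_nodes)
        report["enrichment"] = {}
        for label, top_key in (("go", "top_go"), ("kegg", "top_kegg")):
            out_path = outdir / f"enrichment_{label}.tsv"
            if not query:
                _write_enrichment_tsv([], out_path)
                report["enrichment"][label] = {"n_tested": 0, "n_significant": 0}
                continue
            results = enrich_gene_set(
                query, state[label],
                ease=bool(enr_cfg["ease"]), adjust=str(enr_cfg["adjust"]) or "none",
            )
            top = select_top_terms(results, alpha=float(enr_cfg["alpha"]),
                                   top_k=int(enr_cfg[top_key]))
            _write_enrichment_tsv(top, out_path)
            report["enrichment"][label] = {
                "n_tested": len(results),
                "n_significant": sum(1 for r in results if r.p_raw < enr_cfg["alpha"]),
                "top_terms": [r.term_id for r in top],
            }

    stages = [
        ("inputs", stage_inputs),
        ("adme_screen", stage_adme),
        ("compound_target_network", stage_compound_target),
        ("disease_ppi", stage_disease_ppi),
        ("module_detection", stage_modules),
        ("merged_network", stage_merge),
        ("centrality_screen", stage_screen),
        ("enrichment", stage_enrichment),
    ]
    for name, fn in stages:
        if not _run_stage(name, fn):
            for later, _ in stages[stages.index((name, fn)) + 1:]:
                report["stages"][later] = "skipped"
            break

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
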