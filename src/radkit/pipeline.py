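"""Configuration-driven orchestration of the full comparative analysis.

``run_pipeline`` executes the study's stages in the published order --
net-diversification tables, birth-death model fitting, niche ordination,
trait models (Pagel signal, Mk selection, stochastic mapping), trait-
dependent diversification, geographic range metrics, and age-range
correlation -- on whatever inputs the config names.  Every stage writes
its artifacts into the output directory with a provenance block (inputs,
seeds, package versions); a stage that fails is recorded and skipped
without aborting the stages that do not depend on it.  ``make_report``
renders the collected outputs as one Markdown summary.
"""

from __future__ import annotations

import json
import math
import platform
import time
import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .trees import DatedTree, TreeSample, ltt

STAGES = ["netdiv", "diversification_ml", "ordination", "trait_models",
          "musse", "geography", "arc"]

__all__ = ["RunConfig", "run_pipeline", "make_report", "write_demo_bundle",
           "STAGES"]


@dataclass
class RunConfig:
    """Inputs, stage toggles and per-stage parameters for one run.

    All defaults mirror the published settings: epsilon in {0, 0.9},
    500 stochastic maps, 0.5-Myr shift bins, 1000 ARC iterations.  The
    MuSSE stage defaults to a reduced four-model roster so the full
    pipeline stays affordable on one CPU; pass
    ``musse: {full_roster: true}`` for all 17 models.
    """

    out_dir: str
    tree: Optional[str] = None           # newick, one dated tree
    trees: Optional[str] = None          # newick, posterior sample
    traits: Optional[str] = None         # CSV, species x mixed traits
    occurrences: Optional[str] = None    # CSV: species, x_km, y_km
    clades: Optional[str] = None         # CSV of CladeRecord columns
    stages: List[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    params: Dict[str, Dict[str, Any]] = field(default_factory=dict)

    def __post_init__(self):
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {STAGES}")
        for path in (self.tree, self.trees, self.traits,
                     self.occurrences, self.clades):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input missing: {path}")

    def stage_params(self, stage: str) -> Dict[str, Any]:
        return dict(self.params.get(stage, {}))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"out_dir", "tree", "trees", "traits", "occurrences",
                 "clades", "stages", "seed"}
        kwargs = {k: raw[k] for k in known if k in raw}
        params = {k: v for k, v in raw.items()
                  if k not in known and isinstance(v, dict)}
        if "out_dir" not in kwargs:
            raise ValueError("config must set out_dir")
        return cls(params=params, **kwargs)

    def to_yaml(self, path: str) -> None:
        import yaml
        doc: Dict[str, Any] = {"out_dir": self.out_dir,
                               "stages": self.stages, "seed": self.seed}
        for k in ("tree", "trees", "traits", "occurrences", "clades"):
            v = getattr(self, k)
            if v is not None:
                doc[k] = v
        doc.update(self.params)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# stage implementations (each returns a JSON-serialisable summary dict)


def _stage_netdiv(cfg: RunConfig, out: Path, ctx: Dict) -> Dict:
    from .netdiv import build_comparative_table, records_from_csv
    if cfg.clades is None:
        raise ValueError("netdiv stage needs the 'clades' CSV input")
    p = cfg.stage_params("netdiv")
    records = records_from_csv(cfg.clades)
    eps = tuple(p.get("eps_list", (0.0, 0.9)))
    norms = tuple(p.get("normalizations", ()))
    table = build_comparative_table(records, eps_list=eps,
                                    use_hpd=bool(p.get("use_hpd", False)),
                                    normalizations=norms)
    table.to_csv(out / "netdiv_table.tsv", sep="\t")
    ctx["netdiv_table"] = table
    return {"n_clades": len(table), "eps_list": list(eps),
            "artifact": "netdiv_table.tsv",
            "skipped_rows": table.attrs.get("skipped_normalisation", [])}


def _stage_diversification_ml(cfg: RunConfig, out: Path, ctx: Dict) -> Dict:
    from .birthdeath import fit_constant, fit_shift_model, model_select
    tree = ctx.get("tree")
    if tree is None:
        raise ValueError("diversification_ml stage needs the 'tree' input")
    p = cfg.stage_params("diversification_ml")
    fits = [fit_constant(tree, "yule"), fit_constant(tree, "bd")]
    for k in range(1, int(p.get("max_shifts", 1)) + 1):
        fits.append(fit_shift_model(tree, k,
                                    grid_step=float(p.get("grid_step", 0.5))))
    sel = model_select(fits)
    curve = ltt(tree)
    pd.DataFrame(sorted(curve.items()), columns=["age", "lineages"]
                 ).to_csv(out / "ltt.tsv", sep="\t", index=False)
    ctx["ltt"] = curve
    summary = {
        "best_model": sel["best"].model,
        "table": sel["table"],
        "lrt": sel["lrt"],
        "artifact": "ltt.tsv",
    }
    with open(out / "diversification.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    ctx["diversification"] = summary
    return summary


def _stage_ordination(cfg: RunConfig, out: Path, ctx: Dict) -> Dict:
    from .ordination import (hill_smith, retained_axes, assign_syndromes)
    if cfg.traits is None:
        raise ValueError("ordination stage needs the 'traits' CSV input")
    p = cfg.stage_params("ordination")
    df = pd.read_csv(cfg.traits, index_col=0)
    ordn = hill_smith(df)
    n_axes = retained_axes(ordn, float(p.get("threshold", 0.90)))
    k = int(p.get("k_syndromes", 3))
    syn = assign_syndromes(ordn, k=k, n_axes=n_axes, seed=cfg.seed)
    ordn.scores.to_csv(out / "ordination_scores.tsv", sep="\t")
    syn.labels.rename("syndrome").to_csv(out / "syndromes.tsv", sep="\t")
    ctx["ordination"] = ordn
    ctx["n_axes"] = n_axes
    ctx["syndromes"] = syn
    return {"n_axes_90": n_axes,
            "explained": [round(float(v), 4) for v in ordn.explained],
            "k_syndromes": k,
            "silhouette": syn.silhouette,
            "artifacts": ["ordination_scores.tsv", "syndromes.tsv"]}


def _stage_trait_models(cfg: RunConfig, out: Path, ctx: Dict) -> Dict:
    from .traits import (fit_mk, pagel_continuous, simmap_sample,
                         shift_histogram, multiaxis_signal)
    tree = ctx.get("tree")
    if tree is None:
        raise ValueError("trait_models stage needs the 'tree' input")
    if "syndromes" not in ctx or "ordination" not in ctx:
        raise ValueError("trait_models stage needs the ordination stage")
    p = cfg.stage_params("trait_models")
    ordn, syn = ctx["ordination"], ctx["syndromes"]
    n_axes = int(p.get("n_axes", ctx.get("n_axes", 2)))

    # phylogenetic signal on the retained axes, over the tree sample if
    # one was supplied, otherwise on the single tree
    trees = ctx.get("trees")
    sample = trees if trees is not None else TreeSample([tree])
    signal = {stat: multiaxis_signal(sample, ordn.scores, n_axes, stat)
              for stat in ("lambda", "kappa")}

    trait = syn.labels.astype(str)
    mk_rows = []
    best = None
    for pat in ("ER", "SYM", "ARD"):
        Q, logL, aicc = fit_mk(tree, trait, pat)
        mk_rows.append({"model": pat, "logL": logL, "AICc": aicc})
        if best is None or aicc < best[2]:
            best = (pat, Q, aicc)
    n_maps = int(p.get("n_maps", 500))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        maps = simmap_sample(tree, trait, best[1], n_maps=n_maps,
                             seed=cfg.seed)
    hist = shift_histogram(maps, bin_width=float(p.get("bin_width", 0.5)))
    hdf = pd.DataFrame({"bin_low": hist.bin_edges[:-1],
                        "bin_high": hist.bin_edges[1:],
                        "median": hist.median, "q05": hist.q05,
                        "q95": hist.q95})
    hdf.to_csv(out / "shift_histogram.tsv", sep="\t", index=False)
    ctx["shift_histogram"] = hdf
    summary = {"signal": signal,
               "mk_selection": mk_rows, "best_mk": best[0],
               "n_maps": n_maps,
               "mean_changes": float(np.mean([m.n_changes for m in maps])),
               "artifact": "shift_histogram.tsv"}
    with open(out / "trait_models.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary


def _stage_musse(cfg: RunConfig, out: Path, ctx: Dict) -> Dict:
    from .musse import enumerate_model_set, fit_musse, ModelConstraint
    tree = ctx.get("tree")
    if tree is None:
        raise ValueError("musse stage needs the 'tree' input")
    if "syndromes" not in ctx:
        raise ValueError("musse stage needs the ordination stage")
    p = cfg.stage_params("musse")
    trait = ctx["syndromes"].labels.astype(str)
    if bool(p.get("full_roster", False)):
        roster = enumerate_model_set(len(set(trait)))
    else:
        roster = [
            ModelConstraint("lam_shared.mu_zero.q_shared",
                            "shared", "zero", "shared"),
            ModelConstraint("lam_free.mu_zero.q_shared",
                            "free", "zero", "shared"),
            ModelConstraint("lam_shared.mu_shared.q_shared",
                            "shared", "shared", "shared"),
            ModelConstraint("lam_free.mu_shared.q_shared",
                            "free", "shared", "shared"),
        ]
    rows = []
    for c in roster:
        fit = fit_musse(tree, trait, c,
                        n_starts=int(p.get("n_starts", 2)), seed=cfg.seed)
        rows.append({"model": c.name, "k": fit.k, "logL": fit.logL,
                     "AICc": fit.AICc})
    tab = pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)
    tab["delta_AICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    tab.to_csv(out / "musse_selection.tsv", sep="\t", index=False)
    summary = {"best_model": tab["model"].iloc[0],
               "n_models": len(tab),
               "table": tab.to_dict(orient="records"),
               "artifact": "musse_selection.tsv"}
    with open(out / "musse.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary


def _stage_geography(cfg: RunConfig, out: Path, ctx: Dict) -> Dict:
    from .ranges import build_ranges, pair_metrics, pair_summary
    if cfg.occurrences is None:
        raise ValueError("geography stage needs the 'occurrences' input")
    p = cfg.stage_params("geography")
    occ = pd.read_csv(cfg.occurrences)
    ranges = build_ranges(occ, buffer_km=float(p.get("buffer_km", 0.5)))
    pm = pair_metrics(ranges)
    pm.to_tsv(str(out / "pairs.tsv"))
    areas = pd.Series({k: r.area for k, r in ranges.items()},
                      name="area_km2")
    areas.to_csv(out / "range_areas.tsv", sep="\t")
    ctx["pair_matrix"] = pm
    summary = {"n_species": len(ranges), **pair_summary(pm),
               "artifacts": ["pairs.tsv", "range_areas.tsv"]}
    with open(out / "geography.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary


def _stage_arc(cfg: RunConfig, out: Path, ctx: Dict) -> Dict:
    from .arc import mc_null, super_p
    if "pair_matrix" not in ctx:
        raise ValueError("arc stage needs the geography stage")
    tree, trees = ctx.get("tree"), ctx.get("trees")
    if tree is None and trees is None:
        raise ValueError("arc stage needs the 'tree' or 'trees' input")
    p = cfg.stage_params("arc")
    n_iter = int(p.get("n_iter", 1000))
    alpha = float(p.get("alpha", 0.05))
    pm = ctx["pair_matrix"]
    tree_list = list(trees) if trees is not None else [tree]
    out_metrics: Dict[str, Any] = {}
    nodal_frames = []
    for metric, M in (("overlap", pm.O), ("asymmetry", pm.A)):
        results = [mc_null(t, M, n_iter=n_iter, seed=cfg.seed + i)
                   for i, t in enumerate(tree_list)]
        r0 = results[0]
        nf = r0.nodal.copy()
        nf.insert(0, "metric", metric)
        nodal_frames.append(nf)
        out_metrics[metric] = {
            "slope": r0.slope, "intercept": r0.intercept,
            "p_value": r0.p_value, "n_iter": n_iter,
            "super_p": super_p(results, alpha=alpha),
            "n_trees": len(results),
        }
    pd.concat(nodal_frames).to_csv(out / "arc_nodal.tsv", sep="\t")
    summary = {"alpha": alpha, **out_metrics, "artifact": "arc_nodal.tsv"}
    with open(out / "arc.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    ctx["arc"] = summary
    return summary


_STAGE_FUNCS = {
    "netdiv": _stage_netdiv,
    "diversification_ml": _stage_diversification_ml,
    "ordination": _stage_ordination,
    "trait_models": _stage_trait_models,
    "musse": _stage_musse,
    "geography": _stage_geography,
    "arc": _stage_arc,
}


def run_pipeline(config: RunConfig) -> Dict[str, Any]:
    """Run the toggled stages in the canonical order; never let one
    stage's failure abort independent stages.  Returns the report bundle
    (per-stage summaries + provenance) and writes it, the Markdown
    report, and a machine-readable log under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ctx: Dict[str, Any] = {}
    if config.tree is not None:
        ctx["tree"] = DatedTree.from_newick(
            Path(config.tree).read_text().strip())
    if config.trees is not None:
        ctx["trees"] = TreeSample.from_file(config.trees)
        if "tree" not in ctx:
            ctx["tree"] = ctx["trees"][0]

    log: List[Dict[str, Any]] = []
    outputs: Dict[str, Any] = {}
    for stage in STAGES:
        if stage not in config.stages:
            outputs[stage] = {"status": "skipped"}
            continue
        t0 = time.time()
        entry = {"stage": stage,
                 "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
        try:
            summary = _STAGE_FUNCS[stage](config, out, ctx)
            outputs[stage] = {"status": "ok", **summary}
            entry["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - partial-failure tolerance
            outputs[stage] = {"status": "failed", "error": str(exc)}
            entry["status"] = "failed"
            entry["error"] = str(exc)
            entry["traceback"] = traceback.format_exc()
        entry["seconds"] = round(time.time() - t0, 3)
        log.append(entry)
        print(f"[{entry['started']}] {stage}: {entry['status']} "
              f"({entry['seconds']}s)")

    outputs["provenance"] = _provenance(config)
    with open(out / "report.json", "w") as fh:
        json.dump(outputs, fh, indent=1, default=str)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1)
    report_md = make_report(outputs, ctx)
    (out / "report.md").write_text(report_md)
    return outputs


def _provenance(config: RunConfig) -> Dict[str, Any]:
    import scipy
    import dendropy
    return {
        "seed": config.seed,
        "inputs": {k: getattr(config, k) for k in
                   ("tree", "trees", "traits", "occurrences", "clades")
                   if getattr(config, k) is not None},
        "stages": config.stages,
        "params": config.params,
        "versions": {"radkit": _pkg_version,
                     "numpy": np.__version__,
                     "scipy": scipy.__version__,
                     "pandas": pd.__version__,
                     "dendropy": dendropy.__version__,
                     "python": platform.python_version()},
    }


def _md_table(rows: List[Dict[str, Any]], cols: List[str]) -> str:
    def fmt(v):
        if isinstance(v, float):
            return f"{v:.4g}"
        return str(v)
    head = "| " + " | ".join(cols) + " |"
    sep = "| " + " | ".join("---" for _ in cols) + " |"
    body = ["| " + " | ".join(fmt(r.get(c, "")) for c in cols) + " |"
            for r in rows]
    return "\n".join([head, sep, *body])


def make_report(outputs: Dict[str, Any],
                ctx: Dict[str, Any] | None = None) -> str:
    """Render the pipeline outputs as one Markdown document.  Stages that
    were skipped or failed get a one-line section; regeneration from the
    same outputs dict is byte-identical."""
    ctx = ctx or {}
    lines = ["# Radiation analysis report", ""]
    prov = outputs.get("provenance", {})
    if prov:
        lines += ["## Provenance", "",
                  f"- seed: {prov.get('seed')}",
                  f"- inputs: {json.dumps(prov.get('inputs', {}))}",
                  f"- versions: {json.dumps(prov.get('versions', {}))}", ""]

    def section(title, stage):
        st = outputs.get(stage, {}).get("status", "absent")
        lines.append(f"## {title}")
        lines.append("")
        if st != "ok":
            reason = outputs.get(stage, {}).get("error", "")
            lines.append(f"*{st}*" + (f": {reason}" if reason else ""))
            lines.append("")
            return None
        return outputs[stage]

    s = section("Net diversification", "netdiv")
    if s:
        lines += [f"{s['n_clades']} clades at epsilon = {s['eps_list']}; "
                  f"table in `{s['artifact']}`.", ""]

    s = section("Diversification models (ML)", "diversification_ml")
    if s:
        lines += [f"Best model: **{s['best_model']}**", "",
                  _md_table(s["table"],
                            [c for c in s["table"][0].keys()]), ""]
        if "ltt" in ctx:
            items = sorted(ctx["ltt"].items())
            lines += ["", "Lineages through time:",
                      "", _md_table([{"age": a, "lineages": k}
                                     for a, k in items],
                                    ["age", "lineages"]), ""]

    s = section("Niche ordination", "ordination")
    if s:
        lines += [f"{s['n_axes_90']} axes reach 90% of inertia; "
                  f"{s['k_syndromes']} syndromes "
                  f"(silhouette {s['silhouette']}).", ""]

    s = section("Trait models", "trait_models")
    if s:
        lines += [f"Best Mk model: **{s['best_mk']}**; "
                  f"{s['n_maps']} stochastic maps, mean "
                  f"{s['mean_changes']:.2f} changes per map.", "",
                  _md_table(s["mk_selection"], ["model", "logL", "AICc"]),
                  ""]
        if "shift_histogram" in ctx:
            h = ctx["shift_histogram"]
            lines += ["", "Shift histogram (changes per 0.5-Myr bin):", "",
                      _md_table(h.to_dict(orient="records"),
                                list(h.columns)), ""]

    s = section("Trait-dependent diversification", "musse")
    if s:
        lines += [f"Best model: **{s['best_model']}** of {s['n_models']}.",
                  "", _md_table(s["table"],
                                ["model", "k", "logL", "AICc",
                                 "delta_AICc"]), ""]

    s = section("Geography", "geography")
    if s:
        lines += [f"{s['n_species']} species; mean pairwise overlap "
                  f"{s['mean_overlap']:.3f} (sd {s['sd_overlap']:.3f}), "
                  f"{s['n_overlapping']} of {s['n_pairs']} pairs "
                  "overlapping.", ""]

    s = section("Age-range correlation", "arc")
    if s:
        rows = [{"metric": m, **s[m]} for m in ("overlap", "asymmetry")
                if m in s]
        lines += [_md_table(rows, ["metric", "slope", "p_value",
                                   "super_p", "n_trees"]), ""]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# demo bundle


def write_demo_bundle(directory: str, seed: int = 0,
                      n_tips: int = 24) -> RunConfig:
    """Generate the synthetic demo inputs (tree, posterior sample, mixed
    traits, occurrences, clade table) under ``directory`` and return a
    ready-to-run config writing into ``directory``/out."""
    from .simulate import (simulate_bd, simulate_tree_sample, simulate_mk,
                           simulate_mixed_traits, simulate_ranges_on_tree)
    from .qmatrix import QMatrix
    from .datasets import nc_radiations, NC_OXERA

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    tree, _ = simulate_bd(0.575, 0.0, n_tips=n_tips, seed=seed)
    (d / "tree.nwk").write_text(tree.to_newick() + "\n")
    sample, _ = simulate_tree_sample(tree, n_trees=5, jitter=0.1,
                                     seed=seed + 1)
    sample.write(str(d / "trees.nwk"))

    labels = tree.tip_labels
    # plant syndromes that evolve on the tree, so downstream trait models
    # see phylogenetically structured variation
    syn_trait, _ = simulate_mk(tree, QMatrix.er(("0", "1", "2"), 0.25),
                               seed=seed + 5)
    smap = {lab: int(syn_trait[lab]) for lab in labels}
    table, _ = simulate_mixed_traits(labels, n_quant=4, n_qual=3,
                                     syndrome_map=smap, seed=seed + 2)
    table.to_csv(d / "traits.csv")

    ranges, _ = simulate_ranges_on_tree(tree, seed=seed + 3)
    rows = []
    rng = np.random.default_rng(seed + 4)
    for lab, r in ranges.items():
        minx, miny, maxx, maxy = r.geometry.bounds
        pts = []
        while len(pts) < 6:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            from shapely.geometry import Point
            if r.geometry.contains(Point(x, y)):
                pts.append((x, y))
        rows += [{"species": lab, "x_km": x, "y_km": y} for x, y in pts]
    pd.DataFrame(rows).to_csv(d / "occurrences.csv", index=False)

    recs = nc_radiations()
    clade_rows = []
    for r in recs:
        clade_rows.append({"clade": r.clade, "n": r.n,
                           "stem_age": r.stem_age, "crown_age": r.crown_age,
                           "crown_low": r.crown_low,
                           "crown_high": r.crown_high,
                           "area_km2": r.area_km2 or NC_OXERA.area_km2})
    pd.DataFrame(clade_rows).to_csv(d / "clades.csv", index=False)

    cfg = RunConfig(
        out_dir=str(d / "out"),
        tree=str(d / "tree.nwk"),
        trees=str(d / "trees.nwk"),
        traits=str(d / "traits.csv"),
        occurrences=str(d / "occurrences.csv"),
        clades=str(d / "clades.csv"),
        seed=seed,
        params={"trait_models": {"n_maps": 200},
                "arc": {"n_iter": 500}},
    )
    cfg.to_yaml(str(d / "config.yml"))
    return cfg
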