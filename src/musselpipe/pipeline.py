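"""End-to-end pipeline: validate -> diversity -> differentiation -> hybrids
-> environment association, driven by a YAML/dict config; deterministic
under a fixed seed."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import DataError, annotation_map

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "musselpipe_out",
    "scenario": "default",          # or dict of input paths
    "n_perm": 200,                  # permutation replicates for FST p-values
    "ld": {"enabled": False, "population": None, "n_perm": 200},
    "outliers": {"enabled": True, "n_sim": 3000},
    "brt": {
        "learning_rate": 0.05,
        "max_trees": 300,
        "cv_folds": 5,
        "tree_depth": 2,
        "bag_fraction": 0.5,
        "min_node_size": 5,
        "min_trees_guideline": 50,
        "max_loci": 12,             # cap on per-locus models per run
    },
    "envassoc_enabled": True,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    return _merge(DEFAULT_CONFIG, user)


def _load_inputs(cfg, seed):
    from . import io as mio
    from . import synthdata

    sc = cfg["scenario"]
    if sc == "default":
        sites, clines, profiles = synthdata.default_scenario(seed=seed)
        gm, ann, env, truth = synthdata.generate_study(
            sites, clines, profiles, seed=seed
        )
        refs = synthdata.reference_pops(sites)
        return gm, ann, env, truth, refs
    if not isinstance(sc, dict):
        raise DataError(f"unknown scenario {sc!r}")
    if cfg.get("envassoc_enabled") and "environment" not in sc:
        raise DataError(
            "config error: envassoc is enabled but scenario lacks the "
            "'environment' table field"
        )
    if "genepop" in sc:
        gm = mio.read_genepop(sc["genepop"])
    elif "csv" in sc:
        gm = mio.read_csv_genotypes(sc["csv"])
    else:
        raise DataError("scenario must name a 'genepop' or 'csv' genotype input")
    ann = mio.read_annotation(sc["annotation"]) if "annotation" in sc else None
    env = None
    if "environment" in sc:
        env = mio.read_env_table(sc["environment"])
    elif cfg.get("envassoc_enabled"):
        raise DataError(
            "config error: envassoc is enabled but scenario lacks the "
            "'environment' table field"
        )
    refs = sc.get("reference_pops") or {}
    return gm, ann, env, None, refs


def run_pipeline(config) -> dict:
    """Execute the full analysis chain and write all artifacts.

    Returns a manifest dict (stage -> artifact paths / headline numbers).
    Reruns with the same config and seed produce identical outputs.
    """
    from . import differentiation as diff
    from . import envassoc as ea
    from . import hybrids as hyb
    from . import io as mio
    from . import popstats
    from .brt import BRTConfig

    cfg = load_config(config)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log: list[dict] = []
    manifest: dict = {"version": __version__, "seed": seed, "outdir": str(outdir)}

    def stage(name):
        def deco(fn):
            t = time.time()
            try:
                fn()
            except Exception as exc:  # noqa: BLE001
                raise DataError(f"stage {name!r} failed: {exc}") from exc
            log.append({"stage": name, "seconds": round(time.time() - t, 3)})
        return deco

    gm, ann, env, truth, refs = _load_inputs(cfg, seed)

    @stage("simulate/load")
    def _write_inputs():
        mio.write_genepop(gm, outdir / "genotypes.gen")
        mio.write_csv_genotypes(gm, outdir / "genotypes.csv")
        if ann is not None:
            mio.write_annotation(ann, outdir / "annotation.tsv")
        if env is not None:
            mio.write_env_table(env, outdir / "environment.tsv")
        if truth is not None:
            from .synthdata import write_truth

            write_truth(truth, outdir / "truth.json")

    @stage("validate")
    def _validate():
        rep = mio.validate_dataset(gm, ann, env)
        (outdir / "validation.json").write_text(
            json.dumps(
                {
                    "ok": rep.ok,
                    "issues": rep.issues,
                    "warnings": rep.warnings,
                    "per_population_n": rep.per_population_n,
                },
                indent=1,
                sort_keys=True,
            )
        )
        if not rep.ok:
            raise DataError("; ".join(rep.issues))

    @stage("diversity")
    def _diversity():
        table = popstats.diversity_table(gm)
        table.to_csv(outdir / "diversity.tsv", sep="\t")
        manifest["diversity"] = str(outdir / "diversity.tsv")

    fstm = {}

    @stage("fst")
    def _fst():
        m = diff.pairwise_fst(gm, n_perm=int(cfg["n_perm"]), seed=seed)
        fstm["m"] = m
        m.theta.to_csv(outdir / "fst_matrix.tsv", sep="\t")
        m.pvalues.to_csv(outdir / "fst_pvalues.tsv", sep="\t")
        m.per_locus.to_csv(outdir / "fst_per_locus.tsv", sep="\t", header=["fst"])
        manifest["multilocus_fst"] = m.multilocus

    @stage("outliers")
    def _outliers():
        if not cfg["outliers"]["enabled"]:
            return
        scan = diff.fst_outlier_scan(
            gm, n_sim=int(cfg["outliers"]["n_sim"]), seed=seed
        )
        if not scan.skipped:
            scan.table.to_csv(outdir / "fst_outliers.tsv", sep="\t")
            manifest["n_fst_outliers"] = int(scan.table["outlier"].sum())

    @stage("ld")
    def _ld():
        opts = cfg["ld"]
        if not opts.get("enabled"):
            return
        pop = opts.get("population") or gm.pop_codes[0]
        table = diff.ld_scan(gm, pop, n_perm=int(opts["n_perm"]), seed=seed)
        table.to_csv(outdir / "ld.tsv", sep="\t", index=False)
        manifest["n_ld_pairs"] = len(table)

    @stage("tree")
    def _tree():
        newick = diff.nj_tree(fstm["m"].distance_matrix())
        (outdir / "nj_tree.nwk").write_text(newick + "\n")
        manifest["tree"] = str(outdir / "nj_tree.nwk")

    @stage("ca")
    def _ca():
        ca = diff.correspondence_analysis(diff.pop_allele_count_table(gm))
        ca.row_coords.to_csv(outdir / "ca_coordinates.tsv", sep="\t")
        manifest["ca_inertia_pct_axis12"] = float(ca.inertia_pct[:2].sum())

    @stage("hybrids")
    def _hybrids():
        if len(refs) < 3:
            logger.info("fewer than 3 reference taxa: hybrid stage limited")
        if "trossulus" in refs and "edulis" in refs and "galloprovincialis" in refs:
            panel = hyb.select_diagnostic_panel(gm, refs, "trossulus")
            hi = hyb.hybrid_index(gm, panel)
            hi.per_population.to_csv(outdir / "hybrid_index.tsv", sep="\t")
            post = hyb.assign_hybrid_classes(
                gm, refs["trossulus"], refs["edulis"], loci=panel.loci
            )
            report = post.population_report(gm)
            merged = hi.per_population.join(report)
            merged.to_csv(outdir / "hybrid_table.tsv", sep="\t")
            manifest["panel_size"] = len(panel)
            cf = hyb.cluster_freqs_from_references(
                gm, {t: refs[t] for t in ("trossulus", "edulis")}
            )
            anc = hyb.supervised_ancestry(gm, cf, focal_cluster="trossulus")
            anc.q.join(anc.classification).to_csv(outdir / "ancestry_q.tsv", sep="\t")

    @stage("envassoc")
    def _envassoc():
        if not cfg["envassoc_enabled"] or env is None:
            return
        screen = ea.collinearity_screen(env)
        screen.r.to_csv(outdir / "collinearity.tsv", sep="\t")
        brt_cfg = dict(cfg["brt"])
        max_loci = int(brt_cfg.pop("max_loci"))
        bc = BRTConfig(seed=seed, **brt_cfg)
        amap = annotation_map(ann) if ann is not None else {}
        loci = list(gm.loci)
        if len(loci) > max_loci:
            # prefer a balanced mix of diagnostic and other loci
            diag = [l for l in loci if amap.get(l) and amap[l].diagnostic_for]
            rest = [l for l in loci if l not in diag]
            half = max_loci // 2
            loci = diag[:half] + rest[: max_loci - min(half, len(diag))]
        summaries = ea.per_locus_models(
            gm, env, config=bc, loci=loci, annotation_map=amap
        )
        rows = []
        for s in summaries:
            row = {"locus": s.locus, "loss": s.loss, "n_trees": s.n_trees,
                   "pseudo_r2": s.pseudo_r2, "region_class": s.region_class}
            row.update({f"infl_{k}": v for k, v in s.influence.items()})
            for var, iv in s.transitions.items():
                row[f"transition_{var}"] = "" if iv is None else f"{iv[0]:.2f}-{iv[1]:.2f}"
            rows.append(row)
        pd.DataFrame(rows).to_csv(outdir / "brt_models.tsv", sep="\t", index=False)
        manifest["brt_summary"] = ea.model_summary_stats(summaries)
        with_class = [s for s in summaries if s.region_class]
        groups = {s.region_class for s in with_class}
        counts_ok = all(
            sum(1 for s in with_class if s.region_class == g) >= 2 for g in groups
        )
        if len(groups) == 2 and counts_ok:
            comp = ea.coding_noncoding_comparison(summaries, seed=seed)
            comp.simper_table.to_csv(outdir / "simper.tsv", sep="\t")
            manifest["anosim"] = {"R": comp.anosim_r, "p": comp.p_value}

    log.append({"stage": "total", "seconds": round(time.time() - t0, 3)})
    manifest["log"] = log
    (outdir / "run_log.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def output_hash(outdir) -> str:
    """Stable hash over all text artifacts of a run (idempotence checks)."""
    h = hashlib.sha256()
    for p in sorted(Path(outdir).glob("*")):
        if p.name == "run_log.json":  # contains wall-clock timings
            continue
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()
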