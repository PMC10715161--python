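"""End-to-end orchestration: aggregate -> rarefy -> enterotype ->
diversity -> network -> assembly -> contrasts, with a manifest that makes
every run bit-reproducible.

A run is a pure function of (inputs, config, seed): the manifest written
at the start of each run snapshots the fully resolved config, and
re-running from that snapshot reproduces all outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assembly as asb
from . import diversity as div
from . import enterotypes as ent
from . import groupstats as gs
from . import io as eio
from . import network as net
from .containers import ConfigError
from .simulate import (ScenarioConfig, load_preset, simulate_enterotype_dataset,
                       yule_tree)

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline", "subset_runs", "load_config"]

_STAGES = ("enterotype", "diversity", "network", "assembly", "contrasts")


def default_config() -> dict:
    """The default synthetic study scenario: two seasons x two altitude
    classes, K=3 enterotypes, all stages on."""
    return {
        "seed": 0,
        "simulate": {"preset": "bacterial_like"},
        "stages": {s: True for s in _STAGES},
        "rarefy": {"depth": None},
        "enterotype": {"k_min": 2, "k_max": 6, "alpha": 0.05},
        "diversity": {"n_perm": 999, "shannon_base": None},
        "network": {"min_total_rel_abund": 0.005, "corr_method": "spearman",
                    "r_threshold": 0.7, "p_threshold": 0.05},
        "assembly": {"n_null": 999, "ci_level": 0.95},
        "contrasts": {"factors": ["season", "altitude_class"],
                      "variables": ["shannon", "body_temp_C", "rmr",
                                    "mass_g", "rmr_per_mass"]},
        "subsets": False,
    }


def load_config(source) -> dict:
    """Load and validate a config (dict or YAML path); every schema
    violation is collected and reported at once."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source or {})
    cfg = default_config()
    errors = []
    for key, val in user.items():
        if key in ("inputs", "simulate"):
            continue
        if key not in cfg:
            errors.append(f"unknown config section {key!r}")
        elif isinstance(cfg[key], dict) and isinstance(val, dict):
            for k2, v2 in val.items():
                if k2 not in cfg[key] and key not in ("simulate",):
                    errors.append(f"unknown key {key}.{k2}")
                else:
                    cfg[key][k2] = v2
        else:
            cfg[key] = val
    if "simulate" in user:
        cfg["simulate"] = user["simulate"]
    if user.get("inputs"):
        cfg["inputs"] = user["inputs"]
        cfg.pop("simulate", None)
    if not isinstance(cfg.get("seed"), int):
        errors.append("seed must be an integer")
    for s, on in cfg["stages"].items():
        if s not in _STAGES:
            errors.append(f"unknown stage {s!r}")
        if not isinstance(on, bool):
            errors.append(f"stages.{s} must be boolean")
    if "inputs" in cfg:
        for k in ("feature_table", "metadata"):
            if k not in cfg["inputs"]:
                errors.append(f"inputs.{k} is required when not simulating")
    if errors:
        raise ConfigError("invalid config:\n  - " + "\n  - ".join(errors))
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def _load_inputs(cfg: dict, seed: int):
    """Return (asv_table, tree_or_None, metadata, true_labels_or_None)."""
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        taxonomy = (eio.read_taxonomy(inputs["taxonomy"])
                    if inputs.get("taxonomy") else None)
        table = eio.read_feature_table(inputs["feature_table"],
                                       taxonomy=taxonomy)
        tree = eio.read_tree(inputs["tree"]) if inputs.get("tree") else None
        metadata = eio.read_metadata(inputs["metadata"])
        return table, tree, metadata, None
    sim = dict(cfg.get("simulate") or {})
    preset = sim.pop("preset", None)
    if preset:
        scen = load_preset(preset)
        for k, v in sim.items():
            setattr(scen, k, v)
        scen = ScenarioConfig.from_dict(scen.to_dict())
    else:
        scen = ScenarioConfig.from_dict(sim)
    table, labels, metadata = simulate_enterotype_dataset(scen, seed=seed)
    tree = yule_tree(scen.n_taxa, scen.tree_birth_rate, seed=seed + 2)
    for tip, name in zip(tree.tips(), table.taxon_ids):
        tip.name = name
    return table, tree, metadata, labels


def run_pipeline(config, outdir, seed: int | None = None) -> Path:
    """Execute the configured stages in order and write all outputs under
    ``outdir``. Returns the output directory path."""
    cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = cfg["seed"]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]

    manifest = {
        "software": {"name": "enteroeco", "version": __version__},
        "config": cfg,
        "seeds": {"master": seed, "rarefy": seed + 10, "permanova": seed + 11,
                  "ses_mntd": seed + 12, "kmeans": seed + 13},
        "input_checksums": {},
    }
    if "inputs" in cfg:
        manifest["input_checksums"] = {
            k: _sha256(v) for k, v in cfg["inputs"].items() if v}
    _write_json(manifest, outdir / "manifest.json")

    table, tree, metadata, true_labels = _load_inputs(cfg, seed)
    report: list[str] = ["# Pipeline report", ""]
    report.append(f"Samples: {table.n_samples}; taxa: {table.n_taxa}.")

    # rarefy, then aggregate to genus when a taxonomy map is present
    rarefied = eio.rarefy(table, depth=cfg["rarefy"]["depth"],
                          seed=manifest["seeds"]["rarefy"])
    report.append(f"Rarefied to depth {int(rarefied.sample_sums().iloc[0])}; "
                  f"{rarefied.n_samples} samples retained.")
    if table.taxonomy is not None:
        genus = eio.aggregate_taxa(rarefied, rank="genus")
        report.append(f"Aggregated to {genus.n_taxa} genera "
                      "(aggregation after rarefaction).")
    else:
        genus = rarefied
    metadata = metadata.loc[rarefied.sample_ids]
    rel_genus = eio.to_relative(genus)

    model = None
    if stages["enterotype"]:
        ecfg = cfg["enterotype"]
        jsd = ent.jsd_matrix(rel_genus)
        k_range = range(ecfg["k_min"],
                        min(ecfg["k_max"], rel_genus.n_samples - 1) + 1)
        model = ent.select_k(jsd, k_range)
        wss, elbow = ent.kmeans_wss_curve(jsd, k_range,
                                          seed=manifest["seeds"]["kmeans"])
        model.wss_scores, model.elbow_k = wss, elbow
        model.drivers = ent.driver_taxa(rel_genus, model.assignments,
                                        alpha=ecfg["alpha"])
        edir = outdir / "enterotype"
        edir.mkdir(exist_ok=True)
        model.assignments.rename("enterotype").to_frame().to_csv(
            edir / "assignments.tsv", sep="\t", index_label="sample_id")
        _write_json(model.to_dict(), edir / "model.json")
        report += ["", "## Enterotypes",
                   f"Chosen k = {model.chosen_k} by the CH index "
                   f"(k-means elbow at k = {elbow}).",
                   f"Cluster sizes: {model.cluster_sizes().to_dict()}."]
        if model.small_clusters:
            report.append(f"Clusters below {ent.MIN_CLUSTER_SIZE} samples "
                          f"(excluded from group statistics): "
                          f"{model.small_clusters}.")
        for c, lst in (model.drivers or {}).items():
            names = ", ".join(g for g, _, _ in lst) or "(undetermined)"
            report.append(f"- enterotype {c} drivers: {names}")
        if true_labels is not None:
            from sklearn.metrics import adjusted_rand_score
            ari = adjusted_rand_score(true_labels.loc[model.assignments.index],
                                      model.assignments)
            report.append(f"Adjusted Rand index vs planted labels: {ari:.3f}.")

    if stages["diversity"]:
        dcfg = cfg["diversity"]
        ddir = outdir / "diversity"
        ddir.mkdir(exist_ok=True)
        alpha = div.alpha_diversity(rarefied, base=dcfg["shannon_base"])
        alpha.to_csv(ddir / "alpha.tsv", sep="\t")
        bc = div.bray_curtis_matrix(rarefied)
        ord_res = div.pcoa(bc, n_axes=min(10, rarefied.n_samples - 1))
        coords = ord_res.coordinates.copy()
        coords.to_csv(ddir / "pcoa_coordinates.tsv", sep="\t",
                      index_label="sample_id")
        _write_json({"eigenvalues": list(ord_res.eigenvalues),
                     "proportion_explained": list(ord_res.proportion_explained),
                     "shannon_base": dcfg["shannon_base"] or "e"},
                    ddir / "ordination.json")
        report += ["", "## Diversity",
                   f"Mean Shannon {alpha['shannon'].mean():.3f}, "
                   f"mean Chao1 {alpha['chao1'].mean():.1f}."]
        if model is not None:
            perma = div.permanova(bc, model.assignments, n_perm=dcfg["n_perm"],
                                  seed=manifest["seeds"]["permanova"])
            _write_json(perma.to_dict(), ddir / "permanova.json")
            report.append(
                f"PERMANOVA between enterotypes: pseudo-F = "
                f"{perma.statistic:.2f}, R^2 = {perma.effect_size:.3f}, "
                f"p = {perma.p_value:.4g}.")

    if stages["network"] and model is not None:
        ncfg = cfg["network"]
        ndir = outdir / "network"
        ndir.mkdir(exist_ok=True)
        report += ["", "## Co-occurrence networks"]
        all_metrics = {}
        for c in sorted(model.assignments.unique()):
            members = model.assignments.index[model.assignments == c]
            if len(members) < 5 or int(c) in model.small_clusters:
                continue
            sub = rarefied.subset_samples(members)
            network = net.build_network(sub, **ncfg)
            metrics = net.network_metrics(network)
            if network.graph.number_of_edges() >= 1:
                membership, q = net.detect_modules(network)
                metrics["modularity"] = q
                metrics["n_modules"] = len(set(membership.values()))
            net.edge_table(network).to_csv(
                ndir / f"edges_enterotype{c}.tsv", sep="\t", index=False)
            all_metrics[int(c)] = metrics
            report.append(
                f"- enterotype {c}: {metrics['n_nodes']} nodes, "
                f"{metrics['n_edges']} edges, "
                f"Q = {metrics.get('modularity', float('nan')):.3f}")
        _write_json(all_metrics, ndir / "metrics.json")

    if stages["assembly"]:
        if tree is None:
            report += ["", "## Assembly", "Skipped: no phylogenetic tree input."]
            logger.warning("assembly stage skipped: no tree provided")
        else:
            acfg = cfg["assembly"]
            adir = outdir / "assembly"
            adir.mkdir(exist_ok=True)
            phylo = eio.cophenetic_matrix(tree)
            ses = asb.ses_mntd(rarefied, phylo, n_null=acfg["n_null"],
                               seed=manifest["seeds"]["ses_mntd"])
            ses.to_csv(adir / "ses_mntd.tsv", sep="\t", index=False)
            report += ["", "## Community assembly"]
            groups = ({int(c): model.assignments.index[model.assignments == c]
                       for c in sorted(model.assignments.unique())}
                      if model is not None else {0: rarefied.sample_ids})
            neutral_out = {}
            for c, members in groups.items():
                if len(members) < 5:
                    continue
                props = asb.classify_assembly(ses.loc[ses.index.isin(members)])
                try:
                    fit = asb.fit_neutral_model(
                        rarefied.subset_samples(members),
                        ci_level=acfg["ci_level"])
                    neutral_out[c] = fit.to_dict()
                    fit.taxa.to_csv(adir / f"neutral_taxa_enterotype{c}.tsv",
                                    sep="\t")
                    report.append(
                        f"- enterotype {c}: ses.MNTD clustered "
                        f"{props['clustered']:.0%}, random {props['random']:.0%}; "
                        f"neutral fit R^2 = {fit.r_squared:.3f}, "
                        f"Nm = {fit.Nm:.0f}")
                except ConfigError as exc:
                    report.append(f"- enterotype {c}: neutral fit skipped ({exc})")
                neutral_out.setdefault(c, {})["ses_proportions"] = props
            _write_json(neutral_out, adir / "neutral_fits.json")

    if stages["contrasts"] and model is not None:
        ccfg = cfg["contrasts"]
        cdir = outdir / "contrasts"
        cdir.mkdir(exist_ok=True)
        report += ["", "## Group contrasts"]
        rows = []
        variables = dict(metadata[[v for v in ccfg["variables"]
                                   if v in metadata.columns]])
        if stages["diversity"]:
            alpha = div.alpha_diversity(rarefied, base=cfg["diversity"]["shannon_base"])
            for v in ("shannon", "chao1"):
                if v in ccfg["variables"]:
                    variables[v] = alpha[v]
        for name, series in variables.items():
            res = gs.compare_groups(series.loc[model.assignments.index],
                                    model.assignments)
            rows.append({"variable": name, "grouping": "enterotype",
                         "method": res.method, "statistic": res.statistic,
                         "p_value": res.p_value, "note": res.note})
        pd.DataFrame(rows).to_csv(cdir / "contrasts.tsv", sep="\t", index=False)
        for factor in ccfg["factors"]:
            if factor not in metadata.columns:
                continue
            tab, res, props = gs.enterotype_distribution(model.assignments,
                                                         metadata, factor)
            tab.to_csv(cdir / f"contingency_{factor}.tsv", sep="\t")
            _write_json(res.to_dict(), cdir / f"chi2_{factor}.json")
            report.append(f"### Enterotype x {factor}")
            report.append(tab.to_markdown())
            report.append(f"chi-square = {res.statistic:.2f}, "
                          f"df = {res.df}, p = {res.p_value:.4g}")
        sig = [r for r in rows if r["p_value"] == r["p_value"]
               and r["p_value"] < 0.05]
        report.append(f"{len(sig)} of {len(rows)} physiology/diversity "
                      "contrasts significant at 0.05: "
                      + ", ".join(r["variable"] for r in sig))

    report += ["", "## Parameter decisions in force",
               f"- Shannon log base: {cfg['diversity']['shannon_base'] or 'e'}",
               f"- PERMANOVA permutations: {cfg['diversity']['n_perm']}",
               f"- ses.MNTD null replicates: {cfg['assembly']['n_null']}",
               f"- network correlation: {cfg['network']['corr_method']} "
               f"(|r| > {cfg['network']['r_threshold']}, "
               f"p < {cfg['network']['p_threshold']})",
               f"- seeds: {manifest['seeds']}"]
    (outdir / "report.md").write_text("\n".join(report) + "\n", encoding="utf-8")

    if cfg["subsets"]:
        subset_runs(cfg, outdir, rarefied, metadata, model, tree)
    return outdir


def subset_runs(cfg: dict, outdir: Path, rarefied, metadata, model, tree) -> None:
    """Re-run the enabled downstream stages on the season and altitude
    subsets, carrying the total-run enterotype assignments.

    Enterotypes are fit once on the total dataset; subsets reuse those
    assignments (a per-subset re-clustering is deliberately not the
    default). Subsets failing minimum sizes are skipped with a warning.
    """
    outdir = Path(outdir)
    subsets = {
        "warm": metadata.index[metadata["season"] == "warm"],
        "cold": metadata.index[metadata["season"] == "cold"],
        "low": metadata.index[metadata["altitude_class"] == "low"],
        "high": metadata.index[metadata["altitude_class"] == "high"],
    }
    seed = cfg["seed"]
    for name, members in subsets.items():
        sdir = outdir / "subsets" / name
        if len(members) < 10:
            logger.warning("subset %s skipped: only %d samples", name,
                           len(members))
            continue
        sdir.mkdir(parents=True, exist_ok=True)
        sub = rarefied.subset_samples(members)
        lab = model.assignments.loc[members] if model is not None else None
        summary: dict = {"n_samples": len(members)}
        if lab is not None:
            sizes = lab.value_counts()
            summary["enterotype_sizes"] = {int(k): int(v)
                                           for k, v in sizes.items()}
            usable = sizes[sizes >= ent.MIN_CLUSTER_SIZE]
            if len(usable) >= 2:
                keep = lab[lab.isin(usable.index)]
                bc = div.bray_curtis_matrix(sub.subset_samples(keep.index))
                perma = div.permanova(bc, keep,
                                      n_perm=cfg["diversity"]["n_perm"],
                                      seed=seed + 11)
                summary["permanova"] = perma.to_dict()
                alpha = div.alpha_diversity(sub.subset_samples(keep.index))
                res = gs.compare_groups(alpha["shannon"], keep)
                summary["shannon_contrast"] = res.to_dict()
            else:
                summary["note"] = ("fewer than 2 enterotypes of usable size; "
                                   "contrasts skipped")
        _write_json(summary, sdir / "summary.json")


def rerun_from_manifest(manifest_path, outdir) -> Path:
    """Re-execute a run from its manifest snapshot (bit-identical outputs)."""
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    return run_pipeline(manifest["config"], outdir)
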