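"""End-to-end orchestration: counts -> normalization -> DE -> RC-miR network
-> targets/enrichment -> qPCR, driven by one YAML config.

Every stage writes plain-text outputs (TSV/JSON) into the output directory
and the run closes with a manifest (seed, config hash, file list) so that an
identical config and seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import counts as counts_mod
from . import diffexpr, network, qpcr, simulate, targets


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


DEFAULTS = {
    "de_alpha": 0.05,
    "nbins": None,  # floor(sqrt(n_samples)), min 2
    "tau_step": 0.01,
    "blocks": ["over", "under", "all"],
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = dict(DEFAULTS)
    out.update(cfg)
    return out


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Run every configured stage; returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.get("seed", 0),
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "stages": [],
        "outputs": [],
    }

    def record(stage: str, t0: float) -> None:
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})

    def write_tsv(df: pd.DataFrame, name: str, **kw) -> Path:
        p = outdir / name
        df.to_csv(p, sep="\t", float_format="%.10g", **kw)
        manifest["outputs"].append(name)
        return p

    # --- counts ---------------------------------------------------------
    t0 = time.time()
    try:
        if "counts_path" in config:
            cm = counts_mod.read_count_matrix(
                config["counts_path"], config["group_map"]
            )
        elif "simulate" in config:
            sim = dict(config["simulate"] or {})
            sim.setdefault("seed", config.get("seed", 0))
            clusters = [
                (list(members), float(loading))
                for members, loading in sim.pop("clusters", [])
            ]
            de_effects = {
                int(k): (v[0], float(v[1]))
                for k, v in (sim.pop("de_effects", {}) or {}).items()
            }
            cm, truth = simulate.simulate_counts(
                simulate.SimulationConfig(
                    clusters=clusters, de_effects=de_effects, **sim
                )
            )
            truth.to_json(outdir / "truth.json")
            manifest["outputs"].append("truth.json")
        else:
            raise PipelineError("config needs either counts_path or simulate")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage counts: {exc}") from exc
    cm.to_tsv(outdir / "counts.tsv")
    manifest["outputs"].append("counts.tsv")
    record("counts", t0)

    # --- normalization --------------------------------------------------
    t0 = time.time()
    try:
        nm = counts_mod.normalize(cm)
    except Exception as exc:
        raise PipelineError(f"stage normalize: {exc}") from exc
    write_tsv(nm.values, "normalized.tsv", index_label="mirna_id")
    write_tsv(nm.size_factors.to_frame(), "size_factors.tsv", index_label="sample_id")
    k = min(3, len(cm.sample_ids), len(cm.mirna_ids))
    write_tsv(counts_mod.pca_scores(nm, k), "pca_scores.tsv", index_label="sample_id")
    record("normalize", t0)

    # --- differential expression ---------------------------------------
    contrasts = config.get("contrasts")
    if contrasts is None:
        ref = config.get("reference_condition", "control")
        others = [g for g in dict.fromkeys(cm.groups.values()) if g != ref]
        contrasts = [[ref, g] for g in others]
    de_results: dict[str, pd.DataFrame] = {}
    t0 = time.time()
    for ref, test in contrasts:
        try:
            res = diffexpr.de_test(cm, ref, test)
        except Exception as exc:
            raise PipelineError(f"stage de ({ref} vs {test}): {exc}") from exc
        name = f"de_{test}_vs_{ref}"
        de_results[name] = res
        write_tsv(res, f"{name}.tsv", index=False)
        write_tsv(
            diffexpr.de_table(res, config["de_alpha"]),
            f"{name}_significant.tsv",
            index=False,
        )
    record("de", t0)

    # --- RC-miR networks ------------------------------------------------
    t0 = time.time()
    grid = network.default_tau_grid(config["tau_step"])
    all_clusters: dict[str, dict] = {}
    n_similarity = 0
    for name, res in de_results.items():
        for block in config["blocks"]:
            ids = diffexpr.de_mirnas(res, config["de_alpha"], block)
            tag = f"{name}_{block}"
            if len(ids) < 3:
                all_clusters[tag] = {"skipped": f"only {len(ids)} DE miRNAs"}
                continue
            try:
                s = network.similarity_matrix(nm.values.loc[ids], config["nbins"])
                n_similarity += 1
                write_tsv(s, f"similarity_{tag}.tsv", index_label="mirna_id")
                scan = network.select_threshold(
                    s, grid, fallback_tau=config.get("fallback_tau")
                )
                a = network.adjacency(s, scan.tau_star)
                cs = network.extract_clusters(a)
            except network.NoThresholdError as exc:
                all_clusters[tag] = {"skipped": str(exc)}
                continue
            except Exception as exc:
                raise PipelineError(f"stage network ({tag}): {exc}") from exc
            write_tsv(a, f"adjacency_{tag}.tsv", index_label="mirna_id")
            write_tsv(scan.to_frame(), f"scan_{tag}.tsv", index=False)
            write_tsv(network.edge_list(s, a), f"edges_{tag}.tsv", index=False)
            all_clusters[tag] = {"tau_star": scan.tau_star, **cs.as_dict()}
    (outdir / "clusters.json").write_text(json.dumps(all_clusters, indent=1))
    manifest["outputs"].append("clusters.json")
    manifest["n_similarity_matrices"] = n_similarity
    record("network", t0)

    # --- targets and enrichment ----------------------------------------
    if "targets_path" in config:
        t0 = time.time()
        try:
            edges = targets.read_target_table(
                config["targets_path"], **config.get("target_columns", {})
            )
            de_ids = sorted(
                {m for res in de_results.values()
                 for m in diffexpr.de_mirnas(res, config["de_alpha"])}
            )
            filtered = targets.filter_targets(edges, de_ids)
            write_tsv(filtered, "targets_filtered.tsv", index=False)
            common: dict[str, dict] = {}
            for tag, info in all_clusters.items():
                for i, cluster in enumerate(info.get("clusters", [])):
                    genes, flagged = targets.common_targets(cluster, filtered)
                    common[f"{tag}/cluster{i}"] = {
                        "members": cluster,
                        "common_targets": sorted(genes),
                        "members_without_targets": flagged,
                    }
            (outdir / "common_targets.json").write_text(json.dumps(common, indent=1))
            manifest["outputs"].append("common_targets.json")
            if "genesets_path" in config:
                sets = targets.read_gmt(config["genesets_path"])
                universe = set().union(*sets.values()) | set(edges["gene_symbol"])
                coll = targets.GeneSetCollection(sets=sets, universe=universe)
                enr = targets.hypergeom_enrich(
                    set(filtered["gene_symbol"]), coll, config["de_alpha"]
                )
                write_tsv(enr, "enrichment.tsv", index=False)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage targets: {exc}") from exc
        record("targets", t0)

    # --- qPCR -----------------------------------------------------------
    if "qpcr_path" in config:
        t0 = time.time()
        try:
            meas = pd.read_csv(config["qpcr_path"], sep="\t")
            write_tsv(
                qpcr.rer_table(
                    meas,
                    control_condition=config.get("qpcr_control", "control"),
                    aggregate=config.get("qpcr_aggregate", "pairing"),
                ),
                "rer.tsv",
                index=False,
            )
        except Exception as exc:
            raise PipelineError(f"stage qpcr: {exc}") from exc
        record("qpcr", t0)

    for name in list(manifest["outputs"]):
        manifest.setdefault("hashes", {})[name] = _hash_file(outdir / name)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
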