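"""End-to-end pipeline: simulate -> de -> classify -> signatures -> network
-> celltype, driven by a single YAML configuration.

Each stage reads its inputs from, and writes its outputs to, the configured
output directory, so stages can be re-run individually. All files are written
atomically; a machine-readable run report (gene counts per filter, DEG counts
per contrast, class sizes, output checksums, warnings) is emitted as JSON.
Runs are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    celltype_composition,
    expression_core,
    network_scores,
    signatures,
    synthetic_data,
    trajectory_classes,
)
from .expression_core import DEConfig
from .synthetic_data import DEFAULT_CELLS, cell_key, parse_cell

logger = logging.getLogger(__name__)

__all__ = ["ConfigError", "StageError", "PipelineConfig", "validate_config", "run_pipeline",
           "DEFAULT_CONTRASTS", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1

STAGES = ["simulate", "de", "classify", "signatures", "network", "celltype"]

#: numerator:denominator contrast strings of the demo workflow
DEFAULT_CONTRASTS = [
    "WT,12,SE:WT,6,SE",
    "WT,12,EE:WT,6,EE",
    "TG,12,SE:TG,6,SE",
    "TG,12,EE:TG,6,EE",
    "TG,12,SE:WT,12,SE",
    "TG,12,EE:WT,12,SE",
    "TG,12,EE:TG,12,SE",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (named key)."""


class StageError(RuntimeError):
    """A pipeline stage failed or its inputs are missing."""


DEFAULTS: dict = {
    "outdir": "midtraject_out",
    "seed": 1,
    "stages": list(STAGES),
    "simulate": {
        "n_genes": 600,
        "n_per_cell": 6,
        "n_batches": 6,
        "class_fractions": {1: 0.1, 2: 0.1, 3: 0.1},
        "lfc_magnitude": 1.0,
        "frac_compensated": 0.5,
        "n_bias_genes": 0,
        "bias_shift": 0.0,
        "edge_density": 0.002,
        "hub_degree": 20,
        "n_hubs": 1,
    },
    "de": {
        "min_total_reads": 50,
        "lfc_threshold": 0.3,
        "padj_threshold": 0.1,
        "bias_sd_threshold": 4.0,
        "bias_min_flagged": 3,
        "batch_covariate": False,
        "contrasts": list(DEFAULT_CONTRASTS),
    },
    "classify": {"window": 0.5, "window_rule": "relative"},
    "signatures": {},
    "network": {"relevance_method": "degree"},
    "celltype": {
        "n_markers": 50,
        "n_samples_per_group": 6,
        "n_permutations": 500,
        "noise_alpha": 0.05,
        "shift": 0.0,
    },
}

_POSITIVE_KEYS = {
    ("de", "min_total_reads"),
    ("de", "lfc_threshold"),
    ("de", "padj_threshold"),
    ("de", "bias_sd_threshold"),
    ("classify", "window"),
    ("simulate", "n_genes"),
    ("simulate", "n_per_cell"),
}


class PipelineConfig(dict):
    """A validated configuration; behaves as a plain nested dict."""

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dict(self), fh, sort_keys=True)


def validate_config(config: dict | str | Path) -> PipelineConfig:
    """Merge a (possibly partial) configuration over the defaults.

    Unknown keys are rejected; thresholds must be positive; stage names must
    be known. The result round-trips losslessly through YAML.
    """
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")

    merged = copy.deepcopy(DEFAULTS)
    for key, value in config.items():
        if key not in merged:
            raise ConfigError(f"unknown configuration key: {key!r}")
        if isinstance(merged[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for sub, subval in value.items():
                if sub not in merged[key]:
                    raise ConfigError(f"unknown configuration key: {key}.{sub}")
                merged[key][sub] = subval
        else:
            merged[key] = value

    for stage in merged["stages"]:
        if stage not in STAGES:
            raise ConfigError(f"unknown stage: {stage!r}")
    for section, key in _POSITIVE_KEYS:
        if merged[section][key] <= 0:
            raise ConfigError(f"{section}.{key} must be strictly positive")
    fr = merged["simulate"]["class_fractions"]
    merged["simulate"]["class_fractions"] = {int(k): float(v) for k, v in fr.items()}
    for c in merged["de"]["contrasts"]:
        num_den = c.split(":")
        if len(num_den) != 2:
            raise ConfigError(f"contrast {c!r} is not of the form NUM:DEN")
        parse_cell(num_den[0]), parse_cell(num_den[1])
    return PipelineConfig(merged)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _atomic_write(df: pd.DataFrame, path: Path, **kwargs) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", **kwargs)
    os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _contrast_name(contrast_str: str) -> str:
    num, den = contrast_str.split(":")
    fmt = lambda c: cell_key(parse_cell(c)).replace("_", "").lower()  # noqa: E731
    return f"{fmt(num)}_vs_{fmt(den)}"


def _read_counts(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "counts.tsv", sep="\t", index_col="gene_id", comment="#")


def _read_design(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "samples.tsv", sep="\t", comment="#")


def _require(outdir: Path, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise StageError(f"missing stage inputs in {outdir}: {missing}")


def _log2_norm_expr(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return np.log2(counts.div(factors, axis=1) + 1.0)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, outdir: Path, seed: int) -> dict:
    p = cfg["simulate"]
    design = synthetic_data.make_design(
        p["n_per_cell"], DEFAULT_CELLS, n_batches=p["n_batches"], seed=seed
    )
    truth = synthetic_data.make_truth(
        p["n_genes"],
        p["class_fractions"],
        p["lfc_magnitude"],
        frac_compensated=p["frac_compensated"],
        seed=seed,
        n_bias_genes=p["n_bias_genes"],
        bias_shift=p["bias_shift"],
    )
    counts = synthetic_data.simulate_counts(truth, design, seed=seed + 1)

    comp2 = truth.genes.index[
        (truth.genes["class_label"] == 2) & truth.genes["ee_compensated"]
    ]
    pool = comp2 if len(comp2) else truth.class_genes(2)
    hubs = list(truth.genes.loc[pool, "base_mean"].sort_values(ascending=False).index[: p["n_hubs"]])
    edges = synthetic_data.simulate_network(
        truth, hubs, p["edge_density"], seed=seed + 2, hub_degree=p["hub_degree"],
        self_loop_genes=tuple(hubs[:1]),
    )

    rng = np.random.default_rng(seed + 3)
    lengths = pd.Series(
        np.exp(rng.uniform(np.log(0.5), np.log(10.0), p["n_genes"])),
        index=truth.gene_ids, name="length_kb",
    )
    gmt_sets, directions = synthetic_data.make_signature_sets(truth, seed=seed + 4)
    orth = synthetic_data.make_ortholog_map(truth.gene_ids, seed=seed + 5)

    cp = cfg["celltype"]
    sig = synthetic_data.make_celltype_signature(n_markers=cp["n_markers"], seed=seed + 6)
    k = sig.shape[1]
    n_s = cp["n_samples_per_group"]
    base = np.full(k, 1.0 / k)
    rng2 = np.random.default_rng(seed + 7)
    props_a = rng2.dirichlet(base * 40, size=n_s)
    shifted = base.copy()
    shifted[0] = base[0] + cp["shift"]
    shifted = shifted / shifted.sum()
    props_b = rng2.dirichlet(shifted * 40, size=n_s)
    prop_index = [f"ctA_r{i+1}" for i in range(n_s)] + [f"ctB_r{i+1}" for i in range(n_s)]
    props = pd.DataFrame(np.vstack([props_a, props_b]), index=prop_index, columns=sig.columns)
    bulk = synthetic_data.simulate_mixture(sig, props, seed=seed + 8, alpha=cp["noise_alpha"])

    synthetic_data.write_counts_tsv(counts, outdir / "counts.tsv")
    synthetic_data.write_design_tsv(design, outdir / "samples.tsv")
    synthetic_data.write_truth_tsv(truth, outdir / "truth.tsv")
    synthetic_data.write_edges_tsv(edges, outdir / "edges.tsv")
    lengths.to_frame().to_csv(outdir / "lengths.tsv", sep="\t", index_label="gene_id")
    signatures.write_gmt(gmt_sets, outdir / "signature_sets.gmt")
    _atomic_write(directions, outdir / "signature_directions.tsv", index=False)
    _atomic_write(orth, outdir / "ortholog_map.tsv", index=False)
    _atomic_write(sig, outdir / "celltype_signature.tsv", index_label="marker")
    _atomic_write(bulk, outdir / "celltype_bulk.tsv", index_label="marker")
    _atomic_write(props, outdir / "celltype_true_proportions.tsv", index_label="sample_id")
    (outdir / "hub_genes.txt").write_text("\n".join(hubs) + "\n", encoding="utf-8")

    return {
        "n_genes": int(p["n_genes"]),
        "n_samples": int(len(design)),
        "class_sizes": {int(k_): int(v) for k_, v in
                        truth.genes["class_label"].value_counts().sort_index().items()},
        "hubs": hubs,
        "n_edges": int(len(edges)),
    }


def _stage_de(cfg: PipelineConfig, outdir: Path, seed: int) -> dict:
    _require(outdir, "counts.tsv", "samples.tsv")
    p = cfg["de"]
    deconf = DEConfig(
        min_total_reads=p["min_total_reads"],
        lfc_threshold=p["lfc_threshold"],
        padj_threshold=p["padj_threshold"],
        bias_sd_threshold=p["bias_sd_threshold"],
    )
    counts = _read_counts(outdir)
    design = _read_design(outdir)
    n_before = len(counts)
    counts = expression_core.low_count_filter(counts, deconf.min_total_reads)
    factors = expression_core.size_factors(counts)
    fit = expression_core.fit_nb_glm(
        counts, design, factors=factors, batch_covariate=p["batch_covariate"]
    )
    results, deg_sets = {}, {}
    for contrast_str in p["contrasts"]:
        num, den = contrast_str.split(":")
        name = _contrast_name(contrast_str)
        res = expression_core.contrast(fit, parse_cell(den), parse_cell(num))
        results[name] = res
        deg_sets[name] = expression_core.call_degs(res, deconf)

    candidates = set()
    for degs in deg_sets.values():
        candidates |= set(degs.index)
    norm_expr = _log2_norm_expr(counts, factors)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        excluded, _flags = expression_core.technical_bias_filter(
            norm_expr, design, sorted(candidates),
            sd_threshold=deconf.bias_sd_threshold, min_flagged=p["bias_min_flagged"],
        )
    deg_counts = {}
    for name in list(deg_sets):
        deg_sets[name] = deg_sets[name].loc[~deg_sets[name].index.isin(excluded)]
        deg_counts[name] = int(len(deg_sets[name]))
        _atomic_write(results[name], outdir / f"de_{name}.tsv")
        _atomic_write(deg_sets[name], outdir / f"degs_{name}.tsv")
    _atomic_write(factors.to_frame(), outdir / "size_factors.tsv", index_label="sample_id")
    _atomic_write(norm_expr, outdir / "norm_log2_expr.tsv", index_label="gene_id")
    pd.Series(sorted(excluded), name="gene_id").to_frame().to_csv(
        outdir / "bias_excluded.tsv", sep="\t", index=False
    )
    return {
        "n_genes_before_filter": n_before,
        "n_genes_tested": int(len(counts)),
        "deg_counts": deg_counts,
        "n_bias_excluded": int(len(excluded)),
        "warnings": [str(w.message) for w in caught],
    }


def _read_degs(outdir: Path, name: str) -> pd.DataFrame:
    path = outdir / f"degs_{name}.tsv"
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df


def _read_result(outdir: Path, name: str) -> pd.DataFrame:
    return pd.read_csv(outdir / f"de_{name}.tsv", sep="\t", index_col="gene_id")


def _stage_classify(cfg: PipelineConfig, outdir: Path, seed: int) -> dict:
    names = dict(
        wt_se="wt12se_vs_wt6se", wt_ee="wt12ee_vs_wt6ee",
        tg_se="tg12se_vs_tg6se", tg_ee="tg12ee_vs_tg6ee",
        g12="tg12se_vs_wt12se",
    )
    _require(outdir, *[f"degs_{n}.tsv" for n in names.values()], "norm_log2_expr.tsv",
             "samples.tsv")
    p = cfg["classify"]

    wt_union = trajectory_classes.combine_temporal_degs(
        {"se": _read_degs(outdir, names["wt_se"]), "ee": _read_degs(outdir, names["wt_ee"])}
    )
    fc = pd.DataFrame(
        {
            "fc_se": _read_result(outdir, names["wt_se"])["log2fc"],
            "fc_ee": _read_result(outdir, names["wt_ee"])["log2fc"],
        }
    ).loc[wt_union.index]
    windowed = trajectory_classes.diagonal_window_filter(fc, p["window"], p["window_rule"])
    inside = windowed.index[windowed["inside_window"]]

    # window-restricted WT temporal set; SE direction takes precedence
    wt_dir = wt_union["dir_se"].fillna(wt_union["dir_ee"])
    wt_set = pd.DataFrame({"direction": wt_dir.loc[inside]})

    tg_union = trajectory_classes.combine_temporal_degs(
        {"se": _read_degs(outdir, names["tg_se"]), "ee": _read_degs(outdir, names["tg_ee"])}
    )
    tg_set = pd.DataFrame({"direction": tg_union["dir_se"].fillna(tg_union["dir_ee"])})
    g12_set = _read_degs(outdir, names["g12"])

    assignment = trajectory_classes.assign_classes(wt_set, tg_set, g12_set)

    design = _read_design(outdir)
    norm_expr = pd.read_csv(outdir / "norm_log2_expr.tsv", sep="\t", index_col="gene_id")
    se_samples = design.loc[design["environment"] == "SE", "sample_id"]
    universe = assignment.index.intersection(norm_expr.index)
    z = trajectory_classes.zscore_matrix(norm_expr.loc[universe, se_samples])
    profiles = trajectory_classes.cell_mean_profiles(z, design)
    medoids = trajectory_classes.cluster_medoids(profiles, assignment)
    if len(z) >= 2:
        order, _ = trajectory_classes.hierarchical_order(z)
        z_ordered = z.loc[order]
    else:
        z_ordered = z

    _atomic_write(windowed, outdir / "window_filter.tsv", index_label="gene_id")
    _atomic_write(assignment, outdir / "classes.tsv", index_label="gene_id")
    _atomic_write(medoids, outdir / "cluster_profiles.tsv", index=False)
    _atomic_write(z_ordered, outdir / "zscores_ordered.tsv", index_label="gene_id")
    class_sizes = assignment["class_label"].value_counts().sort_index()
    return {
        "n_union": int(len(assignment)),
        "n_inside_window": int(len(inside)),
        "class_sizes": {int(k): int(v) for k, v in class_sizes.items()},
        "n_clusters": int(len(medoids)),
    }


def _stage_signatures(cfg: PipelineConfig, outdir: Path, seed: int) -> dict:
    _require(outdir, "classes.tsv", "signature_sets.gmt", "signature_directions.tsv",
             "ortholog_map.tsv", "de_wt12se_vs_wt6se.tsv", "de_tg12se_vs_wt12se.tsv",
             "counts.tsv")
    assignment = pd.read_csv(outdir / "classes.tsv", sep="\t", index_col="gene_id")
    gmt = signatures.read_gmt(outdir / "signature_sets.gmt")
    orth = pd.read_csv(outdir / "ortholog_map.tsv", sep="\t")
    directions = pd.read_csv(outdir / "signature_directions.tsv", sep="\t")

    mapping = signatures.map_orthologs(list(assignment.index), orth)
    mapped_assignment = assignment.loc[
        [g for g in assignment.index if g in mapping.mapping]
    ].rename(index=mapping.mapping)

    overlaps = {
        name: signatures.overlap_sets(mapped_assignment, value["genes"])
        for name, value in gmt.items()
    }
    overlap_rows = [
        {"set": name, "n_overlap": ov["n_overlap"],
         **{f"class_{k}": v for k, v in ov["per_class"].items()}}
        for name, ov in overlaps.items()
    ]

    fc_age = _read_result(outdir, "wt12se_vs_wt6se")["log2fc"]
    fc_dist = _read_result(outdir, "tg12se_vs_wt12se")["log2fc"]
    inv = {v: k for k, v in mapping.mapping.items()}
    conc_rows = []
    for name, ov in overlaps.items():
        dir_table = directions.loc[directions["set"] == name].set_index("gene")["direction"]
        for g in ov["genes"]:
            mouse = inv.get(g)
            if mouse is None or mouse not in fc_age.index:
                continue
            conc_rows.append(
                {
                    "set": name,
                    "gene": g,
                    "mouse_gene": mouse,
                    "class_label": int(assignment.loc[mouse, "class_label"]),
                    "fc_age": float(fc_age[mouse]),
                    "fc_disturbance": float(fc_dist[mouse]),
                    "reference_direction": dir_table.get(g, "na"),
                }
            )
    conc = pd.DataFrame(conc_rows)
    if len(conc):
        conc = signatures.directional_concordance(conc)

    counts_index = _read_counts(outdir).index
    universe_mapped = signatures.map_orthologs(list(counts_index), orth).mapped
    query = [
        g for g in mapped_assignment.index[mapped_assignment["class_label"].isin([2, 3])]
        if g in set(universe_mapped)
    ]
    enrichment = signatures.hypergeom_enrichment(query, gmt, universe_mapped)

    _atomic_write(pd.DataFrame(overlap_rows), outdir / "signature_overlap.tsv", index=False)
    _atomic_write(conc, outdir / "concordance.tsv", index=False)
    _atomic_write(enrichment, outdir / "enrichment.tsv", index=False)
    return {
        "n_mapped": len(mapping.mapped),
        "n_unmapped": len(mapping.unmapped),
        "n_ambiguous": len(mapping.ambiguous),
        "overlaps": {name: ov["n_overlap"] for name, ov in overlaps.items()},
    }


def _stage_network(cfg: PipelineConfig, outdir: Path, seed: int) -> dict:
    _require(outdir, "edges.tsv", "classes.tsv", "de_tg12se_vs_wt12se.tsv",
             "de_tg12ee_vs_wt12se.tsv", "degs_tg12ee_vs_tg12se.tsv")
    edges = network_scores.read_edge_tsv(outdir / "edges.tsv")
    assignment = pd.read_csv(outdir / "classes.tsv", sep="\t", index_col="gene_id")
    G = network_scores.build_graph(edges, assignment)
    fc_dist = _read_result(outdir, "tg12se_vs_wt12se")["log2fc"]
    fc_res = _read_result(outdir, "tg12ee_vs_wt12se")["log2fc"]
    ee_degs = set(_read_degs(outdir, "tg12ee_vs_tg12se").index)
    scores = network_scores.score_genes(
        G, fc_dist, fc_res, ee_degs, method=cfg["network"]["relevance_method"]
    )
    ranked = network_scores.rank_candidates(scores)
    _atomic_write(scores, outdir / "network_scores.tsv", index_label="gene_id")
    _atomic_write(ranked, outdir / "ranked_candidates.tsv", index_label="gene_id")
    network_scores.write_sif(G, outdir / "network.sif")
    return {
        "n_nodes": int(G.number_of_nodes()),
        "n_edges": int(G.number_of_edges()),
        "n_ee_responsive": int(scores["ee_responsive"].sum()),
        "top_candidate": str(ranked.index[0]) if len(ranked) else None,
    }


def _stage_celltype(cfg: PipelineConfig, outdir: Path, seed: int) -> dict:
    _require(outdir, "celltype_signature.tsv", "celltype_bulk.tsv")
    p = cfg["celltype"]
    sig = pd.read_csv(outdir / "celltype_signature.tsv", sep="\t", index_col="marker")
    bulk = pd.read_csv(outdir / "celltype_bulk.tsv", sep="\t", index_col="marker")
    props = celltype_composition.estimate_proportions(bulk, sig)
    group = pd.Series(
        ["A" if s.startswith("ctA") else "B" for s in props.index], index=props.index
    )
    shift = celltype_composition.composition_shift_test(
        props.loc[group == "A"], props.loc[group == "B"],
        n_permutations=p["n_permutations"], seed=seed + 9,
    )
    _atomic_write(props, outdir / "celltype_proportions.tsv", index_label="sample_id")
    _atomic_write(shift, outdir / "celltype_shift_test.tsv", index=False)
    return {
        "n_cell_types": int(sig.shape[1]),
        "min_shift_padj": float(shift["padj"].min()),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "classify": _stage_classify,
    "signatures": _stage_signatures,
    "network": _stage_network,
    "celltype": _stage_celltype,
}


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the enabled stages in dependency order and return the run
    report (also written to ``<outdir>/run_report.json``).

    A stage failure aborts the downstream stages; the report records the
    partial completion and the error.
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed,
        "stages": {},
        "status": "success",
    }
    for stage in STAGES:
        if stage not in cfg["stages"]:
            continue
        t0 = time.perf_counter()
        try:
            counts = _STAGE_FUNCS[stage](cfg, outdir, seed)
        except Exception as exc:  # noqa: BLE001 - report and abort downstream
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            report["status"] = "failed"
            logger.error("stage %s failed: %s", stage, exc)
            break
        elapsed = time.perf_counter() - t0
        report["stages"][stage] = {
            "status": "ok",
            "elapsed_s": round(elapsed, 3),
            "counts": counts,
        }
        logger.info("stage %s finished in %.2fs", stage, elapsed)

    checksums = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "run_report.json" and not p.name.endswith(".tmp")
    }
    report["checksums"] = checksums

    tmp = outdir / "run_report.json.tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, outdir / "run_report.json")
    return report
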