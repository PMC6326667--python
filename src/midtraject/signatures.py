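"""Signature overlap, directional concordance and overrepresentation tests.

Class-assigned genes are compared against reference signature sets (an aging
signature; a joint age-and-disease signature) after one-to-one ortholog
mapping. Directional concordance asks whether a gene's midlife (WT 12-vs-6)
change and its genotype-driven (TG-vs-WT at 12 months) change point the same
way, mirroring the published age-vs-disease direction tables. Generic
overrepresentation of GMT gene sets is tested with the one-sided
hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .expression_core import bh_adjust

__all__ = [
    "read_gmt",
    "write_gmt",
    "OrthologMapping",
    "map_orthologs",
    "overlap_sets",
    "directional_concordance",
    "hypergeom_enrichment",
]


def read_gmt(path) -> dict[str, dict]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>gene...``.
    Lines starting with '#' are ignored."""
    sets: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = {"description": parts[1], "genes": parts[2:]}
    return sets


def write_gmt(sets: dict, path) -> None:
    """Write a GMT file; values may be plain gene lists or read_gmt dicts."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, value in sets.items():
            if isinstance(value, dict):
                desc, genes = value.get("description", "na"), value["genes"]
            else:
                desc, genes = "na", list(value)
            fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class OrthologMapping:
    """Result of one-to-one ortholog mapping.

    mapping: source -> target for retained pairs; mapped: target ids in input
    order; unmapped: sources absent from the map; ambiguous: sources (or
    sources of targets) involved in many-to-many relations, quarantined.
    """

    mapping: dict[str, str]
    mapped: list[str]
    unmapped: list[str]
    ambiguous: list[str]


def map_orthologs(genes, ortholog_map: pd.DataFrame) -> OrthologMapping:
    """Map gene ids through a source/target table, keeping only one-to-one
    pairs; ambiguous and unmapped genes are reported, never silently
    dropped."""
    pairs = ortholog_map[["source", "target"]].drop_duplicates()
    src_counts = pairs["source"].value_counts()
    tgt_counts = pairs["target"].value_counts()
    bad_sources = set(src_counts.index[src_counts > 1])
    bad_targets = set(tgt_counts.index[tgt_counts > 1])
    bad_sources |= set(pairs.loc[pairs["target"].isin(bad_targets), "source"])

    clean = pairs[~pairs["source"].isin(bad_sources)]
    mapping = dict(zip(clean["source"], clean["target"]))

    mapped, unmapped, ambiguous = [], [], []
    for g in genes:
        if g in mapping:
            mapped.append(mapping[g])
        elif g in bad_sources:
            ambiguous.append(g)
        else:
            unmapped.append(g)
    return OrthologMapping(mapping=mapping, mapped=mapped, unmapped=unmapped, ambiguous=ambiguous)


def overlap_sets(class_assignment: pd.DataFrame, signature_genes) -> dict:
    """Intersection of class-assigned genes with a signature set, with a
    per-class breakdown. Both sides must be on a common id space."""
    sig = set(signature_genes)
    genes = sorted(set(class_assignment.index) & sig)
    per_class = (
        class_assignment.loc[genes, "class_label"].value_counts().sort_index().to_dict()
        if genes
        else {}
    )
    return {
        "n_overlap": len(genes),
        "genes": genes,
        "per_class": {int(k): int(v) for k, v in per_class.items()},
    }


def directional_concordance(records: pd.DataFrame, dead_zone: float = 0.0) -> pd.DataFrame:
    """Classify each gene's age-change vs disturbance-change directionality.

    Expects columns ``fc_age`` (WT 12-vs-6) and ``fc_disturbance`` (TG-vs-WT
    at 12). call = 'similar' when both signs agree, 'opposite' when they
    differ, 'indeterminate' when either |fc| <= dead_zone (default 0: only
    exact zeros are indeterminate). Calls depend on signs alone, so they are
    invariant to positive rescaling.
    """
    age = records["fc_age"].to_numpy(dtype=float)
    dist = records["fc_disturbance"].to_numpy(dtype=float)
    indet = (np.abs(age) <= dead_zone) | (np.abs(dist) <= dead_zone)
    call = np.where(
        indet, "indeterminate", np.where(np.sign(age) == np.sign(dist), "similar", "opposite")
    )
    out = records.copy()
    out["call"] = call
    return out


def hypergeom_enrichment(query, gene_sets: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of GMT sets in a query.

    Each set is intersected with the universe before testing; the p-value is
    the upper tail P(X >= overlap) for X ~ Hypergeom(|universe|, |set|,
    |query|); BH adjustment across sets. Sorted by adjusted then raw p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    M, n = len(universe), len(query)
    rows = []
    for name, value in gene_sets.items():
        members = set(value["genes"] if isinstance(value, dict) else value) & universe
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, M, len(members), n)) if members else 1.0
        rows.append(
            {
                "set": name,
                "set_size": len(members),
                "overlap": k,
                "pvalue": min(p, 1.0),
                "genes": ",".join(sorted(members & query)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
        out = out.sort_values(["padj", "pvalue", "set"], kind="stable").reset_index(drop=True)
    return out
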