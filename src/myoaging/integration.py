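"""Joining age-associated proteins with age-associated spliced genes,
and category composition summaries.

The join is at the gene-symbol level: a protein group with several
listed symbols contributes its first symbol (with a warning). Category
labels (mitochondria, spliceosome, proteostasis, ...) are consumed as a
curated input annotation; features without a label fall into "other".
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping

import pandas as pd

__all__ = ["overlap_age_sets", "category_distribution", "primary_symbol"]


def primary_symbol(protein_group: str) -> str:
    """First gene symbol of a (possibly multi-gene) protein group id."""
    parts = [p for p in str(protein_group).replace(",", ";").split(";") if p]
    if len(parts) > 1:
        warnings.warn(f"protein group '{protein_group}' maps to several symbols; using {parts[0]}")
    return parts[0]


def overlap_age_sets(
    age_proteins: Iterable[str],
    age_spliced: Iterable[str],
) -> dict:
    """Intersection of age-associated protein genes and age-associated
    alternatively spliced genes, with membership percentages both ways."""
    prot = set(age_proteins)
    spliced = set(age_spliced)
    overlap = prot & spliced
    return {
        "overlap": overlap,
        "n_overlap": len(overlap),
        "n_proteins": len(prot),
        "n_spliced": len(spliced),
        "pct_of_proteins": 100.0 * len(overlap) / len(prot) if prot else 0.0,
        "pct_of_spliced": 100.0 * len(overlap) / len(spliced) if spliced else 0.0,
        "proteins_only": prot - spliced,
        "spliced_only": spliced - prot,
    }


def category_distribution(
    annotation: pd.DataFrame,
    groups: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-category percentage composition of each feature group.

    ``annotation`` must carry a ``category`` column indexed by feature
    id; ``groups`` maps a group label (e.g. ``all``, ``over``,
    ``under``) to the feature ids in that group. Unannotated features
    count as ``other``. Each column sums to 100 (empty groups are all
    zero).
    """
    if "category" not in annotation.columns:
        raise ValueError("annotation must have a 'category' column")
    cat = annotation["category"].astype(str)
    cols = {}
    for label, feats in groups.items():
        feats = list(feats)
        assigned = cat.reindex(feats).fillna("other")
        counts = assigned.value_counts()
        total = counts.sum()
        cols[label] = 100.0 * counts / total if total else counts.astype(float)
    out = pd.DataFrame(cols).fillna(0.0)
    out.index.name = "category"
    return out.sort_index()
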