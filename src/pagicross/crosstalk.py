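"""Feature-pathway selection and crosstalk-gene extraction.

From the FDR-significant pathways, those carrying at least a configurable
number of autophagy genes are kept as feature pathways; the union of their
members present in the expression profile forms the feature mRNAs
(crosstalk genes) passed on to coexpression analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import PathwayCollection

logger = logging.getLogger(__name__)


@dataclass
class FeatureSelection:
    candidate_pathways: list[str]
    feature_pathways: list[str]
    feature_mrnas: list[str]
    autophagy_genes: list[str] = field(default_factory=list)


def annotate_autophagy(scores: pd.DataFrame, pc: PathwayCollection,
                       autophagy: list[str] | set[str]) -> pd.DataFrame:
    """Attach the count of autophagy genes among each pathway's members."""
    aset = set(autophagy)
    counts = {p.id: len(p.genes & aset) for p in pc}
    out = scores.copy()
    out["autophagy_count"] = [counts.get(pid, 0) for pid in out.index]
    return out


def select_features(scores: pd.DataFrame, pc: PathwayCollection,
                    expr_genes, min_autophagy: int = 5,
                    fdr_cut: float = 0.01) -> FeatureSelection:
    """Keep FDR-significant pathways that are autophagy-rich.

    Candidates have FDR < ``fdr_cut``; feature pathways additionally carry
    >= ``min_autophagy`` autophagy genes (a computable proxy for the
    curation step the selection models). Feature mRNAs are the union of the
    feature pathways' members intersected with the expression universe. An
    empty feature set falls back to the candidates with a warning.
    """
    if "autophagy_count" not in scores.columns:
        raise ValueError("run annotate_autophagy before select_features")
    candidates = list(scores.index[scores["fdr"] < fdr_cut])
    features = [pid for pid in candidates
                if scores.loc[pid, "autophagy_count"] >= min_autophagy]
    if not features:
        logger.warning("no autophagy-rich pathway among %d candidates; "
                       "falling back to all candidates", len(candidates))
        features = list(candidates)
    expr_set = set(expr_genes)
    union: set[str] = set()
    for pid in features:
        union |= pc[pid].genes
    return FeatureSelection(
        candidate_pathways=candidates,
        feature_pathways=features,
        feature_mrnas=sorted(union & expr_set),
    )


def top_genes_per_pathway(selection: FeatureSelection, pc: PathwayCollection,
                          influence: pd.DataFrame,
                          k: int = 20) -> dict[str, list[str]]:
    """Per feature pathway, the k member genes with highest GDS.

    Ties break by gene id; pathways smaller than k return all members.
    """
    gds = influence["GDS"]
    out: dict[str, list[str]] = {}
    for pid in selection.feature_pathways:
        members = sorted(pc[pid].genes)
        scored = sorted(members,
                        key=lambda g: (-gds.get(g, 0.0), g))
        out[pid] = scored[: min(k, len(scored))]
    return out


def pathway_gene_table(top: dict[str, list[str]],
                       influence: pd.DataFrame) -> pd.DataFrame:
    """Bipartite pathway-gene edge table for network-style exports."""
    rows = []
    for pid, genes in sorted(top.items()):
        for g in genes:
            rows.append({"pathway_id": pid, "gene": g,
                         "GDS": float(influence["GDS"].get(g, 0.0))})
    return pd.DataFrame(rows, columns=["pathway_id", "gene", "GDS"])
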