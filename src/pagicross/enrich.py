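"""Hypergeometric pathway enrichment of modules and module selection.

Enrichment is an upper-tail hypergeometric test of each module against each
pathway within the coexpression background, BH-adjusted per module; the
analysis module is the one richest in autophagy genes.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coexpr import ModuleAssignment
from .io import DataError, PathwayCollection


def hypergeom_enrich(module_genes, pathway_sets: dict[str, set[str]],
                     background, p_cut: float = 0.05,
                     q_cut: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of one gene set.

    With background size N, pathway size K (in background), module size n
    (in background) and overlap k, p = P(X >= k); q is BH across the tested
    pathways. Significance requires p and q both below their cuts.
    """
    bg = set(background)
    if not bg:
        raise DataError("empty background")
    mod = set(module_genes) & bg
    n_bg, n_mod = len(bg), len(mod)
    rows = []
    for pid in sorted(pathway_sets):
        pw = set(pathway_sets[pid]) & bg
        k = len(mod & pw)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(pw), n_mod))
        rows.append({"pathway_id": pid, "overlap": k, "module_size": n_mod,
                     "pathway_size": len(pw), "background": n_bg,
                     "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    _, q, _, _ = multipletests(df["p"], method="fdr_bh")
    df["q"] = q
    df["significant"] = (df["p"] < p_cut) & (df["q"] < q_cut)
    return df


def enrich_modules(assignment: ModuleAssignment, pc: PathwayCollection,
                   background, p_cut: float = 0.05,
                   q_cut: float = 0.05) -> pd.DataFrame:
    """Enrichment table for every detected module."""
    sets = {p.id: p.genes for p in pc}
    frames = []
    for m in assignment.modules:
        df = hypergeom_enrich(assignment.genes_of(m), sets, background,
                              p_cut, q_cut)
        df.insert(0, "module", m)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["module", "pathway_id", "overlap",
                                     "module_size", "pathway_size",
                                     "background", "p", "q", "significant"])
    return pd.concat(frames, ignore_index=True)


def select_module(assignment: ModuleAssignment, autophagy,
                  ad_pathway_genes=()) -> tuple[int, dict[str, int]]:
    """Pick the module richest in autophagy genes.

    Ties break towards the larger module (then smaller label). Returns the
    chosen module and Venn overlap counts of its members with the autophagy
    list, with the reference disease pathway, and with both.
    """
    mods = assignment.modules
    if not mods:
        raise DataError("no modules to select from")
    aset, dset = set(autophagy), set(ad_pathway_genes)
    sizes = assignment.sizes()

    def sort_key(m: int):
        members = set(assignment.genes_of(m))
        return (-len(members & aset), -sizes[m], m)

    chosen = min(mods, key=sort_key)
    members = set(assignment.genes_of(chosen))
    counts = {
        "module_size": len(members),
        "autophagy_overlap": len(members & aset),
        "disease_pathway_overlap": len(members & dset),
        "both_overlap": len(members & aset & dset),
    }
    return chosen, counts
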