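"""Global-influence pathway scoring.

The three steps of the method:

1. Merge all within-pathway interaction edges into one global gene network;
   pathway crosstalk is realised through genes shared by several pathways.
2. Propagate differential-expression signal (|Welch t|) over the network by
   random walk with restart, ``P(t+1) = (1-r) M P(t) + r P0`` with M the
   column-normalised adjacency; min-max-normalise the stationary vector into
   a global dysregulated score (GDS) per gene.
3. Rank all profiled genes by the weight ``w = |t|^(1+GDS)`` and score each
   pathway with a weighted running-sum (Kolmogorov-Smirnov style) statistic;
   assess significance by phenotype permutation with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import DataError, PathwayCollection

logger = logging.getLogger(__name__)


@dataclass
class GlobalNetwork:
    """Union of pathway graphs with column-stochastic transition matrix."""

    nodes: list[str]
    adjacency: np.ndarray  # symmetric 0/1, zero diagonal
    M: np.ndarray          # column-normalised adjacency

    @property
    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}


@dataclass
class PathwayScoreRecord:
    pathway_id: str
    name: str
    size: int            # members mapped onto the ranked list
    score: float
    peak_index: int      # 1-based position of the running-sum peak
    gene_pct: float
    tag_pct: float
    signal: float
    perm_p: float = np.nan
    fdr: float = np.nan
    autophagy_count: int = -1


def build_global_network(pc: PathwayCollection) -> GlobalNetwork:
    """Collapse all within-pathway edges into one undirected global network.

    Node set is the union of pathway members (isolated members included);
    duplicate edges across pathways collapse to one.
    """
    if len(pc) == 0:
        raise DataError("empty pathway collection")
    nodes = sorted(pc.gene_universe())
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for p in pc:
        for u, v in p.edges:
            if u == v:
                continue
            a[idx[u], idx[v]] = 1.0
            a[idx[v], idx[u]] = 1.0
    col = a.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(col > 0, a / col, 0.0)
    return GlobalNetwork(nodes, a, m)


def t_scores(expr: pd.DataFrame, groups: pd.Series | np.ndarray) -> pd.Series:
    """Per-gene Welch t-statistic, case (AD) minus control.

    Genes with zero variance in both groups get t = 0.
    """
    if isinstance(groups, pd.Series):
        groups = groups.loc[expr.columns].to_numpy()
    mask = np.asarray([g == "AD" for g in groups])
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise DataError("each group needs at least 2 samples for t-scores")
    t = welch_t(expr.to_numpy(dtype=float), mask)
    return pd.Series(t, index=expr.index, name="t")


def welch_t(x: np.ndarray, case_mask: np.ndarray) -> np.ndarray:
    """Vectorised Welch t over rows of ``x`` (zero where both variances 0)."""
    xa, xb = x[:, case_mask], x[:, ~case_mask]
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    denom = np.sqrt(va / na + vb / nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / denom
    return np.where(denom > 0, t, 0.0)


def rwr_stationary(net: GlobalNetwork, p0: np.ndarray, r: float,
                   tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Iterate the restart walk to its stationary vector (L1 stopping)."""
    if not 0 < r < 1:
        raise DataError("restart probability must lie in (0, 1)")
    p = p0.copy()
    for _ in range(max_iter):
        p_next = (1 - r) * (net.M @ p) + r * p0
        if np.abs(p_next - p).sum() < tol:
            return p_next
        p = p_next
    logger.warning("RWR did not converge in %d iterations; returning last "
                   "iterate", max_iter)
    return p


def rwr_linear_solve(net: GlobalNetwork, p0: np.ndarray, r: float) -> np.ndarray:
    """Closed-form stationary vector r (I - (1-r) M)^-1 P0."""
    n = len(net.nodes)
    return r * np.linalg.solve(np.eye(n) - (1 - r) * net.M, p0)


def rwr_gds(net: GlobalNetwork, t: pd.Series, r: float = 0.7,
            tol: float = 1e-10, max_iter: int = 1000,
            uniform_p0: bool = False) -> pd.DataFrame:
    """Stationary RWR probabilities and GDS for every network node.

    The initial probability of a node is proportional to its |t| (genes
    absent from the expression profile seed zero mass); ``uniform_p0``
    switches to an unweighted start. GDS is the min-max-normalised
    stationary probability.
    """
    if len(net.nodes) == 0:
        raise DataError("empty network")
    t_net = t.reindex(net.nodes).fillna(0.0)
    t_abs = t_net.abs().to_numpy()
    if uniform_p0:
        p0 = np.full(len(net.nodes), 1.0 / len(net.nodes))
    else:
        total = t_abs.sum()
        if total == 0:
            raise DataError("all t-scores are zero: no signal to propagate")
        p0 = t_abs / total
    p_inf = rwr_stationary(net, p0, r, tol, max_iter)
    lo, hi = p_inf.min(), p_inf.max()
    gds = (p_inf - lo) / (hi - lo) if hi > lo else np.zeros_like(p_inf)
    out = pd.DataFrame(
        {
            "t": t_net.to_numpy(),
            "p0": p0,
            "p_inf": p_inf,
            "GDS": gds,
            "weight": t_abs ** (1.0 + gds),
        },
        index=pd.Index(net.nodes, name="gene"),
    )
    return out


def gene_weights(t: pd.Series, influence: pd.DataFrame) -> pd.Series:
    """Ranking weight w = |t|^(1+GDS) for every profiled gene.

    Genes outside the network carry GDS = 0, hence w = |t|.
    """
    gds = influence["GDS"].reindex(t.index).fillna(0.0)
    return (t.abs() ** (1.0 + gds)).rename("weight")


def rank_genes(weights: pd.Series) -> pd.DataFrame:
    """Sort genes by weight descending; ties break lexicographically."""
    base = np.argsort(weights.index.to_numpy())          # lexicographic
    w = weights.to_numpy()[base]
    order = base[np.argsort(-w, kind="stable")]
    ranked = weights.iloc[order].to_frame("weight")
    ranked.index.name = "gene"
    return ranked


def _score_from_order(hit: np.ndarray, w_ranked: np.ndarray):
    """Running-sum statistic for one pathway over a ranked list.

    Returns (score, peak 0-based, tag_pct) or None for degenerate cases.
    """
    n = hit.size
    n_p = int(hit.sum())
    if n_p == 0 or n_p == n:
        return None
    hw = np.where(hit, w_ranked, 0.0)
    hit_cum = np.cumsum(hw)
    n_r = hit_cum[-1]
    if n_r == 0:
        return None
    p_hit = hit_cum / n_r
    p_miss = np.cumsum(~hit) / (n - n_p)
    dev = p_hit - p_miss
    i0 = int(np.argmax(np.abs(dev)))
    tag = int(hit[: i0 + 1].sum())
    return float(dev[i0]), i0, tag / n_p


def pathway_score(ranked: pd.DataFrame, members: set[str],
                  pathway_id: str = "", name: str = "") -> PathwayScoreRecord | None:
    """Weighted running-sum score of one gene set against the ranked list.

    ``score`` is the maximum absolute deviation between the weighted
    cumulative hit fraction and the uniform cumulative miss fraction
    (signed); ``gene_pct`` the peak position as a fraction of the list;
    ``signal`` the leading-edge intensity tag% x (1-gene%) x N/(N-N_P).
    Degenerate pathways (no mapped genes, all genes, or zero total member
    weight) return None with a warning.
    """
    genes = ranked.index.to_numpy()
    hit = np.isin(genes, sorted(members))
    res = _score_from_order(hit, ranked["weight"].to_numpy())
    if res is None:
        logger.warning("pathway %s skipped: degenerate on the ranked list",
                       pathway_id or name)
        return None
    score, i0, tag_pct = res
    n = len(genes)
    n_p = int(hit.sum())
    gene_pct = (i0 + 1) / n
    signal = tag_pct * (1.0 - gene_pct) * n / (n - n_p)
    return PathwayScoreRecord(pathway_id, name, n_p, score, i0 + 1,
                              gene_pct, tag_pct, signal)


def score_all_pathways(ranked: pd.DataFrame,
                       pc: PathwayCollection) -> list[PathwayScoreRecord]:
    out = []
    for p in pc:
        rec = pathway_score(ranked, p.genes, p.id, p.name)
        if rec is not None:
            out.append(rec)
    return out


def permutation_fdr(expr: pd.DataFrame, groups: pd.Series,
                    net: GlobalNetwork, pc: PathwayCollection,
                    n_permutations: int = 200, r: float = 0.7,
                    seed: int = 0, permute_gds: bool = False,
                    fdr_cut: float = 0.01, tol: float = 1e-10,
                    max_iter: int = 1000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every pathway and attach phenotype-permutation p and BH FDR.

    Group labels are permuted; t-scores and ranking weights are recomputed
    per permutation while GDS stays fixed at its observed value unless
    ``permute_gds`` (full RWR recomputation) is requested. The permutation
    p-value compares |score|: ``(1 + #{|s_b| >= |s_obs|}) / (B + 1)``.

    Returns (pathway score table, per-gene influence table).
    """
    if n_permutations < 10:
        raise DataError("need at least 10 permutations")
    if 1.0 / (n_permutations + 1) > fdr_cut:
        logger.warning(
            "B=%d permutations cannot reach FDR < %g (min p = %.3g)",
            n_permutations, fdr_cut, 1.0 / (n_permutations + 1))
    rng = np.random.default_rng(seed)
    x = expr.to_numpy(dtype=float)
    mask = (groups.loc[expr.columns] == "AD").to_numpy()

    t_obs = pd.Series(welch_t(x, mask), index=expr.index)
    influence = rwr_gds(net, t_obs, r=r, tol=tol, max_iter=max_iter)
    gds_all = influence["GDS"].reindex(expr.index).fillna(0.0).to_numpy()

    base = np.argsort(expr.index.to_numpy())  # lexicographic tie base

    def rank_order(w: np.ndarray) -> np.ndarray:
        return base[np.argsort(-w[base], kind="stable")]

    # membership masks in expression-gene space
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    memb = {}
    for p in pc:
        rows = [gene_pos[g] for g in p.genes if g in gene_pos]
        v = np.zeros(len(expr.index), dtype=bool)
        v[rows] = True
        memb[p.id] = v

    w_obs = np.abs(t_obs.to_numpy()) ** (1.0 + gds_all)
    order_obs = rank_order(w_obs)
    records: list[PathwayScoreRecord] = []
    kept_ids = []
    for p in pc:
        hit = memb[p.id][order_obs]
        res = _score_from_order(hit, w_obs[order_obs])
        if res is None:
            logger.warning("pathway %s skipped: degenerate on the ranked list",
                           p.id)
            continue
        score, i0, tag_pct = res
        n = len(expr.index)
        n_p = int(hit.sum())
        records.append(PathwayScoreRecord(
            p.id, p.name, n_p, score, i0 + 1, (i0 + 1) / n, tag_pct,
            tag_pct * (1.0 - (i0 + 1) / n) * n / (n - n_p)))
        kept_ids.append(p.id)

    exceed = {pid: 0 for pid in kept_ids}
    obs_abs = {rec.pathway_id: abs(rec.score) for rec in records}
    for _ in range(n_permutations):
        mask_b = rng.permutation(mask)
        t_b = welch_t(x, mask_b)
        if permute_gds:
            infl_b = rwr_gds(net, pd.Series(t_b, index=expr.index), r=r,
                             tol=tol, max_iter=max_iter)
            gds_b = infl_b["GDS"].reindex(expr.index).fillna(0.0).to_numpy()
        else:
            gds_b = gds_all
        w_b = np.abs(t_b) ** (1.0 + gds_b)
        order_b = rank_order(w_b)
        w_ranked = w_b[order_b]
        for pid in kept_ids:
            res = _score_from_order(memb[pid][order_b], w_ranked)
            if res is not None and abs(res[0]) >= obs_abs[pid]:
                exceed[pid] += 1

    perm_p = np.array([(1 + exceed[pid]) / (n_permutations + 1)
                       for pid in kept_ids])
    _, fdr, _, _ = multipletests(perm_p, method="fdr_bh")
    for rec, pp, q in zip(records, perm_p, fdr):
        rec.perm_p = float(pp)
        rec.fdr = float(q)

    table = pd.DataFrame(
        [
            {
                "pathway_id": r_.pathway_id,
                "name": r_.name,
                "size": r_.size,
                "score": r_.score,
                "peak_index": r_.peak_index,
                "gene_pct": r_.gene_pct,
                "signal": r_.signal,
                "perm_p": r_.perm_p,
                "fdr": r_.fdr,
                "significant": r_.fdr < fdr_cut,
            }
            for r_ in records
        ]
    ).set_index("pathway_id")
    return table, influence
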