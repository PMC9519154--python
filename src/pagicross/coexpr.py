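"""Weighted coexpression modules: soft threshold, TOM, clustering, merging.

The network is unsigned: adjacency a_ij = |pearson(x_i, x_j)|^beta, with beta
chosen as the smallest power achieving a scale-free fit R^2 above threshold
(equivalently, the qualifying power with maximal mean connectivity, since
connectivity decreases in beta). Clustering is average-linkage on 1 - TOM
with a deterministic adaptive static cut (a simplification of dynamic tree
cutting: see docs/methods.md), followed by eigengene-correlation merging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

UNASSIGNED = 0  # the "grey" label

N_SCALE_FREE_BINS = 10
CUT_START = 0.99    # first static cut, as a fraction of the top merge height
CUT_STEP = 0.98     # multiplicative descent per step


@dataclass
class SoftThresholdScan:
    beta_grid: list[int]
    signed_r2: list[float]
    mean_connectivity: list[float]
    chosen_beta: int
    dropped_genes: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beta": self.beta_grid,
            "signed_r2": self.signed_r2,
            "mean_connectivity": self.mean_connectivity,
        }).set_index("beta")


@dataclass
class ModuleAssignment:
    labels: pd.Series               # gene -> module label (0 = unassigned)
    eigengenes: pd.DataFrame        # module x sample

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.labels) - {UNASSIGNED})

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.modules}

    def genes_of(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _correlation(expr: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """|Pearson| over genes (rows); constant genes are excluded."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    keep = sd > 0
    dropped = list(expr.index[~keep])
    if dropped:
        logger.warning("excluding %d constant genes from coexpression",
                       len(dropped))
    s = np.abs(np.corrcoef(x[keep]))
    np.clip(s, 0.0, 1.0, out=s)
    return s, list(expr.index[keep]), dropped


def scale_free_fit(k: np.ndarray, n_bins: int = N_SCALE_FREE_BINS) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned into equal-width bins; log10 frequency is
    regressed on log10 mean connectivity per (non-empty) bin. The sign is
    flipped when the slope is positive (anti-scale-free).
    """
    k = np.asarray(k, dtype=float)
    if k.max() == k.min():
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if not sel.any():
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.array(xs) + intercept
    ss_res = float(((np.array(ys) - pred) ** 2).sum())
    ss_tot = float(((np.array(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return r2 if slope <= 0 else -r2


def soft_threshold_scan(expr: pd.DataFrame, r2_threshold: float = 0.85,
                        beta_max: int = 20) -> SoftThresholdScan:
    """Scan beta = 1..beta_max for the scale-free soft threshold.

    Among powers whose signed R^2 exceeds the threshold the one with maximal
    mean connectivity is chosen (the smallest such power, as connectivity is
    monotone decreasing in beta); if none qualifies the largest-R^2 power is
    used with a warning.
    """
    if expr.shape[0] < 3 or expr.shape[1] < 4:
        raise ValueError("need at least 3 genes and 4 samples")
    s, kept, dropped = _correlation(expr)
    np.fill_diagonal(s, 0.0)
    betas = list(range(1, beta_max + 1))
    r2s, ks = [], []
    a = np.ones_like(s)
    for _ in betas:
        a = a * s
        k = a.sum(axis=1)
        ks.append(float(k.mean()))
        r2s.append(scale_free_fit(k))
    qualifying = [i for i, r2 in enumerate(r2s) if r2 > r2_threshold]
    if qualifying:
        best = max(qualifying, key=lambda i: ks[i])
    else:
        best = int(np.argmax(r2s))
        logger.warning("no beta reaches R^2 > %.2f; using beta=%d "
                       "(R^2=%.3f)", r2_threshold, betas[best], r2s[best])
    return SoftThresholdScan(betas, r2s, ks, betas[best], dropped)


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned adjacency |pearson|^beta with zero diagonal."""
    s, kept, _ = _correlation(expr)
    a = s ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=kept, columns=kept)


def tom_matrix(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbour plus direct adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    unit diagonal.
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.diag(a).any():
        raise ValueError("adjacency must have zero diagonal")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _big_cluster_partition(labels: np.ndarray, min_size: int) -> frozenset:
    out = []
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if members.size >= min_size:
            out.append(frozenset(members.tolist()))
    return frozenset(out)


def detect_modules(dissim: pd.DataFrame, min_size: int = 50) -> pd.Series:
    """Average-linkage clustering with a deterministic adaptive static cut.

    Starting at 0.99 x the top merge height, the cut descends in 2% steps
    down to the first merge height; the returned partition is the one with
    the most clusters of at least ``min_size`` genes, taken at the highest
    height achieving that count (so each module keeps its fullest
    membership). Remaining genes are then assigned to their closest module
    when their mean dissimilarity to it beats the cut height (the
    nearest-module rescue of dynamic tree cutting); everything else stays
    unassigned (label 0).
    """
    genes = list(dissim.index)
    if len(genes) < min_size:
        logger.warning("fewer than %d genes: nothing to assign", min_size)
        return pd.Series(UNASSIGNED, index=pd.Index(genes, name="gene"),
                         name="module")
    d = dissim.to_numpy(dtype=float)
    z = linkage(squareform(d, checks=False), method="average")
    top = z[-1, 2]
    floor = z[0, 2]
    h = CUT_START * top
    best_part: frozenset = frozenset()
    best_h = h
    while h >= floor:
        labels = fcluster(z, t=h, criterion="distance")
        part = _big_cluster_partition(labels, min_size)
        if len(part) > len(best_part):
            best_part, best_h = part, h
        h *= CUT_STEP
    # relabel: big clusters -> 1..k by decreasing size (tie: first gene)
    final = np.full(len(genes), UNASSIGNED, dtype=int)
    clusters = sorted(best_part, key=lambda c: (-len(c), min(c)))
    for newlab, members in enumerate(clusters, start=1):
        final[list(members)] = newlab
    # nearest-module rescue for genes the static cut left out
    if clusters:
        cluster_rows = [sorted(c) for c in clusters]
        for i in np.where(final == UNASSIGNED)[0]:
            mean_d = np.array([d[i, rows].mean() for rows in cluster_rows])
            j = int(np.argmin(mean_d))
            if mean_d[j] < best_h:
                final[i] = j + 1
    return pd.Series(final, index=pd.Index(genes, name="gene"), name="module")


def module_eigengene(expr: pd.DataFrame) -> pd.Series:
    """First principal component over samples of the standardized module.

    Sign-aligned to correlate positively with the module's mean expression.
    A single-gene module returns that gene standardized.
    """
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    if z.shape[0] == 1:
        e = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(e, mean_profile) < 0:
        e = -e
    norm = np.linalg.norm(e)
    if norm > 0:
        e = e / norm
    return pd.Series(e, index=expr.columns)


def _eigengene_frame(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    mods = sorted(set(labels) - {UNASSIGNED})
    rows = {m: module_eigengene(expr.loc[labels.index[labels == m]])
            for m in mods}
    return pd.DataFrame(rows).T.rename_axis(index="module")


def merge_modules(labels: pd.Series, expr: pd.DataFrame,
                  cut_height: float = 0.25,
                  max_rounds: int = 10) -> ModuleAssignment:
    """Merge modules whose eigengenes cluster below ``cut_height``.

    Eigengene dissimilarity is 1 - pearson correlation; average-linkage
    groups joined below the cut merge into one module, eigengenes are
    recomputed, and the procedure repeats until stable.
    """
    labels = labels.copy()
    for _ in range(max_rounds):
        mods = sorted(set(labels) - {UNASSIGNED})
        if len(mods) <= 1:
            break
        eig = _eigengene_frame(expr, labels)
        corr = np.corrcoef(eig.to_numpy())
        diss = 1.0 - corr
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
        z = linkage(squareform(diss, checks=False), method="average")
        grouped = fcluster(z, t=cut_height, criterion="distance")
        if len(set(grouped)) == len(mods):
            break
        mapping = {}
        for mod, grp in zip(mods, grouped):
            mapping.setdefault(grp, []).append(mod)
        for grp, members in mapping.items():
            target = min(members)
            for m in members:
                labels[labels == m] = target
    # canonical relabel by size
    mods = sorted(set(labels) - {UNASSIGNED})
    sizes = {m: (labels == m).sum() for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], m))
    remap = {m: i + 1 for i, m in enumerate(order)}
    labels = labels.map(lambda m: remap.get(m, UNASSIGNED))
    eig = _eigengene_frame(expr, labels)
    return ModuleAssignment(labels.rename("module"), eig)


def build_modules(expr: pd.DataFrame, r2_threshold: float = 0.85,
                  beta_max: int = 20, min_size: int = 50,
                  merge_height: float = 0.25
                  ) -> tuple[ModuleAssignment, SoftThresholdScan]:
    """Full coexpression-module construction over ``expr`` (genes x samples)."""
    scan = soft_threshold_scan(expr, r2_threshold, beta_max)
    keep = expr.drop(index=scan.dropped_genes)
    adj = adjacency(keep, scan.chosen_beta)
    tom = tom_matrix(adj)
    raw = detect_modules(1.0 - tom, min_size=min_size)
    assignment = merge_modules(raw, keep, cut_height=merge_height)
    if scan.dropped_genes:
        extra = pd.Series(UNASSIGNED, index=pd.Index(scan.dropped_genes,
                                                     name="gene"))
        assignment.labels = pd.concat([assignment.labels, extra]).reindex(
            expr.index).astype(int).rename("module")
    return assignment, scan
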