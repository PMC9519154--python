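"""Shared fixtures: small synthetic cohorts and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from pagicross.config import SimConfig
from pagicross import synthio


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A reduced cohort that keeps every planted structure but runs fast."""
    return SimConfig(
        n_genes=400,
        n_lnc=80,
        n_pathways=8,
        pathway_size_range=(30, 50),
        n_dysregulated=2,
        n_case=30,
        n_control=30,
        n_modules=2,
        module_size=60,
        lnc_de_fraction=0.3,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    pathways = synthio.simulate_pathways(small_cfg)
    mrna, lnc, truth = synthio.simulate_counts(small_cfg, pathways)
    return pathways, mrna, lnc, truth


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)


def brute_running_sum(genes, weights, members):
    """Position-by-position walk of the weighted running-sum statistic."""
    members = set(members)
    n = len(genes)
    n_p = sum(g in members for g in genes)
    n_r = sum(w for g, w in zip(genes, weights) if g in members)
    if n_p == 0 or n_p == n or n_r == 0:
        return None
    hit_sum, miss_count = 0.0, 0
    best, best_i = 0.0, 0
    for i, (g, w) in enumerate(zip(genes, weights), start=1):
        if g in members:
            hit_sum += w
        else:
            miss_count += 1
        dev = hit_sum / n_r - miss_count / (n - n_p)
        if abs(dev) > abs(best):
            best, best_i = dev, i
    return best, best_i


def tom_triple_loop(a: np.ndarray) -> np.ndarray:
    """Direct evaluation of the topological overlap formula."""
    n = a.shape[0]
    k = a.sum(axis=1)
    t = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = sum(a[i, u] * a[u, j] for u in range(n)) + a[i, j]
            t[i, j] = num / (min(k[i], k[j]) + 1.0 - a[i, j])
    return t


def hypergeom_tail_exact(k: int, n_bg: int, n_pw: int, n_mod: int) -> float:
    """Exact combinatorial upper tail P(X >= k)."""
    total = math.comb(n_bg, n_mod)
    return sum(
        math.comb(n_pw, x) * math.comb(n_bg - n_pw, n_mod - x)
        for x in range(k, min(n_pw, n_mod) + 1)
    ) / total


def cox_newton_oracle(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                      n_iter: int = 100) -> float:
    """Single-covariate Cox partial-likelihood Newton solver (Breslow)."""
    beta = 0.0
    for _ in range(n_iter):
        score = 0.0
        info = 0.0
        for i in np.where(event == 1)[0]:
            risk = time >= time[i]
            w = np.exp(beta * x[risk])
            s0 = w.sum()
            s1 = (w * x[risk]).sum()
            s2 = (w * x[risk] ** 2).sum()
            score += x[i] - s1 / s0
            info += s2 / s0 - (s1 / s0) ** 2
        step = score / info
        beta += step
        if abs(step) < 1e-12:
            break
    return beta


def random_connected_graph(n_nodes: int, rng: np.random.Generator):
    """A connected undirected graph as a pathway-like edge list."""
    from pagicross.synthio import _connected_er

    nodes = [f"N{i:03d}" for i in range(n_nodes)]
    return nodes, _connected_er(nodes, rng)
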