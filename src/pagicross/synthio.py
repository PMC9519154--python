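"""Synthetic cohort generator with planted, recorded truth.

Generates every input the analysis pipeline reads — pathway gene sets with
crosstalk (shared membership), within-pathway interaction edges, mRNA and
lncRNA count matrices, gene lengths, an autophagy gene list, and a clinical
survival table — together with a :class:`SimTruth` record of exactly what
was planted, so downstream stages can be scored against known answers.

Counts are drawn on the log2 scale and realised as negative-binomial
integers (gamma-Poisson mixture), so that dysregulation shifts
(``effect_delta``), coexpression-module loadings and prognostic-hazard
coefficients all act on the same log2 scale the pipeline's t-tests and Cox
model operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from . import io as pio
from .io import CountMatrix, Pathway, PathwayCollection

AUTOPHAGY_PER_PLANTED = 8
AUTOPHAGY_BACKGROUND = 30
EXPECTED_DEGREE = 3.0

# module loadings are log-normal: graded membership with hub-like tails and
# essentially no undetectably-weak "members"
MODULE_LOADING_MU = 0.3
MODULE_LOADING_SIGMA = 0.6
# weak background co-regulation shared by all genes (see docs/methods.md)
N_BG_FACTORS = 50
BG_MEMBERSHIP_RATE = 2.0
# prognostic genes get the median member loading, deterministically, so
# their membership of the planted module does not hinge on a lucky draw
PROGNOSTIC_LOADING = 1.35


@dataclass
class SimTruth:
    """What was planted: the answer key for the synthetic cohort."""

    dysregulated_pathway_ids: list[str] = field(default_factory=list)
    affected_genes: list[str] = field(default_factory=list)
    affected_direction: dict[str, int] = field(default_factory=dict)
    module_assignments: dict[str, int] = field(default_factory=dict)
    de_lnc_ids: dict[str, int] = field(default_factory=dict)  # gene -> +1/-1
    prognostic_genes: dict[str, float] = field(default_factory=dict)
    autophagy_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dysregulated_pathway_ids": sorted(self.dysregulated_pathway_ids),
            "affected_genes": sorted(self.affected_genes),
            "affected_direction": dict(sorted(self.affected_direction.items())),
            "module_assignments": dict(sorted(self.module_assignments.items())),
            "de_lnc_ids": dict(sorted(self.de_lnc_ids.items())),
            "prognostic_genes": self.prognostic_genes,
            "autophagy_genes": sorted(self.autophagy_genes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            dysregulated_pathway_ids=list(d["dysregulated_pathway_ids"]),
            affected_genes=list(d["affected_genes"]),
            affected_direction={k: int(v) for k, v
                                in d.get("affected_direction", {}).items()},
            module_assignments={k: int(v) for k, v in d["module_assignments"].items()},
            de_lnc_ids={k: int(v) for k, v in d["de_lnc_ids"].items()},
            prognostic_genes={k: float(v) for k, v in d["prognostic_genes"].items()},
            autophagy_genes=list(d.get("autophagy_genes", [])),
        )


def mrna_ids(cfg: SimConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]


def lnc_ids(cfg: SimConfig) -> list[str]:
    return [f"LNC{i:04d}" for i in range(1, cfg.n_lnc + 1)]


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _connected_er(members: list[str], rng: np.random.Generator) -> list[tuple[str, str]]:
    """Connected Erdos-Renyi graph over members with expected degree ~3."""
    m = len(members)
    if m < 2:
        return []
    p = min(1.0, EXPECTED_DEGREE / (m - 1))
    g = nx.gnp_random_graph(m, p, seed=int(rng.integers(2**31)))
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c[0])
    while len(comps) > 1:
        a = comps[0][int(rng.integers(len(comps[0])))]
        b = comps[1][int(rng.integers(len(comps[1])))]
        g.add_edge(a, b)
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: c[0])
    return [(members[a], members[b]) for a, b in sorted(g.edges())]


def simulate_pathways(cfg: SimConfig) -> PathwayCollection:
    """Draw pathway gene sets arranged in a crosstalk ring.

    Pathway i shares ``round(crosstalk_overlap * size_i)`` genes with pathway
    (i+1) mod n; all other membership is disjoint, so crosstalk exists only
    through the designated shared genes. Within-pathway edges form a
    connected Erdos-Renyi graph with expected degree ~3.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    universe = mrna_ids(cfg)
    n = cfg.n_pathways
    lo, hi = cfg.pathway_size_range
    sizes = rng.integers(lo, hi + 1, size=n)

    pool = [str(g) for g in rng.permutation(universe)]

    def fresh(k: int) -> list[str]:
        if k > len(pool):
            raise ConfigError("gene universe exhausted while drawing pathways")
        out = pool[:k]
        del pool[:k]
        return out

    members: list[list[str]] = []
    shares: list[list[str]] = []  # shares[i] = genes shared between i and i+1
    for i in range(n):
        size = int(sizes[i])
        inherited = shares[i - 1] if i > 0 else []
        mem = list(inherited) + fresh(size - len(inherited))
        members.append(mem)
        k_share = round(cfg.crosstalk_overlap * size)
        if n == 1 or (n == 2 and i == 1):
            shares.append([])
            continue
        if i < n - 1:
            eligible = [g for g in mem if g not in inherited]
            idx = rng.choice(len(eligible), size=min(k_share, len(eligible)),
                             replace=False)
            shares.append([eligible[j] for j in sorted(idx)])
        else:
            # close the ring: the last pathway adopts genes from pathway 0
            eligible = [g for g in members[0]
                        if g not in shares[0] and g not in mem]
            idx = rng.choice(len(eligible), size=min(k_share, len(eligible)),
                             replace=False)
            adopted = [eligible[j] for j in sorted(idx)]
            # replace an equal number of this pathway's fresh genes
            replaceable = [g for g in mem if g not in inherited]
            mem[:] = [g for g in mem if g not in replaceable[:len(adopted)]]
            mem.extend(adopted)
            shares.append(adopted)

    pathways = []
    for i in range(n):
        mem = sorted(members[i])
        edges = _connected_er(mem, rng)
        pathways.append(Pathway(f"pw{i + 1:02d}", f"synthetic pathway {i + 1}",
                                set(mem), edges))
    return PathwayCollection(pathways)


def planted_pathway_indices(cfg: SimConfig) -> list[int]:
    """Evenly spaced indices of the dysregulated pathways."""
    if cfg.effect_delta == 0 or cfg.n_dysregulated == 0:
        return []
    n, k = cfg.n_pathways, cfg.n_dysregulated
    return sorted({int(round(j * n / k)) % n for j in range(k)})


def simulate_counts(
    cfg: SimConfig, pathways: PathwayCollection
) -> tuple[CountMatrix, CountMatrix, SimTruth]:
    """Draw mRNA and lncRNA NB count matrices with planted structure.

    Case samples receive a +``effect_delta`` log2 shift on the affected
    fraction of each dysregulated pathway's members; coexpression modules
    are induced by a shared per-sample latent factor with log-normal
    loadings (scaled by ``module_factor_sd``); every gene additionally
    carries weak background co-regulation (a sparse factor model), giving
    the transcriptome the heavy-tailed coexpression-degree distribution
    the soft-threshold scan expects of real data. Planted DE lncRNAs are
    shifted by +/- ``lnc_de_lfc`` in cases. Batch labels are assigned
    round-robin and carry no effect unless ``batch_effect_sd`` > 0.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    genes = mrna_ids(cfg)
    lncs = lnc_ids(cfg)

    samples = [f"AD_{i + 1:03d}" for i in range(cfg.n_case)] + [
        f"CT_{i + 1:03d}" for i in range(cfg.n_control)
    ]
    group = ["AD"] * cfg.n_case + ["control"] * cfg.n_control
    batch = [i % cfg.n_batches for i in range(len(samples))]
    pheno = pd.DataFrame({"group": group, "batch": batch},
                         index=pd.Index(samples, name="sample"))
    case_mask = np.array([g == "AD" for g in group])

    truth = SimTruth()

    # --- dysregulated pathways and affected genes
    planted_idx = planted_pathway_indices(cfg)
    affected: set[str] = set()
    # alternate the direction of dysregulation between planted pathways so
    # composition-sensitive normalisation (TPM) stays unbiased globally
    for pos, i in enumerate(planted_idx):
        pw = pathways.pathways[i]
        sign = 1 if pos % 2 == 0 else -1
        mem = sorted(pw.genes)
        k = round(cfg.affected_fraction * len(mem))
        pick = rng.choice(len(mem), size=k, replace=False)
        chosen = {mem[j] for j in sorted(pick)}
        affected |= chosen
        for g in chosen:
            truth.affected_direction[g] = sign
        truth.dysregulated_pathway_ids.append(pw.id)
    truth.affected_genes = sorted(affected)

    # --- DE lncRNAs
    n_de = round(cfg.lnc_de_fraction * cfg.n_lnc)
    de_pick = rng.choice(cfg.n_lnc, size=n_de, replace=False)
    de_lnc = [lncs[j] for j in sorted(de_pick)]
    signs = rng.choice([1, -1], size=n_de)
    if cfg.lnc_de_lfc != 0:
        truth.de_lnc_ids = {g: int(s) for g, s in zip(de_lnc, signs)}

    # --- coexpression modules over dysregulated-pathway mRNAs + DE lncRNAs
    n_mod_lnc = round(cfg.module_size * cfg.module_lnc_fraction)
    n_mod_mrna = cfg.module_size - n_mod_lnc
    pool_src = truth.dysregulated_pathway_ids or pathways.ids
    mrna_pool = sorted(set().union(*(pathways[pid].genes for pid in pool_src)))
    mrna_pool = [str(g) for g in rng.permutation(mrna_pool)]
    spill = [g for g in genes if g not in set(mrna_pool)]
    mrna_pool += [str(g) for g in rng.permutation(spill)]
    lnc_pool = [str(g) for g in rng.permutation(de_lnc)]
    lnc_pool += [l for l in lncs if l not in set(lnc_pool)]

    module_of: dict[str, int] = {}
    for m in range(cfg.n_modules):
        for g in mrna_pool[m * n_mod_mrna:(m + 1) * n_mod_mrna]:
            module_of[g] = m
        for l in lnc_pool[m * n_mod_lnc:(m + 1) * n_mod_lnc]:
            module_of[l] = m
    truth.module_assignments = module_of

    # --- prognostic genes: two module-0 mRNAs (module members by invariant)
    if cfg.n_modules > 0:
        prog = mrna_pool[:2]
    else:
        prog = sorted(mrna_pool[:2])
    truth.prognostic_genes = {prog[0]: cfg.prognostic_coefs[0],
                              prog[1]: cfg.prognostic_coefs[1]}

    # --- autophagy gene list: planted pathways are autophagy-rich, and the
    # autophagy genes concentrate in module 0 (the module carrying the
    # prognostic genes), mirroring an analysis module selected for its
    # autophagy content
    auto: set[str] = set(prog)
    shared = _multi_membership(pathways)
    module0 = {g for g, m in module_of.items() if m == 0}
    for pid in truth.dysregulated_pathway_ids:
        exclusive = sorted(pathways[pid].genes - shared)
        preferred = [g for g in exclusive if g in module0]
        other = [g for g in exclusive if g not in module0]
        take = preferred[:AUTOPHAGY_PER_PLANTED]
        short = AUTOPHAGY_PER_PLANTED - len(take)
        if short > 0 and other:
            pick = rng.choice(len(other), size=min(short, len(other)),
                              replace=False)
            take += [other[j] for j in sorted(pick)]
        auto |= set(take)
    bg = rng.choice(cfg.n_genes, size=AUTOPHAGY_BACKGROUND, replace=False)
    auto |= {genes[j] for j in sorted(bg)}
    truth.autophagy_genes = sorted(auto)

    # --- assemble log2 means
    lo, hi = cfg.base_log2_range
    mu_m = rng.uniform(lo, hi, size=cfg.n_genes)
    mu_l = rng.uniform(lo, hi, size=cfg.n_lnc)

    log2_m = np.tile(mu_m[:, None], (1, len(samples)))
    log2_l = np.tile(mu_l[:, None], (1, len(samples)))

    gene_index = {g: i for i, g in enumerate(genes)}
    lnc_index = {l: i for i, l in enumerate(lncs)}

    if cfg.effect_delta != 0:
        case_cols = np.where(case_mask)[0]
        for g in truth.affected_genes:
            log2_m[gene_index[g], case_cols] += (
                truth.affected_direction[g] * cfg.effect_delta)

    if cfg.lnc_de_lfc != 0:
        for g, s in truth.de_lnc_ids.items():
            log2_l[lnc_index[g], case_mask] += s * cfg.lnc_de_lfc

    if cfg.n_modules > 0:
        factors = rng.standard_normal((cfg.n_modules, len(samples)))
        prog_set = set(truth.prognostic_genes)
        for g, m in module_of.items():
            if g in prog_set:
                loading = cfg.module_factor_sd * PROGNOSTIC_LOADING
            else:
                loading = cfg.module_factor_sd * rng.lognormal(
                    MODULE_LOADING_MU, MODULE_LOADING_SIGMA)
            if g in gene_index:
                log2_m[gene_index[g]] += loading * factors[m]
            else:
                log2_l[lnc_index[g]] += loading * factors[m]

    if cfg.bg_factor_sd > 0:
        bg = rng.standard_normal((N_BG_FACTORS, len(samples)))
        for mat, n_rows in ((log2_m, cfg.n_genes), (log2_l, cfg.n_lnc)):
            for i in range(n_rows):
                k = min(rng.poisson(BG_MEMBERSHIP_RATE), N_BG_FACTORS)
                if k == 0:
                    continue
                for f in rng.choice(N_BG_FACTORS, size=k, replace=False):
                    # signed loadings: background co-regulation includes
                    # repression, and gene-level offsets stay incoherent
                    mat[i] += rng.normal(0.0, cfg.bg_factor_sd) * bg[f]

    if cfg.batch_effect_sd > 0:
        offsets = rng.normal(0.0, cfg.batch_effect_sd, size=cfg.n_batches)
        log2_m += offsets[np.array(batch)][None, :]
        log2_l += offsets[np.array(batch)][None, :]

    counts_m = _nb_counts(log2_m, cfg.nb_dispersion, rng)
    counts_l = _nb_counts(log2_l, cfg.nb_dispersion, rng)

    mrna = CountMatrix(pd.DataFrame(counts_m, index=genes, columns=samples), pheno)
    lnc = CountMatrix(pd.DataFrame(counts_l, index=lncs, columns=samples), pheno.copy())
    return mrna, lnc, truth


def _multi_membership(pathways: PathwayCollection) -> set[str]:
    seen: set[str] = set()
    multi: set[str] = set()
    for p in pathways:
        multi |= p.genes & seen
        seen |= p.genes
    return multi


def _nb_counts(log2_mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    mean = np.exp2(log2_mean)
    if dispersion > 0:
        lam = rng.gamma(1.0 / dispersion, mean * dispersion)
    else:
        lam = mean
    return rng.poisson(lam).astype(np.int64)


def simulate_lengths(cfg: SimConfig) -> pd.Series:
    """Gene lengths (bp) for the full mRNA + lncRNA universe."""
    rng = _rng(cfg, 3)
    all_genes = mrna_ids(cfg) + lnc_ids(cfg)
    return pd.Series(rng.integers(500, 5001, size=len(all_genes)),
                     index=all_genes, name="length")


def simulate_survival(cfg: SimConfig, mrna: CountMatrix, truth: SimTruth,
                      lengths: pd.Series | None = None) -> pd.DataFrame:
    """Exponential proportional-hazards survival for the case samples.

    The event rate for sample s is ``baseline_hazard * exp(sum_k coef_k *
    z_ks)`` with z the standardized log2 expression of the planted
    prognostic genes, on the same normalised scale the analysis reads
    (log2(TPM+1) when ``lengths`` are supplied, log2(count+1) otherwise);
    censoring time is Uniform(0, censor_horizon). Clinical severity scores
    (braaksc 0-6, ceradsc 1-4, dcfdx_lv 1-6) are drawn with probabilities
    weakly increasing in the linear predictor.
    """
    rng = _rng(cfg, 2)
    case_samples = [s for s, g in zip(mrna.sample_ids, mrna.pheno["group"])
                    if g == "AD"]
    if not case_samples:
        raise ConfigError("no case samples: cannot simulate survival")
    missing = [g for g in truth.prognostic_genes if g not in mrna.counts.index]
    if missing:
        raise ConfigError(f"prognostic genes missing from matrix: {missing}")

    if lengths is not None:
        from .preprocess import tpm_normalize

        tpm = tpm_normalize(mrna, lengths, log_transform=True)
        expr = tpm.loc[list(truth.prognostic_genes),
                       case_samples].to_numpy()
    else:
        expr = np.log2(mrna.counts.loc[list(truth.prognostic_genes),
                                       case_samples].to_numpy() + 1.0)
    sd = expr.std(axis=1)
    sd[sd == 0] = 1.0
    z = (expr - expr.mean(axis=1, keepdims=True)) / sd[:, None]
    coefs = np.array(list(truth.prognostic_genes.values()))
    lp = coefs @ z

    rate = cfg.baseline_hazard * np.exp(lp)
    n = len(case_samples)
    with np.errstate(divide="ignore"):
        t_event = np.where(rate > 0, rng.exponential(1.0, size=n) / np.maximum(rate, 1e-300), np.inf)
    t_cens = rng.uniform(0.0, cfg.censor_horizon, size=n) if cfg.censor_horizon > 0 \
        else np.zeros(n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    # risk percentile drives severity scores (weakly increasing)
    order = pd.Series(lp).rank(method="average").to_numpy()
    rho = (order - 1) / max(n - 1, 1)
    braaksc = rng.binomial(6, np.clip(0.25 + 0.5 * rho, 0, 1))
    ceradsc = 1 + rng.binomial(3, np.clip(0.3 + 0.3 * rho, 0, 1))
    dcfdx = 1 + rng.binomial(5, np.clip(0.25 + 0.3 * rho, 0, 1))

    n_train = round(cfg.train_fraction * n)
    perm = rng.permutation(n)
    split = np.array(["test"] * n, dtype=object)
    split[perm[:n_train]] = "train"

    return pd.DataFrame(
        {
            "time_years": time,
            "event": event,
            "braaksc": braaksc,
            "ceradsc": ceradsc,
            "dcfdx_lv": dcfdx,
            "split": split,
        },
        index=pd.Index(case_samples, name="sample"),
    )


def simulate_all(cfg: SimConfig, outdir: str | Path):
    """Run the full generator and write every pipeline input to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pathways = simulate_pathways(cfg)
    mrna, lnc, truth = simulate_counts(cfg, pathways)
    lengths = simulate_lengths(cfg)
    surv = simulate_survival(cfg, mrna, truth, lengths=lengths)

    pio.write_counts(mrna, outdir / "mrna_counts.tsv", outdir / "pheno.tsv")
    pio.write_counts(lnc, outdir / "lnc_counts.tsv")
    pio.write_gmt(pathways, outdir / "pathways.gmt")
    pio.write_edges(pathways, outdir / "pathway_edges.tsv")
    pio.write_gene_lengths(lengths, outdir / "gene_lengths.tsv")
    pio.write_gene_list(sorted(truth.autophagy_genes), outdir / "autophagy_genes.txt")
    pio.write_survival(surv, outdir / "survival.tsv")
    pio.write_json(truth.to_dict(), outdir / "truth.json")
    return pathways, mrna, lnc, truth, surv
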