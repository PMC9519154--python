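"""End-to-end orchestration of the analysis stages over one run directory.

Stage order: simulate -> preprocess -> de_lnc -> pagi -> crosstalk ->
coexpr -> enrich -> prognosis. Every stage reads and writes plain-text files
in the run directory; a JSON manifest records the configuration, the seed,
per-stage output hashes, warnings and timing, so identical configurations
reproduce identical file hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpr as cx
from . import crosstalk as ct
from . import enrich as en
from . import io as pio
from . import pagi
from . import preprocess as pp
from . import prognosis as pg
from . import synthio
from .config import RunConfig

logger = logging.getLogger(__name__)


class DependencyError(RuntimeError):
    """An upstream output required by a stage is missing."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, d: Path) -> None:
    synthio.simulate_all(cfg.sim, d)


def stage_preprocess(cfg: RunConfig, d: Path) -> None:
    m = pio.read_counts(d / "mrna_counts.tsv", d / "pheno.tsv")
    lengths = pio.read_gene_lengths(d / "gene_lengths.tsv")
    filtered = pp.cpm_filter(m, cfg.pipeline.cpm_threshold,
                             cfg.pipeline.cpm_fraction)
    expr = pp.tpm_normalize(filtered, lengths, log_transform=True)
    pio.write_matrix(expr, d / "mrna_expr.tsv")


def stage_de_lnc(cfg: RunConfig, d: Path) -> None:
    lnc = pio.read_counts(d / "lnc_counts.tsv", d / "pheno.tsv")
    de, sf = pp.de_lncrna(lnc, cfg.pipeline.de_p, cfg.pipeline.de_lfc)
    de.to_csv(d / "de_lncrna.tsv", sep="\t", float_format=pio.FLOAT_FMT)
    y = np.log2(lnc.counts.to_numpy(dtype=float)
                / sf.to_numpy()[None, :] + 1.0)
    pio.write_matrix(pd.DataFrame(y, index=lnc.counts.index,
                                  columns=lnc.counts.columns),
                     d / "lnc_expr.tsv")


def stage_pagi(cfg: RunConfig, d: Path) -> None:
    expr = pio.read_matrix(d / "mrna_expr.tsv")
    pheno = pd.read_csv(d / "pheno.tsv", sep="\t", index_col=0)
    pc = pio.read_pathways(d / "pathways.gmt", d / "pathway_edges.tsv")
    net = pagi.build_global_network(pc)
    scores, influence = pagi.permutation_fdr(
        expr, pheno["group"], net, pc,
        n_permutations=cfg.pipeline.n_permutations,
        r=cfg.pipeline.restart_prob, seed=cfg.sim.seed,
        permute_gds=cfg.pipeline.permute_gds,
        fdr_cut=cfg.pipeline.fdr_cut, tol=cfg.pipeline.rwr_tol,
        max_iter=cfg.pipeline.rwr_max_iter)
    autophagy = pio.read_gene_list(d / "autophagy_genes.txt")
    scores = ct.annotate_autophagy(scores, pc, autophagy)
    scores.to_csv(d / "pathway_scores.tsv", sep="\t",
                  float_format=pio.FLOAT_FMT)
    influence.to_csv(d / "gene_influence.tsv", sep="\t",
                     float_format=pio.FLOAT_FMT)


def stage_crosstalk(cfg: RunConfig, d: Path) -> None:
    scores = pd.read_csv(d / "pathway_scores.tsv", sep="\t", index_col=0)
    pc = pio.read_pathways(d / "pathways.gmt", d / "pathway_edges.tsv")
    expr = pio.read_matrix(d / "mrna_expr.tsv")
    influence = pio.read_matrix(d / "gene_influence.tsv")
    sel = ct.select_features(scores, pc, expr.index,
                             min_autophagy=cfg.pipeline.min_autophagy,
                             fdr_cut=cfg.pipeline.fdr_cut)
    scores.loc[sel.feature_pathways].to_csv(
        d / "feature_pathways.tsv", sep="\t", float_format=pio.FLOAT_FMT)
    pio.write_gene_list(sel.feature_mrnas, d / "feature_mrnas.txt")
    top = ct.top_genes_per_pathway(sel, pc, influence, k=cfg.pipeline.top_k)
    ct.pathway_gene_table(top, influence).to_csv(
        d / "pathway_gene_network.tsv", sep="\t", index=False,
        float_format=pio.FLOAT_FMT)


def _coexpr_input(d: Path) -> pd.DataFrame:
    feature = pio.read_gene_list(d / "feature_mrnas.txt")
    expr = pio.read_matrix(d / "mrna_expr.tsv")
    de = pd.read_csv(d / "de_lncrna.tsv", sep="\t", index_col=0)
    lnc_expr = pio.read_matrix(d / "lnc_expr.tsv")
    sig_lnc = [g for g in de.index[de["significant"]] if g in lnc_expr.index]
    rows = [expr.loc[[g for g in feature if g in expr.index]],
            lnc_expr.loc[sig_lnc]]
    return pd.concat(rows)


def stage_coexpr(cfg: RunConfig, d: Path) -> None:
    expr = _coexpr_input(d)
    assignment, scan = cx.build_modules(
        expr, r2_threshold=cfg.pipeline.r2_threshold,
        beta_max=cfg.pipeline.beta_max,
        min_size=cfg.pipeline.min_module_size,
        merge_height=cfg.pipeline.merge_height)
    out = assignment.labels.to_frame()
    out["type"] = ["lncRNA" if g.startswith("LNC") else "mRNA"
                   for g in out.index]
    out.to_csv(d / "modules.tsv", sep="\t")
    pio.write_matrix(assignment.eigengenes, d / "eigengenes.tsv",
                     index_name="module")
    scan.as_frame().to_csv(d / "soft_threshold_scan.tsv", sep="\t",
                           float_format=pio.FLOAT_FMT)


def _load_module_labels(d: Path) -> pd.Series:
    labels = pd.read_csv(d / "modules.tsv", sep="\t", index_col=0)["module"]
    if (labels == cx.UNASSIGNED).all():
        # robustness fallback: with no module passing the size cut, carry
        # the whole coexpression input forward as a single module
        logger.warning("no coexpression module passed the size cut; "
                       "treating the full input gene set as one module")
        labels = pd.Series(1, index=labels.index, name="module")
    return labels


def stage_enrich(cfg: RunConfig, d: Path) -> None:
    eig = pio.read_matrix(d / "eigengenes.tsv")
    labels = _load_module_labels(d)
    assignment = cx.ModuleAssignment(labels, eig)
    pc = pio.read_pathways(d / "pathways.gmt", d / "pathway_edges.tsv")
    autophagy = pio.read_gene_list(d / "autophagy_genes.txt")
    background = list(labels.index)
    table = en.enrich_modules(assignment, pc, background,
                              p_cut=cfg.pipeline.enrich_p,
                              q_cut=cfg.pipeline.enrich_q)
    table.to_csv(d / "enrichment.tsv", sep="\t", index=False,
                 float_format=pio.FLOAT_FMT)
    # reference disease pathway = top |score| among FDR-significant pathways
    scores = pd.read_csv(d / "pathway_scores.tsv", sep="\t", index_col=0)
    cand = scores[scores["fdr"] < cfg.pipeline.fdr_cut]
    if len(cand) == 0:
        cand = scores
    ad_pid = cand["score"].abs().idxmax()
    chosen, counts = en.select_module(assignment, autophagy,
                                      pc[ad_pid].genes)
    (d / "selected_module.txt").write_text(f"{chosen}\n")
    counts["reference_pathway"] = str(ad_pid)
    pio.write_json(counts, d / "venn_counts.json")


def stage_prognosis(cfg: RunConfig, d: Path) -> None:
    labels = _load_module_labels(d)
    chosen = int((d / "selected_module.txt").read_text().strip())
    genes = list(labels.index[labels == chosen])
    expr = pd.concat([pio.read_matrix(d / "mrna_expr.tsv"),
                      pio.read_matrix(d / "lnc_expr.tsv")])
    genes = [g for g in genes if g in expr.index]
    surv = pio.read_survival(d / "survival.tsv")
    samples = [s for s in surv.index if s in expr.columns]
    surv = surv.loc[samples]
    train = list(surv.index[surv["split"] == "train"])
    test = list(surv.index[surv["split"] == "test"])

    z = pg.standardize_expression(expr.loc[genes, samples], train)
    uni = pg.univariate_cox(z[train], surv.loc[train],
                            p_cut=cfg.pipeline.uni_cox_p)
    uni.to_csv(d / "univariate_cox.tsv", sep="\t", float_format=pio.FLOAT_FMT)
    kept = list(uni.index[uni["keep"]])
    if not kept:
        # robustness fallback: relax the screen to the strongest candidates
        # rather than abort the run
        logger.warning("no gene passed the univariate Cox screen at p < %g; "
                       "relaxing to the 10 smallest p-values",
                       cfg.pipeline.uni_cox_p)
        kept = list(uni.sort_values("p").index[:10])
    if not kept:
        raise pio.DataError("univariate Cox screen produced no usable gene")
    # events-per-variable safeguard: keep the multivariate input
    # identifiable by truncating to the strongest univariate hits
    max_covariates = max(2, int(surv.loc[train, "event"].sum()) // 2)
    if len(kept) > max_covariates:
        logger.warning("%d genes passed the screen; truncating the "
                       "multivariate input to the top %d by p-value",
                       len(kept), max_covariates)
        kept = list(uni.loc[kept].sort_values("p").index[:max_covariates])
    model = pg.stepwise_cox(z.loc[kept], surv, train_samples=train)
    pio.write_json(model.to_dict(), d / "risk_model.json")

    split_tbl = pg.risk_split(model, z, surv)
    split_tbl.to_csv(d / "risk_scores.tsv", sep="\t",
                     float_format=pio.FLOAT_FMT)

    km_out, forest_rows, auc_rows = {}, [], []
    for name, idx in (("train", train), ("test", test)):
        if not idx:
            continue
        classes = split_tbl.loc[idx, "risk_class"]
        if classes.nunique() == 2:
            km = pg.km_logrank(surv.loc[idx], classes)
            km_out[name] = {"statistic": km["statistic"], "p": km["p"]}
        try:
            forest = pg.independent_prognostic(surv.loc[idx],
                                               split_tbl.loc[idx, "riskScore"])
            forest["split"] = name
            forest_rows.append(forest.reset_index())
        except pio.DataError as exc:
            logger.warning("forest fit skipped for %s: %s", name, exc)
        aucs = pg.time_dependent_auc(surv.loc[idx], surv.loc[idx],
                                     split_tbl.loc[idx, "riskScore"],
                                     cfg.pipeline.roc_times)
        for t, a in aucs.items():
            auc_rows.append({"split": name, "index": "riskScore",
                             "time": t, "AUC": a})
        multi = pg.multi_index_auc(surv.loc[idx], surv.loc[idx],
                                   split_tbl.loc[idx, "riskScore"],
                                   max(cfg.pipeline.roc_times))
        for key, a in multi.items():
            auc_rows.append({"split": name, "index": key,
                             "time": max(cfg.pipeline.roc_times), "AUC": a})
    pio.write_json(km_out, d / "km_logrank.json")
    if forest_rows:
        pd.concat(forest_rows, ignore_index=True).to_csv(
            d / "forest.tsv", sep="\t", index=False,
            float_format=pio.FLOAT_FMT)
    else:
        (d / "forest.tsv").write_text("covariate\tcoef\tHR\tHR_lower_95\t"
                                      "HR_upper_95\tp\tsplit\n")
    pd.DataFrame(auc_rows).to_csv(d / "td_auc.tsv", sep="\t", index=False,
                                  float_format=pio.FLOAT_FMT)


STAGES: list[tuple[str, list[str], callable]] = [
    ("simulate", [], stage_simulate),
    ("preprocess", ["mrna_counts.tsv", "pheno.tsv", "gene_lengths.tsv"],
     stage_preprocess),
    ("de_lnc", ["lnc_counts.tsv", "pheno.tsv"], stage_de_lnc),
    ("pagi", ["mrna_expr.tsv", "pheno.tsv", "pathways.gmt",
              "pathway_edges.tsv", "autophagy_genes.txt"], stage_pagi),
    ("crosstalk", ["pathway_scores.tsv", "gene_influence.tsv",
                   "pathways.gmt", "mrna_expr.tsv"], stage_crosstalk),
    ("coexpr", ["feature_mrnas.txt", "mrna_expr.tsv", "de_lncrna.tsv",
                "lnc_expr.tsv"], stage_coexpr),
    ("enrich", ["modules.tsv", "eigengenes.tsv", "pathways.gmt",
                "autophagy_genes.txt", "pathway_scores.tsv"], stage_enrich),
    ("prognosis", ["modules.tsv", "selected_module.txt", "mrna_expr.tsv",
                   "lnc_expr.tsv", "survival.tsv"], stage_prognosis),
]

_PRODUCER = {
    "mrna_counts.tsv": "simulate", "lnc_counts.tsv": "simulate",
    "pheno.tsv": "simulate", "gene_lengths.tsv": "simulate",
    "pathways.gmt": "simulate", "pathway_edges.tsv": "simulate",
    "autophagy_genes.txt": "simulate", "survival.tsv": "simulate",
    "truth.json": "simulate",
    "mrna_expr.tsv": "preprocess",
    "de_lncrna.tsv": "de_lnc", "lnc_expr.tsv": "de_lnc",
    "pathway_scores.tsv": "pagi", "gene_influence.tsv": "pagi",
    "feature_pathways.tsv": "crosstalk", "feature_mrnas.txt": "crosstalk",
    "pathway_gene_network.tsv": "crosstalk",
    "modules.tsv": "coexpr", "eigengenes.tsv": "coexpr",
    "soft_threshold_scan.tsv": "coexpr",
    "enrichment.tsv": "enrich", "selected_module.txt": "enrich",
    "venn_counts.json": "enrich",
    "univariate_cox.tsv": "prognosis", "risk_model.json": "prognosis",
    "risk_scores.tsv": "prognosis", "km_logrank.json": "prognosis",
    "forest.tsv": "prognosis", "td_auc.tsv": "prognosis",
}

STAGE_NAMES = [name for name, _, _ in STAGES]


def run_all(cfg: RunConfig, outdir: str | Path, seed: int | None = None,
            from_stage: str | None = None) -> dict:
    """Execute the pipeline and return the run manifest.

    ``seed`` overrides the configured simulation/permutation seed;
    ``from_stage`` resumes mid-pipeline, verifying that every input the
    remaining stages need already exists (a missing file raises
    :class:`DependencyError` naming the stage that produces it).
    """
    d = Path(outdir)
    d.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        cfg = RunConfig(sim=cfg.sim.replace(seed=seed), pipeline=cfg.pipeline)
    start_at = 0
    if from_stage is not None:
        if from_stage not in STAGE_NAMES:
            raise ValueError(f"unknown stage {from_stage!r}; "
                             f"expected one of {STAGE_NAMES}")
        start_at = STAGE_NAMES.index(from_stage)

    handler = logging.FileHandler(d / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s "
                                           "%(levelname)s %(message)s"))
    root = logging.getLogger("pagicross")
    root.addHandler(handler)
    manifest = {
        "config": {"sim": dataclasses.asdict(cfg.sim),
                   "pipeline": dataclasses.asdict(cfg.pipeline)},
        "seed": cfg.sim.seed,
        "stages": {},
    }
    try:
        for name, inputs, func in STAGES[start_at:]:
            for f in inputs:
                if not (d / f).exists():
                    raise DependencyError(
                        f"stage '{name}' needs {f}, which is produced by "
                        f"stage '{_PRODUCER.get(f, '?')}' — run that first")
            t0 = time.perf_counter()
            logger.info("running stage %s", name)
            func(cfg, d)
            outputs = sorted(f for f, prod in _PRODUCER.items()
                             if prod == name and (d / f).exists())
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": {f: _sha256(d / f) for f in outputs},
            }
    finally:
        root.removeHandler(handler)
        handler.close()
    pio.write_json(manifest, d / "manifest.json")
    return manifest
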