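"""Configuration objects for the simulator and the analysis pipeline.

Two dataclasses govern everything: :class:`SimConfig` describes the synthetic
cohort (what is planted, how strongly, and at what sample size) and
:class:`PipelineConfig` carries every analysis threshold, defaulting to the
values the pipeline is designed around (CPM >= 1 in > 50% of samples,
DE at p < 0.05 and |log2FC| > 0.5, pathway FDR < 0.01, scale-free fit
R^2 > 0.85, minimum module size 50, eigengene merge height 0.25,
univariate Cox p < 0.01).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The defaults describe the study conditions the pipeline is exercised
    under: a two-group (AD vs control) negative-binomial count cohort with
    nine sequencing batches, twenty pathways of 80-120 genes arranged in a
    crosstalk ring (each sharing 20% of its genes with its successor), four
    dysregulated pathways with half of their members shifted by one log2
    unit, three latent-factor coexpression modules of 120 genes spanning
    mRNAs and DE lncRNAs, and exponential proportional-hazards survival for
    case samples driven by two planted protective genes (coefficients
    -1.13 and -1.41). Default sample counts mirror the cohort being
    emulated: 155 cases, 86 controls, with 40% of cases in the training
    split of the survival table.
    """

    n_genes: int = 2000
    n_lnc: int = 300
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (80, 120)
    crosstalk_overlap: float = 0.2
    n_dysregulated: int = 4
    effect_delta: float = 1.0
    affected_fraction: float = 0.5
    n_case: int = 155
    n_control: int = 86
    n_batches: int = 9
    nb_dispersion: float = 0.2
    n_modules: int = 3
    module_size: int = 120
    module_lnc_fraction: float = 1.0 / 6.0
    module_factor_sd: float = 1.0
    # strength of the sparse background co-regulation shared by all genes
    bg_factor_sd: float = 0.35
    lnc_de_fraction: float = 0.25
    lnc_de_lfc: float = 1.0
    prognostic_coefs: tuple[float, float] = (-1.13, -1.41)
    baseline_hazard: float = 0.15
    censor_horizon: float = 10.0
    train_fraction: float = 0.4
    # log2 baseline abundance range for genes
    base_log2_range: tuple[float, float] = (3.0, 9.0)
    # robustness-testing hook only; the default cohort carries batch labels
    # but no batch effect
    batch_effect_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi):
            raise ConfigError("pathway_size_range must satisfy 0 < min <= max")
        if hi > self.n_genes:
            raise ConfigError(
                f"pathway_size_range max ({hi}) exceeds n_genes ({self.n_genes})"
            )
        for name in ("crosstalk_overlap", "affected_fraction",
                     "module_lnc_fraction", "lnc_de_fraction",
                     "train_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_dysregulated > self.n_pathways:
            raise ConfigError("n_dysregulated cannot exceed n_pathways")
        if self.n_case < 0 or self.n_control < 0:
            raise ConfigError("sample counts must be non-negative")
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        if len(self.prognostic_coefs) != 2:
            raise ConfigError("prognostic_coefs must hold exactly two values")
        if self.censor_horizon < 0:
            raise ConfigError("censor_horizon must be non-negative")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """Analysis thresholds for every pipeline stage."""

    cpm_threshold: float = 1.0
    cpm_fraction: float = 0.5
    de_p: float = 0.05
    de_lfc: float = 0.5
    restart_prob: float = 0.7
    rwr_tol: float = 1e-10
    rwr_max_iter: int = 1000
    n_permutations: int = 1000
    permute_gds: bool = False
    fdr_cut: float = 0.01
    min_autophagy: int = 5
    top_k: int = 20
    r2_threshold: float = 0.85
    beta_max: int = 20
    min_module_size: int = 50
    merge_height: float = 0.25
    enrich_p: float = 0.05
    enrich_q: float = 0.05
    uni_cox_p: float = 0.01
    roc_times: tuple[float, ...] = (3.0, 5.0)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class RunConfig:
    """Top-level configuration: simulation plus analysis settings."""

    sim: SimConfig = field(default_factory=SimConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)


def _coerce(cls, mapping: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in mapping.items():
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration with ``sim:`` and ``pipeline:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = _coerce(SimConfig, raw.get("sim", {}))
    sim.validate()
    pipe = _coerce(PipelineConfig, raw.get("pipeline", {}))
    return RunConfig(sim=sim, pipeline=pipe)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = {
        "sim": dataclasses.asdict(cfg.sim),
        "pipeline": dataclasses.asdict(cfg.pipeline),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
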