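"""End-to-end orchestration of the analysis stages.

Stage order: simulate (optional) -> filter -> normalize -> de -> network ->
connectivity -> enrich -> phenotype/behaviour.  Each enabled stage reads the
previous stage's outputs from the run directory, writes its own outputs
there, and logs the thresholds it applied.  A :class:`RunManifest` with the
configuration hash and per-file checksums is written atomically at the end,
so deterministic stages can be verified to reproduce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .connectivity import (
    DifferentialConnectivity,
    bonferroni_threshold,
    format_threshold,
)
from .de import NegativeBinomialExposureLRT
from .enrichment import module_enrichment
from .network import SignedCoexpressionNetwork
from .phenotype import behaviour_tests, derive_health_metrics, health_tests
from .preprocessing import (
    filter_low_expression,
    log2_normalize,
    median_of_ratios_size_factors,
)
from .simulate import (
    SimulationConfig,
    simulate_behaviour,
    simulate_counts,
    simulate_design,
    simulate_fish_metrics,
    simulate_gene_metadata,
)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger("coexdiff")

STAGES = (
    "simulate",
    "filter",
    "normalize",
    "de",
    "network",
    "connectivity",
    "enrich",
    "phenotype",
    "behaviour",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative run configuration.  Unknown keys are rejected on load."""

    outdir: str = "results"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # inputs (ignored when the simulate stage is enabled)
    counts_path: str | None = None
    design_path: str | None = None
    lengths_path: str | None = None
    gmt_path: str | None = None
    phenotype_path: str | None = None
    behaviour_path: str | None = None
    # simulation
    n_genes: int = 2000
    n_per_group: int = 16
    # preprocessing
    min_count: int = 10
    min_samples: int = 16
    # differential expression
    fdr_threshold: float = 0.10
    # network
    beta: float = 12.0
    min_module_size: int = 20
    max_block_size: int = 5000
    # connectivity / enrichment / behaviour
    alpha: float = 0.05
    min_term_size: int = 10
    behaviour_n_tests: int = 18

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        order = [s for s in STAGES if s in self.stages]
        if order != self.stages:
            raise ValueError("stages must follow the pipeline order")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages_run: list[str]
    outputs: dict[str, str]  # relative path -> sha256
    started: float
    finished: float

    def write(self, path) -> None:
        """Atomic write (temp file + rename)."""
        payload = dataclasses.asdict(self)
        tmp = str(path) + ".tmp"
        Path(tmp).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(outdir: Path, filename: str, stage: str, needed_by: str) -> Path:
    p = outdir / filename
    if not p.exists():
        raise PipelineError(
            f"stage '{needed_by}' requires output '{filename}' of stage '{stage}', "
            f"which did not run"
        )
    return p


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    stages_run: list[str] = []

    for stage in config.stages:
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            _mark_partial(outdir, stage)
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        stages_run.append(stage)

    outputs = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and not p.name.endswith((".partial", ".tmp", "manifest.json"))
    }
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stages_run=stages_run,
        outputs=outputs,
        started=started,
        finished=time.time(),
    )
    manifest.write(outdir / "manifest.json")
    return manifest


_STAGE_OUTPUTS = {
    "simulate": ["counts.tsv", "design.csv", "gene_lengths.tsv", "categories.gmt",
                 "behaviour.tsv", "phenotype.csv", "truth.json"],
    "filter": ["counts_filtered.tsv"],
    "normalize": ["size_factors.csv", "expression.tsv"],
    "de": ["de_results.tsv"],
    "network": ["modules.tsv"],
    "connectivity": ["connectivity.tsv", "connectivity_anova.tsv"],
    "enrich": ["enrichment.tsv"],
    "phenotype": ["health_tests.tsv"],
    "behaviour": ["behaviour_tests.tsv"],
}


def _mark_partial(outdir: Path, stage: str) -> None:
    for name in _STAGE_OUTPUTS.get(stage, []):
        p = outdir / name
        if p.exists():
            p.rename(outdir / (name + ".partial"))


def _stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    sim = SimulationConfig(
        n_genes=config.n_genes, n_per_group=config.n_per_group, seed=config.seed
    )
    design = simulate_design(sim)
    counts, truth = simulate_counts(design, sim)
    lengths, categories = simulate_gene_metadata(sim, truth)
    behaviour = simulate_behaviour(design, seed=config.seed)
    phenotype = simulate_fish_metrics(design, seed=config.seed)
    cio.write_counts(counts, outdir / "counts.tsv")
    cio.write_design(design, outdir / "design.csv")
    cio.write_gene_lengths(lengths, outdir / "gene_lengths.tsv")
    cio.write_gmt(categories, outdir / "categories.gmt")
    cio.write_table(behaviour, outdir / "behaviour.tsv")
    cio.write_table(phenotype, outdir / "phenotype.csv", sep=",")
    cio.write_truth_json(truth, outdir / "truth.json")
    logger.info("stage simulate: %d genes x %d samples, seed %d",
                sim.n_genes, sim.n_samples, config.seed)


def _load_counts_design(config: PipelineConfig, outdir: Path, needed_by: str):
    if "simulate" in config.stages:
        counts = cio.read_counts(_require(outdir, "counts.tsv", "simulate", needed_by))
        design = cio.read_design(_require(outdir, "design.csv", "simulate", needed_by))
    else:
        if not (config.counts_path and config.design_path):
            raise PipelineError(
                f"stage '{needed_by}': counts_path and design_path must be set "
                f"when the simulate stage is disabled"
            )
        counts = cio.read_counts(config.counts_path)
        design = cio.read_design(config.design_path)
    return counts, design


def _stage_filter(config: PipelineConfig, outdir: Path) -> None:
    counts, _ = _load_counts_design(config, outdir, "filter")
    kept = filter_low_expression(counts, config.min_count, config.min_samples)
    cio.write_counts(kept, outdir / "counts_filtered.tsv")
    logger.info(
        "stage filter: >= %d reads in >= %d samples; kept %d / %d genes",
        config.min_count, config.min_samples, kept.shape[0], counts.shape[0],
    )


def _stage_normalize(config: PipelineConfig, outdir: Path) -> None:
    path = _require(outdir, "counts_filtered.tsv", "filter", "normalize")
    counts = cio.read_counts(path)
    size_factors = median_of_ratios_size_factors(counts)
    expr = log2_normalize(counts, size_factors)
    size_factors.to_csv(outdir / "size_factors.csv", lineterminator="\n")
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene",
                lineterminator="\n")
    logger.info("stage normalize: median-of-ratios size factors; log2(count/s + 1)")


def _stage_de(config: PipelineConfig, outdir: Path) -> None:
    counts = cio.read_counts(_require(outdir, "counts_filtered.tsv", "filter", "de"))
    _, design = _load_counts_design(config, outdir, "de")
    est = NegativeBinomialExposureLRT(fdr_threshold=config.fdr_threshold)
    est.fit(counts, design.loc[counts.columns])
    cio.write_table(est.results_.reset_index(), outdir / "de_results.tsv")
    logger.info(
        "stage de: NB-GLM LRT (exposure | sex + week); FDR threshold %.2f; "
        "%d significant genes", config.fdr_threshold, len(est.significant_),
    )


def _stage_network(config: PipelineConfig, outdir: Path) -> None:
    expr = pd.read_csv(_require(outdir, "expression.tsv", "normalize", "network"),
                       sep="\t", index_col=0)
    net = SignedCoexpressionNetwork(
        beta=config.beta,
        min_module_size=config.min_module_size,
        max_block_size=config.max_block_size,
        random_state=config.seed,
    )
    net.fit(expr)
    net.modules_.rename("module").to_csv(outdir / "modules.tsv", sep="\t",
                                         lineterminator="\n")
    n_modules = int(net.modules_.max())
    logger.info(
        "stage network: signed, beta = %g, min module size = %d, "
        "max block size = %d; %d modules",
        config.beta, config.min_module_size, config.max_block_size, n_modules,
    )


def _stage_connectivity(config: PipelineConfig, outdir: Path) -> None:
    expr = pd.read_csv(
        _require(outdir, "expression.tsv", "normalize", "connectivity"),
        sep="\t", index_col=0,
    )
    modules = pd.read_csv(
        _require(outdir, "modules.tsv", "network", "connectivity"),
        sep="\t", index_col=0,
    )["module"]
    _, design = _load_counts_design(config, outdir, "connectivity")
    dc = DifferentialConnectivity(beta=config.beta, alpha=config.alpha)
    dc.fit(expr, design.loc[expr.columns], modules)
    cio.write_table(dc.connectivity_, outdir / "connectivity.tsv")
    cio.write_table(dc.anova_.reset_index(), outdir / "connectivity_anova.tsv")
    n_tested = len(dc.anova_)
    if n_tested:
        thr = bonferroni_threshold(n_tested, config.alpha)
        logger.info(
            "stage connectivity: |r|^%g kWithin; ANOVA over %d modules; "
            "Bonferroni threshold %s (alpha %.2f / %d)",
            config.beta, n_tested, format_threshold(thr), config.alpha, n_tested,
        )


def _stage_enrich(config: PipelineConfig, outdir: Path) -> None:
    modules = pd.read_csv(
        _require(outdir, "modules.tsv", "network", "enrich"), sep="\t", index_col=0
    )["module"]
    anova = pd.read_csv(
        _require(outdir, "connectivity_anova.tsv", "connectivity", "enrich"), sep="\t"
    )
    if "simulate" in config.stages:
        lengths = cio.read_gene_lengths(_require(outdir, "gene_lengths.tsv",
                                                 "simulate", "enrich"))
        categories = cio.read_gmt(_require(outdir, "categories.gmt",
                                           "simulate", "enrich"))
    else:
        if not (config.lengths_path and config.gmt_path):
            raise PipelineError(
                "stage 'enrich': lengths_path and gmt_path must be set "
                "when the simulate stage is disabled"
            )
        lengths = cio.read_gene_lengths(config.lengths_path)
        categories = cio.read_gmt(config.gmt_path)
    significant = anova.loc[anova["significant"], "module"].astype(int)
    to_test = {
        int(m): set(modules.index[modules == m]) for m in significant
    }
    universe = list(modules.index)
    result, threshold = module_enrichment(
        to_test, categories, universe, lengths,
        alpha=config.alpha, min_term_size=config.min_term_size,
    )
    cio.write_table(result, outdir / "enrichment.tsv")
    if result.empty:
        logger.info("stage enrich: no connectivity-significant modules to test")
    else:
        family = result["term"].nunique()
        logger.info(
            "stage enrich: min term size %d; Bonferroni threshold %s "
            "(alpha %.2f / %d terms)",
            config.min_term_size, format_threshold(threshold), config.alpha, family,
        )


def _stage_phenotype(config: PipelineConfig, outdir: Path) -> None:
    if "simulate" in config.stages:
        path = _require(outdir, "phenotype.csv", "simulate", "phenotype")
    elif config.phenotype_path:
        path = Path(config.phenotype_path)
    else:
        raise PipelineError("stage 'phenotype': phenotype_path must be set")
    metrics = derive_health_metrics(pd.read_csv(path))
    res = health_tests(metrics)
    cio.write_table(res, outdir / "health_tests.tsv")
    logger.info("stage phenotype: exposure ANOVA per sex on %d metrics",
                res["metric"].nunique())


def _stage_behaviour(config: PipelineConfig, outdir: Path) -> None:
    if "simulate" in config.stages:
        path = _require(outdir, "behaviour.tsv", "simulate", "behaviour")
    elif config.behaviour_path:
        path = Path(config.behaviour_path)
    else:
        raise PipelineError("stage 'behaviour': behaviour_path must be set")
    records = pd.read_csv(path, sep="\t")
    res = behaviour_tests(records, n_tests=config.behaviour_n_tests, alpha=config.alpha)
    cio.write_table(res, outdir / "behaviour_tests.tsv")
    thr = bonferroni_threshold(config.behaviour_n_tests, config.alpha)
    logger.info(
        "stage behaviour: exposure ANOVA per zone x session; Bonferroni "
        "threshold %s (alpha %.2f / %d tests)",
        format_threshold(thr), config.alpha, config.behaviour_n_tests,
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "normalize": _stage_normalize,
    "de": _stage_de,
    "network": _stage_network,
    "connectivity": _stage_connectivity,
    "enrich": _stage_enrich,
    "phenotype": _stage_phenotype,
    "behaviour": _stage_behaviour,
}
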