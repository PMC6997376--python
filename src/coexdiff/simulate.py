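"""Synthetic data emulating a dose-response RNA-seq exposure study.

The generator reproduces the statistical structure the downstream analysis
assumes: a balanced three-group design (vehicle control plus a low and a
high dose, 16 fish per group, sexes and experimental weeks balanced within
group, two tanks per group and week), negative-binomial counts with
per-sample size factors, planted differentially expressed genes with
additive or opposite-direction dose patterns, planted co-expression modules
whose within-group correlation strength depends on dose, lognormal gene
lengths with optional length bias of membership, GMT-style category
annotations, multinomial tank-position observations with a dose-dependent
shift toward the top zone, and fish body metrics.

Every planted effect is recorded in a :class:`GroundTruth` object so that
parameter-recovery tests can compare estimates against the simulated truth.

Counts are drawn as NB(mean m, dispersion alpha) with variance m + alpha*m^2,
the same parameterisation the differential-expression stage fits.  Module
signal is added on the log2 scale before exponentiation, so planted
correlations survive the downstream log2(normalised count + 1) transform up
to an attenuation by the NB sampling noise (small at the default baseline
means).

Randomness: a single global seed; each generator component draws from its
own documented substream (spawn key), so stages can be regenerated
independently and in any order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModuleSpec",
    "DESpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_design",
    "simulate_counts",
    "simulate_gene_metadata",
    "simulate_behaviour",
    "simulate_fish_metrics",
    "default_zone_probs",
]

# substream indices of the global seed, one per generator component
_STREAM_COUNTS = 1
_STREAM_METADATA = 2
_STREAM_BEHAVIOUR = 3
_STREAM_METRICS = 4

# log2-mean cap guarding against overflow when exponentiating
_MAX_LOG2_MEAN = 30.0  # 2^30 ~ 1.07e9 expected counts


def _component_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic per-component substream of the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    Within an exposure group the module genes share one standard-normal
    latent factor per sample with loading ``loadings[group]`` on the log2
    scale, plus independent residual noise with standard deviation
    ``residual_sd``.  The expected within-group pairwise correlation is
    rho = lambda^2 / (lambda^2 + sigma^2).
    """

    size: int
    loadings: Mapping[str, float]
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        for group, lam in self.loadings.items():
            if lam < 0:
                raise ValueError(f"loading for group {group!r} must be >= 0")

    def rho(self, group: str) -> float:
        """Expected within-group pairwise correlation of module genes."""
        lam2 = self.loadings[group] ** 2
        return lam2 / (lam2 + self.residual_sd**2)

    @classmethod
    def from_rho(
        cls,
        size: int,
        rho_per_group: Mapping[str, float],
        residual_sd: float = 1.0,
    ) -> "ModuleSpec":
        """Build a spec from target within-group correlations."""
        loadings = {}
        for group, rho in rho_per_group.items():
            if not 0 <= rho < 1:
                raise ValueError("rho must lie in [0, 1)")
            loadings[group] = residual_sd * math.sqrt(rho / (1.0 - rho))
        return cls(size=size, loadings=loadings, residual_sd=residual_sd)


@dataclass(frozen=True)
class DESpec:
    """Planted differential expression: log2 shifts of the dosed groups
    relative to control.  Same-sign values give an additive dose pattern,
    opposite signs the opposite-direction pattern."""

    n_genes: int
    log2fc_low: float
    log2fc_high: float

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")


def _default_modules() -> list[ModuleSpec]:
    # dose-dependent connectivity gain, loss, and a stable module
    return [
        ModuleSpec.from_rho(50, {"control": 0.1, "low": 0.4, "high": 0.8}),
        ModuleSpec.from_rho(50, {"control": 0.7, "low": 0.4, "high": 0.3}),
        ModuleSpec.from_rho(50, {"control": 0.5, "low": 0.5, "high": 0.5}),
    ]


def _default_de() -> list[DESpec]:
    return [
        DESpec(10, 0.8, 1.2),    # additive up
        DESpec(10, -0.5, -0.8),  # additive down
        DESpec(5, -0.8, 0.4),    # opposite directions
    ]


@dataclass
class SimulationConfig:
    """Study-design and generative parameters.

    Defaults emulate the analysed design: three groups (vehicle control,
    low dose, high dose) of 16 fish each, half male, split over two weeks
    with two tanks per group and week.
    """

    n_genes: int = 2000
    groups: tuple[str, ...] = ("control", "low", "high")
    n_per_group: int = 16
    sex_balance: float = 0.5
    n_weeks: int = 2
    baseline_log2_mean_mu: float = 6.0
    baseline_log2_mean_sd: float = 2.0
    dispersion_log_mu: float = math.log(0.05)
    dispersion_log_sd: float = 0.5
    size_factor_log_sd: float = 0.15
    module_specs: list[ModuleSpec] = field(default_factory=_default_modules)
    de_specs: list[DESpec] = field(default_factory=_default_de)
    allow_de_module_overlap: bool = False
    length_log_mu: float = 7.5
    length_log_sd: float = 0.7
    length_bias: float = 0.0
    n_categories: int = 150
    category_size_range: tuple[int, int] = (10, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if len(self.groups) < 1:
            raise ValueError("at least one group required")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance must be in [0, 1]")
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        for name in ("baseline_log2_mean_sd", "dispersion_log_sd",
                     "size_factor_log_sd", "length_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        lo, hi = self.category_size_range
        if lo < 2:
            raise ValueError("category_size_range lower bound must be >= 2")
        if hi < lo:
            raise ValueError("category_size_range must be (low, high) with low <= high")
        n_planted = sum(m.size for m in self.module_specs)
        if not self.allow_de_module_overlap:
            n_planted += sum(d.n_genes for d in self.de_specs)
        if n_planted > self.n_genes:
            raise ValueError("planted module/DE genes exceed n_genes")

    @property
    def n_samples(self) -> int:
        return self.n_per_group * len(self.groups)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """Complete record of every simulated effect."""

    de_log2fc: pd.DataFrame  # index gene id, columns log2fc_low/log2fc_high
    module_membership: pd.Series  # gene id -> module index (1-based), planted genes only
    module_loadings: list[dict]  # per planted module: loadings per group, residual sd
    dispersions: pd.Series  # per gene
    baseline_log2: pd.Series  # per gene
    size_factors: pd.Series  # per sample
    behaviour_zone_probs: dict | None = None  # group -> (bottom, middle, top)

    def is_de(self, gene: str) -> bool:
        return gene in self.de_log2fc.index


def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Balanced sample design table.

    Within each group, sexes are balanced to ``sex_balance``, fish are split
    evenly over the weeks, and each group x week cell is housed in two tanks.
    The layout is fully determined by the configuration (no random draws), so
    identical configs give byte-identical tables.
    """
    rows = []
    for group in config.groups:
        n = config.n_per_group
        n_male = int(round(config.sex_balance * n))
        sexes = ["M"] * n_male + ["F"] * (n - n_male)
        for i in range(n):
            week = (i % config.n_weeks) + 1
            # two tanks per group-week cell, fish alternating between them
            tank = f"{group}_w{week}_t{(i // config.n_weeks) % 2 + 1}"
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "sex": sexes[i],
                    "week": week,
                    "tank": tank,
                }
            )
    design = pd.DataFrame(rows).set_index("sample_id")
    design["group"] = pd.Categorical(design["group"], categories=list(config.groups))
    return design


def _assign_planted_genes(config: SimulationConfig, gene_ids: list[str]):
    """Allocate disjoint gene blocks to modules, then DE specs."""
    cursor = 0
    module_genes: list[list[str]] = []
    for spec in config.module_specs:
        module_genes.append(gene_ids[cursor : cursor + spec.size])
        cursor += spec.size
    de_genes: list[list[str]] = []
    de_cursor = 0 if config.allow_de_module_overlap else cursor
    for spec in config.de_specs:
        de_genes.append(gene_ids[de_cursor : de_cursor + spec.n_genes])
        de_cursor += spec.n_genes
    return module_genes, de_genes


def simulate_counts(
    design: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial count matrix (genes x samples) plus ground truth.

    Count mean for gene g in sample j:
    ``s_j * 2^(b_g + delta_g(group_j) + lambda_{g,group_j} f_{m(g),j} + sigma_m eps)``
    with size factor s_j, baseline b_g, planted DE shift delta, and the
    shared per-module, per-sample latent factor f.  Dispersion per gene is
    lognormal.  Extreme means are capped at 2^30 with a warning.
    """
    rng = _component_rng(config.seed, _STREAM_COUNTS)
    n_genes, n_samples = config.n_genes, len(design)
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    sample_ids = list(design.index)
    groups = design["group"].astype(str).to_numpy()

    baseline = rng.normal(config.baseline_log2_mean_mu, config.baseline_log2_mean_sd, n_genes)
    dispersion = np.exp(rng.normal(config.dispersion_log_mu, config.dispersion_log_sd, n_genes))
    size_factors = np.exp(rng.normal(0.0, config.size_factor_log_sd, n_samples))
    size_factors /= np.exp(np.mean(np.log(size_factors)))  # geometric mean 1

    module_genes, de_genes = _assign_planted_genes(config, gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    log2_mean = np.tile(baseline[:, None], (1, n_samples)).astype(float)

    # planted DE shifts per group
    de_records = {}
    for spec, genes in zip(config.de_specs, de_genes):
        delta = np.zeros(n_samples)
        for g_label, fc in (("low", spec.log2fc_low), ("high", spec.log2fc_high)):
            if g_label in config.groups:
                delta[groups == g_label] = fc
        for g in genes:
            log2_mean[gene_index[g], :] += delta
            de_records[g] = {"log2fc_low": spec.log2fc_low, "log2fc_high": spec.log2fc_high}

    # planted module structure: shared latent factor per module and sample
    membership = {}
    loadings_rec = []
    for m_idx, (spec, genes) in enumerate(zip(config.module_specs, module_genes), start=1):
        f = rng.normal(0.0, 1.0, n_samples)
        lam = np.array([spec.loadings.get(g, 0.0) for g in groups])
        eps = rng.normal(0.0, spec.residual_sd, (len(genes), n_samples))
        rows = np.array([gene_index[g] for g in genes])
        log2_mean[rows, :] += lam[None, :] * f[None, :] + eps
        for g in genes:
            membership[g] = m_idx
        loadings_rec.append(
            {"module": m_idx, "loadings": dict(spec.loadings), "residual_sd": spec.residual_sd}
        )

    if np.any(log2_mean > _MAX_LOG2_MEAN):
        warnings.warn(
            "simulated log2 means exceed 2^30; capping to avoid overflow",
            RuntimeWarning,
            stacklevel=2,
        )
        log2_mean = np.minimum(log2_mean, _MAX_LOG2_MEAN)

    mean = size_factors[None, :] * np.exp2(log2_mean)
    counts = _nb_draw(rng, mean, dispersion[:, None])

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    truth = GroundTruth(
        de_log2fc=pd.DataFrame.from_dict(de_records, orient="index"),
        module_membership=pd.Series(membership, dtype=int),
        module_loadings=loadings_rec,
        dispersions=pd.Series(dispersion, index=gene_ids),
        baseline_log2=pd.Series(baseline, index=gene_ids),
        size_factors=pd.Series(size_factors, index=sample_ids),
    )
    return counts_df, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: np.ndarray) -> np.ndarray:
    """NB(mean m, dispersion alpha) draws, variance m + alpha m^2.

    Genes with dispersion below 1e-12 fall back to the Poisson limit.
    """
    mean = np.broadcast_to(mean, np.broadcast_shapes(mean.shape, dispersion.shape)).astype(float)
    dispersion = np.broadcast_to(dispersion, mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = dispersion < 1e-12
    if np.any(tiny):
        out[tiny] = rng.poisson(mean[tiny])
    if np.any(~tiny):
        r = 1.0 / dispersion[~tiny]
        p = r / (r + mean[~tiny])
        out[~tiny] = rng.negative_binomial(r, p)
    return out


def simulate_gene_metadata(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    planted_module_categories: Sequence[int] = (),
) -> tuple[pd.Series, dict[str, set[str]]]:
    """Gene lengths (bp) and category annotations.

    Lengths are lognormal; when ``config.length_bias`` is non-zero, genes
    that are planted DE or module members get their log-length shifted by
    that amount, producing a membership-length association for the
    probability-weighting stage to detect and correct.  Categories are drawn
    uniformly with sizes in ``category_size_range``; ``planted_module_
    categories`` adds one term per listed planted module equal to its exact
    gene set.
    """
    rng = _component_rng(config.seed, _STREAM_METADATA)
    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    log_len = rng.normal(config.length_log_mu, config.length_log_sd, config.n_genes)
    if config.length_bias != 0.0:
        if truth is None:
            raise ValueError("length_bias requires the ground truth to locate planted genes")
        member = np.zeros(config.n_genes, dtype=bool)
        flagged = set(truth.de_log2fc.index) | set(truth.module_membership.index)
        for i, g in enumerate(gene_ids):
            if g in flagged:
                member[i] = True
        log_len[member] += config.length_bias
    lengths = pd.Series(np.maximum(np.exp(log_len), 100.0).round().astype(int),
                        index=gene_ids, name="length")

    lo, hi = config.category_size_range
    categories: dict[str, set[str]] = {}
    for t in range(config.n_categories):
        size = int(rng.integers(lo, hi + 1))
        size = min(size, config.n_genes)
        chosen = rng.choice(config.n_genes, size=size, replace=False)
        categories[f"CAT{t + 1:04d}"] = {gene_ids[i] for i in chosen}
    for m_idx in planted_module_categories:
        if truth is None:
            raise ValueError("planted_module_categories requires the ground truth")
        genes = set(truth.module_membership.index[truth.module_membership == m_idx])
        if not genes:
            raise ValueError(f"no planted module {m_idx} in the ground truth")
        categories[f"PLANTED_M{m_idx}"] = genes
    return lengths, categories


def default_zone_probs(groups: Sequence[str] = ("control", "low", "high")) -> dict:
    """Default (bottom, middle, top) zone probabilities per group: a
    dose-dependent shift toward the top of the tank."""
    table = {
        "control": (0.45, 0.35, 0.20),
        "low": (0.30, 0.40, 0.30),
        "high": (0.10, 0.30, 0.60),
    }
    out = {}
    for i, g in enumerate(groups):
        out[g] = table.get(g, tuple(table.values())[min(i, 2)])
    return out


def simulate_behaviour(
    design: pd.DataFrame,
    zone_probs_per_group: Mapping[str, Sequence[float]] | None = None,
    n_observations: int = 30,
    n_sessions: int = 9,
    seed: int = 0,
) -> pd.DataFrame:
    """Per fish x session multinomial zone counts (bottom, middle, top).

    Each session yields ``n_observations`` minute-by-minute position records
    summing to ``n_observations`` per fish.  Sessions cycle through the
    three assessment types (spawning, feeding, general) over days.
    """
    if zone_probs_per_group is None:
        zone_probs_per_group = default_zone_probs(design["group"].cat.categories)
    for g, probs in zone_probs_per_group.items():
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (3,):
            raise ValueError(f"zone probabilities for {g!r} must have 3 entries")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError(f"zone probabilities for {g!r} must lie in [0, 1]")
        if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"zone probabilities for {g!r} must sum to 1")
    rng = _component_rng(seed, _STREAM_BEHAVIOUR)
    session_types = ["spawning", "feeding", "general"]
    rows = []
    for sample_id, rec in design.iterrows():
        probs = np.asarray(zone_probs_per_group[str(rec["group"])], dtype=float)
        for s in range(n_sessions):
            counts = rng.multinomial(n_observations, probs)
            rows.append(
                {
                    "fish_id": sample_id,
                    "group": str(rec["group"]),
                    "sex": rec["sex"],
                    "week": rec["week"],
                    "tank": rec["tank"],
                    "session_type": session_types[s % 3],
                    "day": s // 3 + 1,
                    "bottom": counts[0],
                    "middle": counts[1],
                    "top": counts[2],
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FishMetricParams:
    """Means and standard deviations of the raw body measures."""

    body_weight_g: tuple[float, float] = (0.45, 0.08)
    fork_length_cm: tuple[float, float] = (3.3, 0.25)
    liver_weight_mg: tuple[float, float] = (12.0, 3.0)
    brain_weight_mg: tuple[float, float] = (8.0, 1.5)

    def __post_init__(self) -> None:
        for name in ("body_weight_g", "fork_length_cm", "liver_weight_mg", "brain_weight_mg"):
            mu, sd = getattr(self, name)
            if mu <= 0 or sd <= 0:
                raise ValueError(f"{name} location and scale must be > 0")


def simulate_fish_metrics(
    design: pd.DataFrame,
    seed: int = 0,
    params: FishMetricParams | None = None,
    group_effects: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Fish body measures: positive normal draws, no group effect by default.

    ``group_effects`` optionally maps metric name -> group -> multiplicative
    shift of the mean (e.g. ``{"body_weight_g": {"high": 1.2}}``).
    """
    params = params or FishMetricParams()
    rng = _component_rng(seed, _STREAM_METRICS)
    rows = []
    for sample_id, rec in design.iterrows():
        row = {"fish_id": sample_id, "group": str(rec["group"]),
               "sex": rec["sex"], "week": rec["week"]}
        for name in ("body_weight_g", "fork_length_cm", "liver_weight_mg", "brain_weight_mg"):
            mu, sd = getattr(params, name)
            if group_effects and name in group_effects:
                mu = mu * group_effects[name].get(str(rec["group"]), 1.0)
            val = rng.normal(mu, sd)
            # resample into the positive tail rather than truncating at zero
            while val <= 0.05 * mu:
                val = rng.normal(mu, sd)
            row[name] = val
        rows.append(row)
    return pd.DataFrame(rows)
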