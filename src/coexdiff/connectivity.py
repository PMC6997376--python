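"""Per-group intramodular connectivity and differential-connectivity ANOVA.

For each exposure group separately, the intramodular connectivity of gene i
in module M is

    kWithin_i = sum_{j in M, j != i} |r_ij|^beta

with Pearson correlations r computed within the group's samples only and
soft-thresholding power beta (default 12).  Note the deliberate asymmetry
with the network construction stage: the network is signed, but the
connectivity statistic uses absolute correlations.  The procedure is kept
that way because it is what the statistic is defined as in this analysis;
``use_signed=True`` switches to the signed adjacency instead.

Per module, a one-way ANOVA treats each gene's kWithin as an observation
and the exposure groups as levels; the module-level Bonferroni threshold is
alpha divided by the number of modules tested.  Genes within a module are
correlated, so the gene-level F test is anti-conservative under the null;
a label-permutation null is available as a cross-check
(:func:`permutation_module_pvalues`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .network import pearson_correlation, signed_adjacency

__all__ = [
    "group_connectivity",
    "connectivity_table",
    "module_connectivity_anova",
    "bonferroni_threshold",
    "format_threshold",
    "permutation_module_pvalues",
    "DifferentialConnectivity",
]


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test Bonferroni significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return alpha / n_tests


def format_threshold(threshold: float, sig_figs: int = 3) -> str:
    """Threshold rendered to ``sig_figs`` significant figures (e.g. 1.47E-03)."""
    return np.format_float_scientific(
        threshold, precision=sig_figs - 1, exp_digits=2
    ).upper()


def _kwithin_from_weights(w: np.ndarray) -> np.ndarray:
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    return off.sum(axis=1)


def group_connectivity(
    expr_group: pd.DataFrame,
    modules: pd.Series,
    beta: float = 12.0,
    use_signed: bool = False,
) -> pd.DataFrame:
    """Intramodular connectivity within one exposure group.

    ``expr_group`` is the gene-major expression matrix restricted to the
    group's samples; ``modules`` maps gene id -> module label.  Only modules
    1..M are scored (label 0 is unassigned).  Zero-variance genes within the
    group contribute zero-strength edges (handled in the correlation step).
    """
    if expr_group.shape[1] < 3:
        raise ValueError("a group needs at least 3 samples for connectivity")
    modules = modules.reindex(expr_group.index)
    if modules.isna().any():
        raise ValueError("module labels missing for some genes")
    rows = []
    for m in sorted(modules.unique()):
        if m == 0:
            continue
        genes = modules.index[modules == m]
        sub = expr_group.loc[genes]
        r = pearson_correlation(sub)
        if use_signed:
            w = signed_adjacency(r, beta)
        else:
            w = np.abs(r) ** beta
        kwithin = _kwithin_from_weights(w)
        for g, k in zip(genes, kwithin):
            rows.append({"gene": g, "module": int(m), "kwithin": float(k)})
    return pd.DataFrame(rows, columns=["gene", "module", "kwithin"])


def connectivity_table(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    modules: pd.Series,
    beta: float = 12.0,
    use_signed: bool = False,
) -> pd.DataFrame:
    """Long-format per-gene, per-group intramodular connectivity."""
    frames = []
    groups = design["group"].astype(str)
    for g in pd.unique(groups):
        samples = design.index[groups == g]
        tab = group_connectivity(expr[samples], modules, beta, use_signed)
        tab.insert(1, "group", g)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def _anova_oneway(samples: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA by explicit sums of squares."""
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = len(all_vals) - len(samples)
    if df_b < 1 or df_w < 1:
        return np.nan, np.nan
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        if msb == 0:
            return 0.0, 1.0
        return np.inf, 0.0
    f = msb / msw
    return float(f), float(stats.f.sf(f, df_b, df_w))


def module_connectivity_anova(
    conn_table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-module one-way ANOVA of kWithin across exposure groups.

    Each gene's kWithin is an observation, groups are the factor levels.
    Modules with fewer than two genes are skipped with a warning.  Zero
    within-group variance with unequal means is reported as F = inf, p = 0
    with the ``degenerate`` flag set.  Significance is Bonferroni-corrected
    for the number of modules tested.
    """
    group_order = list(pd.unique(conn_table["group"]))
    rows = []
    for m, sub in conn_table.groupby("module"):
        pivot = sub.pivot(index="gene", columns="group", values="kwithin")
        if pivot.isna().any().any():
            raise ValueError(f"module {m}: kWithin missing for some gene/group pairs")
        if pivot.shape[0] < 2:
            warnings.warn(f"module {m} has < 2 genes; skipped", RuntimeWarning, stacklevel=2)
            continue
        samples = [pivot[g].to_numpy(dtype=float) for g in group_order]
        f, p = _anova_oneway(samples)
        row = {"module": int(m), "n_genes": int(pivot.shape[0]), "F": f, "pvalue": p,
               "degenerate": bool(np.isinf(f))}
        for g in group_order:
            row[f"mean_kwithin_{g}"] = float(pivot[g].mean())
        rows.append(row)
    columns = ["module", "n_genes", "F", "pvalue", "degenerate"] + [
        f"mean_kwithin_{g}" for g in group_order
    ]
    res = pd.DataFrame(rows, columns=columns if not rows else None).set_index("module")
    if len(res):
        threshold = bonferroni_threshold(len(res), alpha)
        res["bonferroni_threshold"] = threshold
        res["significant"] = res["pvalue"] < threshold
    return res


def permutation_module_pvalues(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    modules: pd.Series,
    beta: float = 12.0,
    n_perm: int = 200,
    seed: int = 0,
) -> pd.Series:
    """Permutation null for the module ANOVA F.

    Group labels are permuted across samples, connectivity and the per-module
    F recomputed; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  This respects
    the correlation between genes that the gene-level F test ignores.
    """
    rng = np.random.default_rng(seed)
    obs = module_connectivity_anova(connectivity_table(expr, design, modules, beta))
    if obs.empty:
        return pd.Series(dtype=float)
    hits = pd.Series(0, index=obs.index, dtype=int)
    perm_design = design.copy()
    groups = design["group"].to_numpy()
    for _ in range(n_perm):
        perm_design["group"] = rng.permutation(groups)
        perm = module_connectivity_anova(
            connectivity_table(expr, perm_design, modules, beta)
        )
        f_perm = perm["F"].reindex(obs.index)
        hits += (f_perm >= obs["F"]).astype(int)
    return (1 + hits) / (1 + n_perm)


class DifferentialConnectivity(BaseEstimator):
    """Estimator wrapper: per-group kWithin plus the module-level ANOVA.

    ``fit(expr, design, modules)`` computes ``connectivity_`` (long table)
    and ``anova_`` (per-module F, p, group means, Bonferroni flag at
    ``alpha`` / number of modules).
    """

    def __init__(self, beta: float = 12.0, alpha: float = 0.05, use_signed: bool = False):
        self.beta = beta
        self.alpha = alpha
        self.use_signed = use_signed

    def fit(self, expr: pd.DataFrame, design: pd.DataFrame, modules: pd.Series):
        self.connectivity_ = connectivity_table(
            expr, design, modules, self.beta, self.use_signed
        )
        self.anova_ = module_connectivity_anova(self.connectivity_, self.alpha)
        self.significant_modules_ = (
            list(self.anova_.index[self.anova_["significant"]]) if len(self.anova_) else []
        )
        return self
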