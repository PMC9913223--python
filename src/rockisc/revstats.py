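"""Comparison statistics with bootstrap confidence intervals.

Two scalar statistics compare a treated and a control sample:

* T, the total absolute difference between cell-type proportion vectors,
  sum_t |pi_A(t) - pi_B(t)| (0 for identical compositions, at most 2);
* D, the mean absolute difference between the two samples' pseudotime
  quantiles over a fine percentile grid (0.1, 0.2, ..., 100.0).

Percentile bootstrap CIs come from resampling cells with replacement
independently within each sample.  The treatment-vs-withdrawal ratio
R = D_treatment / D_withdrawal (or the T analogue) carries a CI built from
ratios of paired bootstrap draws; its lower bound supports "at least k times
larger" statements.  Differential expression uses the two-sided Wilcoxon
rank-sum test (normal approximation with tie and continuity corrections)
with Benjamini-Hochberg adjustment and a |log2 fold change| > 1 call rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .celltype import ProportionVector

PERCENTILE_GRID = np.round(np.arange(1, 1001) * 0.1, 10)  # 0.1 .. 100.0


class StatisticError(ValueError):
    pass


@dataclass
class ComparisonResult:
    statistic: float
    draws: np.ndarray
    ci: tuple
    n_boot: int
    alpha: float
    seed: int
    name: str = ""

    def __post_init__(self):
        if self.ci[0] > self.ci[1]:
            raise StatisticError("CI lower bound exceeds upper bound")


@dataclass
class RatioResult:
    ratio: float
    ci: tuple
    n_boot: int
    seed: int
    undefined: bool = False


@dataclass
class DEResult:
    table: pd.DataFrame
    n_up: int
    n_down: int
    fc_threshold: float
    p_threshold: float


def quantile_mad(pt_a, pt_b, grid=PERCENTILE_GRID) -> float:
    """Mean absolute difference of linear-interpolation quantiles."""
    pt_a, pt_b = np.asarray(pt_a, float), np.asarray(pt_b, float)
    if len(pt_a) == 0 or len(pt_b) == 0:
        raise StatisticError("pseudotime samples must be non-empty")
    q = np.asarray(grid, float) / 100.0
    qa = np.quantile(pt_a, q, method="linear")
    qb = np.quantile(pt_b, q, method="linear")
    return float(np.abs(qa - qb).mean())


def quantile_profile(pt_a, pt_b, grid=PERCENTILE_GRID) -> pd.DataFrame:
    """Per-percentile |quantile difference| profile (for plotting)."""
    q = np.asarray(grid, float) / 100.0
    qa = np.quantile(np.asarray(pt_a, float), q)
    qb = np.quantile(np.asarray(pt_b, float), q)
    return pd.DataFrame({"percentile": grid, "q_a": qa, "q_b": qb,
                         "abs_diff": np.abs(qa - qb)})


def total_abs_prop_diff(pi_a, pi_b) -> float:
    """Sum over types of |pi_A - pi_B| (between 0 and 2)."""
    a = pi_a.values if isinstance(pi_a, ProportionVector) else np.asarray(pi_a, float)
    b = pi_b.values if isinstance(pi_b, ProportionVector) else np.asarray(pi_b, float)
    if a.shape != b.shape:
        raise StatisticError("proportion vectors must have equal length")
    return float(np.abs(a - b).sum())


def bootstrap_ci(statistic, samples, n_boot: int = 1000, alpha: float = 0.05,
                 seed: int = 0, name: str = "") -> ComparisonResult:
    """Percentile bootstrap CI, resampling within each sample independently.

    *statistic* takes len(samples) arrays; draws that raise (degenerate
    resamples, e.g. an empty category) are redrawn and counted.
    """
    if n_boot < 100:
        raise StatisticError("n_boot must be >= 100")
    samples = [np.asarray(s) for s in samples]
    point = float(statistic(*samples))
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    redone = 0
    for i in range(n_boot):
        for _attempt in range(100):
            resampled = [s[rng.integers(0, len(s), size=len(s))] for s in samples]
            try:
                draws[i] = statistic(*resampled)
                break
            except Exception:
                redone += 1
        else:
            raise StatisticError("bootstrap draws persistently degenerate")
    if redone > 0.01 * n_boot:
        warnings.warn(f"{redone} degenerate bootstrap draws were redone")
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ComparisonResult(statistic=point, draws=draws, ci=(float(lo), float(hi)),
                            n_boot=n_boot, alpha=alpha, seed=seed, name=name)


def bootstrap_proportion_T(labels_a, labels_b, types=("holoclone", "clonogenic",
                                                      "differentiated"),
                           n_boot: int = 1000, alpha: float = 0.05,
                           seed: int = 0) -> ComparisonResult:
    """T with a bootstrap over assigned cell labels of each sample."""
    from .celltype import proportions

    def stat(la, lb):
        return total_abs_prop_diff(proportions(la, types=types),
                                   proportions(lb, types=types))

    la = np.asarray(labels_a, dtype=object)
    lb = np.asarray(labels_b, dtype=object)
    la = la[np.isin(la, types)]
    lb = lb[np.isin(lb, types)]
    return bootstrap_ci(stat, [la, lb], n_boot=n_boot, alpha=alpha, seed=seed,
                        name="total_abs_prop_diff")


def bootstrap_quantile_D(pt_a, pt_b, grid=PERCENTILE_GRID, n_boot: int = 1000,
                         alpha: float = 0.05, seed: int = 0) -> ComparisonResult:
    """D with a bootstrap over cells carrying a pseudotime."""
    pt_a = np.asarray(pt_a, float)
    pt_b = np.asarray(pt_b, float)
    pt_a, pt_b = pt_a[np.isfinite(pt_a)], pt_b[np.isfinite(pt_b)]
    return bootstrap_ci(lambda a, b: quantile_mad(a, b, grid), [pt_a, pt_b],
                        n_boot=n_boot, alpha=alpha, seed=seed, name="quantile_mad")


def ratio_with_ci(boot_treat: ComparisonResult, boot_withdraw: ComparisonResult,
                  alpha: float = 0.05, seed: int = 0) -> RatioResult:
    """R = D_treatment / D_withdrawal with a paired-draw percentile CI."""
    num, den = boot_treat.draws, boot_withdraw.draws
    n = min(len(num), len(den))
    num, den = num[:n], den[:n]
    undefined = bool((den == 0).any()) or boot_withdraw.statistic == 0
    if boot_withdraw.statistic == 0:
        point = np.inf
    else:
        point = boot_treat.statistic / boot_withdraw.statistic
    with np.errstate(divide="ignore", invalid="ignore"):
        draws = np.where(den > 0, num / np.maximum(den, 1e-300), np.inf)
    lo = float(np.quantile(draws, alpha / 2.0))
    hi = np.inf if undefined else float(np.quantile(draws, 1.0 - alpha / 2.0))
    return RatioResult(ratio=float(point), ci=(lo, hi), n_boot=n, seed=seed,
                       undefined=undefined)


def _ranksum_pvalues(X: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Wilcoxon rank-sum with tie and continuity
    corrections, per gene (rows of X)."""
    n1 = int(in_a.sum())
    n2 = X.shape[1] - n1
    n = n1 + n2
    ranks = stats.rankdata(X, axis=1)
    r1 = ranks[:, in_a].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction per gene
    tie_term = np.zeros(X.shape[0])
    for g in range(X.shape[0]):
        _, counts = np.unique(X[g], return_counts=True)
        tie_term[g] = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    diff = u - mu
    z = np.where(var > 0, (diff - np.sign(diff) * 0.5) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(var > 0, np.minimum(p, 1.0), 1.0)
    return p


def wilcoxon_de(expr: np.ndarray, gene_symbols, in_group_a: np.ndarray,
                fc_threshold: float = 1.0, p_threshold: float = 0.05,
                eps: float = 1e-9) -> DEResult:
    """Per-gene Wilcoxon rank-sum DE between group A and group B.

    *expr* is log-normalized expression (genes x cells); the fold change is
    log2 of the ratio of the groups' mean de-logged expression.
    """
    in_a = np.asarray(in_group_a, dtype=bool)
    if in_a.sum() < 3 or (~in_a).sum() < 3:
        raise StatisticError("both groups need at least 3 cells")
    p = _ranksum_pvalues(np.asarray(expr, float), in_a)
    mean_a = np.expm1(expr[:, in_a]).mean(axis=1)
    mean_b = np.expm1(expr[:, ~in_a]).mean(axis=1)
    log2fc = np.log2((mean_a + eps) / (mean_b + eps))
    constant = expr.std(axis=1) == 0
    log2fc = np.where(constant, 0.0, log2fc)
    p_adj = multipletests(p, method="fdr_bh")[1]
    direction = np.where((log2fc > fc_threshold) & (p_adj < p_threshold), "up",
                         np.where((log2fc < -fc_threshold) & (p_adj < p_threshold),
                                  "down", "ns"))
    table = pd.DataFrame({"gene": np.asarray(gene_symbols, dtype=object),
                          "p_value": p, "p_adjusted": p_adj,
                          "log2fc": log2fc, "direction": direction})
    return DEResult(table=table, n_up=int((direction == "up").sum()),
                    n_down=int((direction == "down").sum()),
                    fc_threshold=fc_threshold, p_threshold=p_threshold)
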