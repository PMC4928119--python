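"""Alpha-diversity metrics and between-group comparisons.

Implements Shannon diversity and equitability, the nonparametric ACE
richness estimator (with its Chao1 fallback for all-singleton samples),
Gaussian kernel-density curves of per-sample diversity for each metadata
group, and all-pairs Wilcoxon rank-sum tests with Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import OtuTable

log = logging.getLogger("otukit")


def relative_abundance(table: OtuTable) -> OtuTable:
    """Convert counts to per-sample proportions (columns sum to 1).

    All-zero samples are left at zero and logged — they carry no
    compositional information.
    """
    counts = table.counts.values.astype(float)
    col_sums = counts.sum(axis=0)
    zero_cols = col_sums == 0
    if zero_cols.all():
        raise ValueError("table has no nonzero sample")
    if zero_cols.any():
        log.warning(
            "%d all-zero sample(s) left at zero: %s",
            int(zero_cols.sum()),
            [s for s, z in zip(table.sample_ids, zero_cols) if z],
        )
    props = np.divide(counts, np.where(zero_cols, 1.0, col_sums), where=True)
    frame = pd.DataFrame(props, index=table.otu_ids, columns=table.sample_ids)
    return OtuTable(frame, taxonomy=table.taxonomy)


# ---------------------------------------------------------------------------
# Shannon / equitability
# ---------------------------------------------------------------------------

def shannon(p, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero proportions.

    Natural log by default; pass ``base`` (e.g. 2) for other conventions.
    Input is renormalized, so raw counts are accepted too.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = p[p > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def equitability(p, base: float | None = None) -> float:
    """Evenness: H / log S, in [0, 1]; defined as 0 for a single species."""
    p = np.asarray(p, dtype=float)
    s = int((p > 0).sum())
    if s <= 1:
        return 0.0
    return shannon(p, base=base) / (np.log(s) / (np.log(base) if base else 1.0))


def observed_richness(counts) -> float:
    counts = np.asarray(counts, dtype=float)
    return float((counts > 0).sum())


# ---------------------------------------------------------------------------
# ACE
# ---------------------------------------------------------------------------

@dataclass
class AceComponents:
    """Intermediate quantities of the ACE richness estimator."""

    s_obs: int
    s_abund: int
    s_rare: int
    n_rare: int
    f_k: dict[int, int]
    c_ace: float
    gamma_sq: float
    chao1_fallback: bool = False


def ace(counts, rare_threshold: int = 10) -> tuple[float, AceComponents]:
    """Abundance-based Coverage Estimator of species richness.

    Species with count <= ``rare_threshold`` are "rare" and drive the
    coverage estimate C_ace = 1 - F1/N_rare; the estimator is

        S_ace = S_abund + S_rare/C_ace + (F1/C_ace) * gamma^2,

    with gamma^2 the squared coefficient of variation of the rare
    abundances, floored at zero. If every rare species is a singleton
    (C_ace = 0) the estimator is undefined and the bias-corrected Chao1
    estimate S_obs + F1(F1-1)/(2(F2+1)) is returned instead, flagged in the
    components.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    counts = counts[counts > 0].astype(int)
    if counts.size == 0:
        raise ValueError("all-zero count vector")
    s_obs = int(counts.size)
    rare = counts[counts <= rare_threshold]
    s_rare = int(rare.size)
    s_abund = s_obs - s_rare
    n_rare = int(rare.sum())
    f_k = {k: int((rare == k).sum()) for k in range(1, rare_threshold + 1)}
    if s_rare == 0:
        comps = AceComponents(s_obs, s_abund, 0, 0, f_k, 1.0, 0.0)
        return float(s_obs), comps
    f1 = f_k.get(1, 0)
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        f2 = f_k.get(2, 0)
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        comps = AceComponents(s_obs, s_abund, s_rare, n_rare, f_k, 0.0, 0.0, True)
        return float(chao1), comps
    sum_kk1 = sum(k * (k - 1) * f for k, f in f_k.items())
    if n_rare > 1:
        gamma_sq = max(
            (s_rare / c_ace) * sum_kk1 / (n_rare * (n_rare - 1)) - 1.0, 0.0
        )
    else:
        gamma_sq = 0.0
    estimate = s_abund + s_rare / c_ace + (f1 / c_ace) * gamma_sq
    comps = AceComponents(s_obs, s_abund, s_rare, n_rare, f_k, c_ace, gamma_sq)
    return float(estimate), comps


#: Built-in per-sample metrics; extend by registering a callable taking the
#: sample's count vector.
METRICS: dict[str, Callable] = {
    "shannon": shannon,
    "equitability": equitability,
    "ace": lambda c: ace(c)[0],
    "observed": observed_richness,
}


def sample_diversity(table: OtuTable, metric: str | Callable = "shannon") -> pd.Series:
    """Apply an alpha-diversity metric to every sample column."""
    fn = METRICS[metric] if isinstance(metric, str) else metric
    vals = {s: float(fn(table.counts[s].values)) for s in table.sample_ids}
    return pd.Series(vals, name=metric if isinstance(metric, str) else "metric")


# ---------------------------------------------------------------------------
# kernel density curves
# ---------------------------------------------------------------------------

@dataclass
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def kde_curve(values, bandwidth: float | str = "scott", n_grid: int = 256) -> DensityCurve:
    """Gaussian KDE of a sample of diversity values.

    Scott's rule h = sigma * n^(-1/5) by default; the curve is evaluated on
    ``n_grid`` points spanning [min - 3h, max + 3h] so that it integrates to
    ~1 by the trapezoid rule.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError(
            "need at least two distinct values; for constant data pass an "
            "explicit bandwidth and jittered input"
        )
    sigma = values.std(ddof=1)
    if bandwidth == "scott":
        h = sigma * values.size ** (-1 / 5)
    else:
        h = float(bandwidth)
        if h <= 0:
            raise ValueError("bandwidth must be positive")
    kde = stats.gaussian_kde(values, bw_method=h / sigma)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, n_grid)
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=h)


# ---------------------------------------------------------------------------
# pairwise group tests
# ---------------------------------------------------------------------------

@dataclass
class PairTest:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    q_value: float = np.nan
    significant: bool = False


@dataclass
class GroupComparisonResult:
    tests: list[PairTest]
    fdr_level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_a": t.group_a,
                    "group_b": t.group_b,
                    "statistic": t.statistic,
                    "p": t.p_value,
                    "q": t.q_value,
                    "significant": t.significant,
                }
                for t in self.tests
            ]
        )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    _, qvals, _, _ = multipletests(list(pvals), method="fdr_bh")
    return np.asarray(qvals)


def _has_ties(x, y) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def pairwise_group_tests(
    values_by_group: Mapping[str, np.ndarray], fdr_level: float = 0.1
) -> GroupComparisonResult:
    """Two-sided Wilcoxon rank-sum test for every unordered pair of groups.

    The exact null distribution is used when both groups have n <= 20 and
    the pooled data are tie-free; otherwise the normal approximation with
    tie and continuity corrections. p-values are adjusted across all pairs
    by Benjamini-Hochberg step-up, and pairs with q below ``fdr_level`` are
    flagged.
    """
    groups = list(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(values_by_group[g]) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    tests: list[PairTest] = []
    for ga, gb in combinations(groups, 2):
        x = np.asarray(values_by_group[ga], dtype=float)
        y = np.asarray(values_by_group[gb], dtype=float)
        exact = len(x) <= 20 and len(y) <= 20 and not _has_ties(x, y)
        res = stats.mannwhitneyu(
            x,
            y,
            alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=True,
        )
        tests.append(PairTest(ga, gb, float(res.statistic), float(res.pvalue)))
    qvals = bh_adjust([t.p_value for t in tests])
    for t, q in zip(tests, qvals):
        t.q_value = float(q)
        t.significant = bool(q < fdr_level)
    return GroupComparisonResult(tests=tests, fdr_level=fdr_level)
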