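"""Beta-diversity ordination: classical PCoA and Fisher LDA.

``pcoa`` embeds a (possibly non-Euclidean) distance matrix by Gower double
centering and eigendecomposition; ``lda`` projects compositional OTU tables
onto the discriminants that best separate labeled sample groups, with a
ridge-regularized within-class scatter so that tables with far more OTUs
than samples stay solvable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import linalg
from skbio import DistanceMatrix

from .diversity import relative_abundance
from .io_formats import OtuTable

log = logging.getLogger("otukit")

#: Relative eigenvalue cutoff below which a PCoA axis is numerical noise.
EIGENVALUE_RTOL = 1e-10

#: Relative ridge added to the within-class scatter in LDA.
LDA_RIDGE = 1e-4


@dataclass
class OrdinationResult:
    """Sample coordinates on ordered ordination axes."""

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    explained_fraction: np.ndarray
    method: str
    negative_eigenvalue_magnitude: float = 0.0

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    if vectors.size == 0:
        return vectors
    idx = np.abs(vectors).argmax(axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Gower centering B = -1/2 J D^2 J is eigendecomposed; axes whose
    eigenvalue exceeds ``EIGENVALUE_RTOL`` times the largest are kept and
    scaled by sqrt(eigenvalue). Negative eigenvalues — the signature of a
    non-Euclidean distance such as unweighted UniFrac — are dropped, with
    their summed magnitude reported on the result. Explained fractions are
    relative to the positive-eigenvalue total.
    """
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for PCoA")
    d2 = dm.data.astype(float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    eigvals, eigvecs = linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos_sum = float(eigvals[eigvals > 0].sum())
    neg_mag = float(-eigvals[eigvals < 0].sum())
    if eigvals.size and eigvals[0] > 0:
        keep = eigvals > EIGENVALUE_RTOL * eigvals[0]
    else:
        keep = np.zeros_like(eigvals, dtype=bool)
    lam = eigvals[keep]
    vec = _fix_signs(eigvecs[:, keep])
    coords = vec * np.sqrt(lam)
    explained = lam / pos_sum if pos_sum > 0 else np.zeros_like(lam)
    return OrdinationResult(
        sample_ids=list(dm.ids),
        coordinates=coords,
        explained_fraction=explained,
        method="pcoa",
        negative_eigenvalue_magnitude=neg_mag,
    )


def lda(
    table: OtuTable,
    labels: Mapping[str, str],
    n_axes: int = 2,
) -> OrdinationResult:
    """Fisher linear discriminant projection of a compositional OTU table.

    Maximizes between-class over within-class scatter; at most
    (number of groups - 1) discriminants exist. The within-class scatter of
    a compositional table is rank-deficient (features typically outnumber
    samples), so it is regularized as S_w + eps * (tr(S_w)/p) * I with
    eps = ``LDA_RIDGE``. Input must be per-sample proportions; raw counts
    are rejected.
    """
    samples = table.sample_ids
    unlabeled = [s for s in samples if s not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled sample(s): {unlabeled}")
    x = table.counts.values.T.astype(float)  # samples x features
    col_sums = table.counts.values.sum(axis=0)
    if not np.allclose(col_sums, 1.0, atol=1e-6):
        raise ValueError(
            "lda expects per-sample proportions (columns summing to 1); "
            "convert counts with relative_abundance() first"
        )
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault(str(labels[s]), []).append(i)
    g = len(groups)
    if g < 2:
        raise ValueError("need at least two groups")
    for name, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {name!r} has a single sample")
    if n_axes > g - 1:
        raise ValueError(f"n_axes={n_axes} exceeds groups-1={g - 1}")

    p = x.shape[1]
    mu = x.mean(axis=0)
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    for idx in groups.values():
        xg = x[idx]
        mg = xg.mean(axis=0)
        cg = xg - mg
        s_w += cg.T @ cg
        dm = (mg - mu)[:, None]
        s_b += len(idx) * (dm @ dm.T)
    trace = np.trace(s_w)
    ridge = LDA_RIDGE * (trace / p) if trace > 0 else 1e-12
    s_w_reg = s_w + ridge * np.eye(p)

    eigvals, eigvecs = linalg.eigh(s_b, s_w_reg)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    lam = np.clip(eigvals[:n_axes], 0.0, None)
    w = _fix_signs(eigvecs[:, :n_axes])
    pos_sum = float(eigvals[eigvals > 0].sum())
    explained = lam / pos_sum if pos_sum > 0 else np.zeros_like(lam)
    coords = (x - mu) @ w
    return OrdinationResult(
        sample_ids=list(samples),
        coordinates=coords,
        explained_fraction=explained,
        method="lda",
    )


def group_separation(result: OrdinationResult, labels: Mapping[str, str], axis: int = 0) -> float:
    """|mean difference| between two groups on one axis, over pooled within-group SD.

    A scale-free effect size for how well an ordination axis separates two
    labeled groups.
    """
    vals: dict[str, list[float]] = {}
    for s, c in zip(result.sample_ids, result.coordinates[:, axis]):
        vals.setdefault(str(labels[s]), []).append(float(c))
    if len(vals) != 2:
        raise ValueError("separation statistic is defined for exactly two groups")
    (a, b) = (np.asarray(v) for v in vals.values())
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    pooled_sd = np.sqrt(pooled_var)
    if pooled_sd == 0:
        return np.inf
    return float(abs(a.mean() - b.mean()) / pooled_sd)


def bubble_sizes(
    table: OtuTable, otu_id: str, max_size: float, min_size: float = 5.0
) -> dict[str, float]:
    """Per-sample marker sizes proportional to one OTU's relative abundance.

    The most abundant sample gets ``max_size``; samples where the OTU is
    absent get the fixed ``min_size`` so they stay visible.
    """
    if otu_id not in table.counts.index:
        raise KeyError(f"OTU {otu_id!r} not in table")
    rel = relative_abundance(table)
    r = rel.counts.loc[otu_id].values.astype(float)
    peak = r.max()
    if peak == 0:
        log.warning("OTU %r absent from every sample; all markers at minimum size", otu_id)
        return {s: min_size for s in table.sample_ids}
    return {
        s: (max_size * v / peak if v > 0 else min_size)
        for s, v in zip(table.sample_ids, r)
    }
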