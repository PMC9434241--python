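"""Metafounder relationship matrix (Gamma) estimation and summaries.

Gamma encodes base-population structure: ``Gamma_ij = 8 cov(p_i, p_j)``
where ``p_i`` are allele frequencies in base population ``i``. It is
estimated from descendant genotypes by GLS-estimating the base frequencies
per marker and taking 8x their second moment across markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .genomic import GenotypeMatrix, impute_marker_means
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)


@dataclass
class GammaMatrix:
    """K x K symmetric matrix of metafounder self- and cross-relationships."""

    labels: list[str]
    values: np.ndarray
    estimation_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = [str(g) for g in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        K = len(self.labels)
        if self.values.shape != (K, K):
            raise ValueError("gamma shape does not match labels")
        if len(set(self.labels)) != K:
            raise ValueError("duplicate metafounder labels")
        if np.max(np.abs(self.values - self.values.T), initial=0.0) > 1e-10:
            raise ValueError("gamma matrix not symmetric")
        if np.any(np.diag(self.values) < 0):
            raise ValueError("gamma diagonal entries must be nonnegative")

    @property
    def k(self) -> int:
        return len(self.labels)

    def psd_repair(self, floor: float = 1e-6) -> "GammaMatrix":
        """Clip eigenvalues at ``floor`` to make Gamma positive definite."""
        w, V = np.linalg.eigh(self.values)
        repaired = (V * np.maximum(w, floor)) @ V.T
        repaired = 0.5 * (repaired + repaired.T)
        meta = dict(self.estimation_meta, psd_repaired=True)
        return GammaMatrix(list(self.labels), repaired, meta)

    def is_psd(self, tol: float = -1e-10) -> bool:
        return bool(np.min(np.linalg.eigvalsh(self.values)) >= tol)


def estimate_gamma_gls(
    genotypes: GenotypeMatrix,
    a22: RelationshipMatrix,
    q: pd.DataFrame,
    center: str = "half",
    psd_repair: bool = False,
) -> GammaMatrix:
    """GLS estimate of Gamma from genotyped descendants.

    Per marker ``j`` the base-frequency vector is the GLS solution
    ``p_j = (Q' A22^{-1} Q)^{-1} Q' A22^{-1} m_j / 2`` with ``m_j`` the gene
    contents and ``Q`` the metafounder-contribution rows of the genotyped
    individuals; then ``Gamma = 8/m * sum_j (p_j - c)(p_j - c)'``.

    Parameters
    ----------
    center
        ``"half"`` (default): second moment about ``c = 0.5``, the reference
        frequency of the ideal base population (matches ``G05``).
        ``"mean"``: per-metafounder marker-mean centering (a covariance
        proper across markers).
    psd_repair
        Repair an indefinite estimate by eigenvalue clipping. When False and
        the estimate is indefinite, a warning is logged.
    """
    if center not in ("half", "mean"):
        raise ValueError(f"center must be 'half' or 'mean', got {center!r}")
    if list(q.index) != list(genotypes.individual_ids) or list(q.index) != list(
        a22.entity_ids
    ):
        raise ValueError("genotypes, a22 and q must share one individual ordering")
    Q = q.to_numpy(dtype=float)
    labels = [str(c) for c in q.columns]
    empty = np.flatnonzero(Q.sum(axis=0) == 0)
    if empty.size:
        raise ValueError(
            f"metafounder {labels[empty[0]]!r} has no genotyped descendant "
            "with nonzero contribution"
        )
    A = a22.to_dense()
    try:
        Ainv_Q = np.linalg.solve(A, Q)
    except np.linalg.LinAlgError:
        raise ValueError("A22 is singular; GLS requires positive definite A22")
    lhs = Q.T @ Ainv_Q  # K x K
    if np.linalg.cond(lhs) > 1e12:
        raise ValueError(
            "GLS normal equations singular: some metafounder has no effective "
            "genotyped representation"
        )
    M = impute_marker_means(genotypes)
    # K x m matrix of estimated base frequencies
    P = np.linalg.solve(lhs, Ainv_Q.T @ M) / 2.0
    m = M.shape[1]
    if center == "half":
        D = P - 0.5
    else:
        D = P - P.mean(axis=1, keepdims=True)
    gamma = 8.0 * (D @ D.T) / m
    gamma = 0.5 * (gamma + gamma.T)
    meta = {
        "n_markers": m,
        "n_genotyped": genotypes.n_individuals,
        "centering": center,
        "psd_repaired": False,
    }
    out = GammaMatrix(labels, gamma, meta)
    if not out.is_psd():
        if psd_repair:
            out = out.psd_repair()
        else:
            logger.warning(
                "estimated gamma is indefinite; consider psd_repair=True"
            )
    return out


def k_scalar(gamma: GammaMatrix) -> float:
    """``k = 1 + mean(diag(Gamma))/2 - mean(Gamma)``.

    Divides the additive variance in metafounder models so it is comparable
    with the classical (unrelated-founder) parameterization.
    """
    v = gamma.values
    return float(1.0 + np.mean(np.diag(v)) / 2.0 - np.mean(v))


def gamma_diversity_summary(gamma: GammaMatrix) -> dict:
    """Diversity interpretation of Gamma.

    Diagonal min/mean/max, per-metafounder implied inbreeding
    ``F_g = Gamma_gg - 1`` (negative values = more diversity than a single
    non-inbred founder pair would carry), and each metafounder's most
    related partner (largest off-diagonal in its row).
    """
    v = gamma.values
    d = np.diag(v)
    K = gamma.k
    partners = {}
    for i in range(K):
        if K < 2:
            partners[gamma.labels[i]] = (None, np.nan)
            continue
        off = [(v[i, j], gamma.labels[j]) for j in range(K) if j != i]
        best = max(off, key=lambda t: t[0])
        partners[gamma.labels[i]] = (best[1], float(best[0]))
    return {
        "diag_min": float(np.min(d)),
        "diag_mean": float(np.mean(d)),
        "diag_max": float(np.max(d)),
        "inbreeding_per_mf": {
            g: float(d[i] - 1.0) for i, g in enumerate(gamma.labels)
        },
        "inbreeding_mean": float(np.mean(d - 1.0)),
        "most_related_partner": partners,
    }


def gamma_distance(gamma: GammaMatrix) -> np.ndarray:
    """Covariance-derived distances ``d_ij = (G_ii + G_jj)/2 - G_ij``, clipped at 0."""
    v = gamma.values
    d = 0.5 * (np.add.outer(np.diag(v), np.diag(v))) - v
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


def upgma_from_gamma(gamma: GammaMatrix) -> str:
    """UPGMA (average-linkage) tree of metafounders, as a Newick string.

    Distances are the covariance-derived ``(G_ii + G_jj)/2 - G_ij``; node
    heights are half the merge distance, so the tree is ultrametric.
    """
    if gamma.k < 2:
        raise ValueError("UPGMA needs at least 2 metafounders")
    dist = gamma_distance(gamma)
    linkage = hierarchy.average(squareform(dist, checks=False))
    tree = hierarchy.to_tree(linkage)

    def newick(node, parent_height: float) -> str:
        height = 0.0 if node.is_leaf() else node.dist / 2.0
        branch = parent_height - height
        if node.is_leaf():
            return f"{gamma.labels[node.id]}:{branch:.10g}"
        left = newick(node.left, height)
        right = newick(node.right, height)
        return f"({left},{right}):{branch:.10g}"

    root_height = tree.dist / 2.0
    left = newick(tree.left, root_height)
    right = newick(tree.right, root_height)
    return f"({left},{right});"
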