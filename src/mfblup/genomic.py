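"""Genomic relationship matrices (VanRaden method 1) and matrix summaries.

``G_obs`` centers gene contents at observed allele frequencies; ``G05``
centers at 0.5 — the natural companion of metafounder models, where base
relationships are referenced to an ideal population with all frequencies at
0.5. Rescaling and blending make ``G`` compatible with (and invertible
against) its pedigree counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix, require_same_ordering


@dataclass
class GenotypeMatrix:
    """Gene-content matrix (0/1/2 reference-allele counts; NaN = missing)."""

    individual_ids: list[str]
    marker_ids: list[str]
    gene_content: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.gene_content = np.asarray(self.gene_content, dtype=float)
        n, m = self.gene_content.shape
        if n != len(self.individual_ids) or m != len(self.marker_ids):
            raise ValueError("gene_content shape does not match id lists")
        vals = self.gene_content[~np.isnan(self.gene_content)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"gene content value {bad!r} outside {{0,1,2}}")
        if np.any(np.all(np.isnan(self.gene_content), axis=0)):
            j = int(np.flatnonzero(np.all(np.isnan(self.gene_content), axis=0))[0])
            raise ValueError(f"marker {self.marker_ids[j]!r} entirely missing")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_rate(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.mean(np.isnan(self.gene_content), axis=0)

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {g: i for i, g in enumerate(self.individual_ids)}
        try:
            rows = [index[str(i)] for i in ids]
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not genotyped") from None
        return GenotypeMatrix(
            [str(i) for i in ids], list(self.marker_ids), self.gene_content[rows]
        )


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Observed per-marker reference-allele frequencies (non-missing mean / 2)."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(genotypes.gene_content, axis=0) / 2.0


def impute_marker_means(genotypes: GenotypeMatrix) -> np.ndarray:
    """Gene contents with missing entries replaced by the marker mean."""
    M = genotypes.gene_content.copy()
    if np.any(np.isnan(M)):
        means = np.nanmean(M, axis=0)
        idx = np.where(np.isnan(M))
        M[idx] = means[idx[1]]
    return M


def g_vanraden(genotypes: GenotypeMatrix, center: str = "observed") -> RelationshipMatrix:
    """Genomic relationship matrix ``ZZ'/c`` (VanRaden's first method).

    Parameters
    ----------
    center
        ``"observed"``: Z = M - 2p with observed frequencies and
        ``c = 2 * sum(p(1-p))``; monomorphic markers are dropped (they
        contribute nothing). ``"half"``: p = 0.5 for every marker,
        ``c = m/2``; all markers are retained.
    """
    if center not in ("observed", "half"):
        raise ValueError(f"center must be 'observed' or 'half', got {center!r}")
    M = impute_marker_means(genotypes)
    if center == "half":
        Z = M - 1.0
        c = M.shape[1] / 2.0
        kind = "G05"
    else:
        p = M.mean(axis=0) / 2.0
        poly = (p > 0.0) & (p < 1.0)
        if not np.any(poly):
            raise ValueError(
                "all markers monomorphic under observed centering (c = 0)"
            )
        Z = M[:, poly] - 2.0 * p[poly]
        c = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
        kind = "G_obs"
    G = Z @ Z.T / c
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(list(genotypes.individual_ids), G, kind)


def rescale_g(
    g_obs: RelationshipMatrix, a22: RelationshipMatrix
) -> RelationshipMatrix:
    """Affine rescale of ``G`` so its mean diagonal and overall mean match ``A22``.

    Solves ``G_scaled = alpha + beta * G_obs`` from the two moment
    conditions; ``beta = (mean diag A22 - mean A22) / (mean diag G - mean G)``.
    """
    require_same_ordering(g_obs, a22)
    G = g_obs.to_dense()
    A = a22.to_dense()
    dg, da = float(np.mean(np.diag(G))), float(np.mean(np.diag(A)))
    mg, ma = float(np.mean(G)), float(np.mean(A))
    denom = dg - mg
    if abs(denom) < 1e-12:
        raise ValueError(
            "degenerate rescaling system: mean diagonal equals overall mean of G"
        )
    beta = (da - ma) / denom
    alpha = ma - beta * mg
    return RelationshipMatrix(list(g_obs.entity_ids), alpha + beta * G, "G_scaled")


def blend_g(
    g: RelationshipMatrix, a_ref: RelationshipMatrix, weight: float = 0.95
) -> RelationshipMatrix:
    """``weight * G + (1 - weight) * A_ref`` (guards against singular G)."""
    if not 0.0 < weight <= 1.0:
        raise ValueError(f"blend weight must be in (0, 1], got {weight}")
    require_same_ordering(g, a_ref)
    out = weight * g.to_dense() + (1.0 - weight) * a_ref.to_dense()
    return RelationshipMatrix(list(g.entity_ids), out, "G_blend")


def matrix_comparison(
    m1: RelationshipMatrix, m2: RelationshipMatrix
) -> pd.DataFrame:
    """Diagonal/off-diagonal correlations and per-matrix element summaries.

    Pearson correlation of diagonal elements and of strict lower-triangle
    off-diagonal elements, plus mean/min/max of each element class for each
    matrix. A zero-variance element class yields a missing correlation.
    """
    require_same_ordering(m1, m2)
    if m1.n < 3:
        raise ValueError("need at least 3 entities to compare matrices")
    rows = []
    tri = np.tril_indices(m1.n, k=-1)
    parts = {
        "diagonal": (np.diag(m1.to_dense()), np.diag(m2.to_dense())),
        "off_diagonal": (m1.to_dense()[tri], m2.to_dense()[tri]),
    }
    for element, (x, y) in parts.items():
        if np.std(x) < 1e-15 or np.std(y) < 1e-15:
            corr = np.nan
        else:
            corr = float(np.corrcoef(x, y)[0, 1])
        rows.append(
            {
                "element": element,
                "correlation": corr,
                "m1_kind": m1.kind,
                "m1_mean": float(np.mean(x)),
                "m1_min": float(np.min(x)),
                "m1_max": float(np.max(x)),
                "m2_kind": m2.kind,
                "m2_mean": float(np.mean(y)),
                "m2_min": float(np.min(y)),
                "m2_max": float(np.max(y)),
            }
        )
    return pd.DataFrame(rows)
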