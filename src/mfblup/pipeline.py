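"""End-to-end wiring: dataset -> relationship structures -> model inputs.

Builds every relationship structure the five model variants need from one
pedigree + genotype pair, so the solver, the LR validation harness, the CLI
and the acceptance runs all share one construction path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gamma import GammaMatrix, estimate_gamma_gls, k_scalar
from .genomic import GenotypeMatrix, blend_g, g_vanraden, rescale_g
from .hmatrix import h_gamma_inverse, h_inverse
from .model import ModelSpec
from .pedigree import (
    Pedigree,
    a_gamma_matrix,
    a_gamma_inverse,
    a_inverse,
    a_matrix,
    upg_design,
)
from .relmat import RelationshipMatrix


@dataclass
class RelationshipBundle:
    """All relationship structures for one population set."""

    pedigree: Pedigree
    genotyped_ids: list[str]
    q: pd.DataFrame
    gamma: GammaMatrix
    k: float
    a_inv: RelationshipMatrix
    a22: RelationshipMatrix
    g_blend: RelationshipMatrix
    h_inv: RelationshipMatrix
    a_gamma_inv: RelationshipMatrix
    a_gamma22: RelationshipMatrix
    g05_blend: RelationshipMatrix
    h_gamma_inv: RelationshipMatrix


def build_relationships(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    gamma: GammaMatrix | None = None,
    center: str = "half",
    blend_weight: float = 0.95,
    psd_repair: bool = True,
) -> RelationshipBundle:
    """Construct A/G/H structures (plain and Gamma-augmented).

    When ``gamma`` is None it is estimated from the genotyped individuals by
    GLS. ``G_obs`` is rescaled to and blended with ``A22``; ``G05`` is
    blended with ``A_gamma22`` (both referenced to 0.5 frequencies).
    """
    gids = list(genotypes.individual_ids)
    q_full = upg_design(pedigree)
    a22 = a_matrix(pedigree, subset=gids)
    if gamma is None:
        gamma = estimate_gamma_gls(
            genotypes, a22, q_full.loc[gids], center=center, psd_repair=psd_repair
        )
    ainv = a_inverse(pedigree)
    g_obs = g_vanraden(genotypes, center="observed")
    gb = blend_g(rescale_g(g_obs, a22), a22, blend_weight)
    hinv = h_inverse(ainv, a22, gb, gids)

    aginv = a_gamma_inverse(pedigree, gamma)
    ag22 = a_gamma_matrix(
        pedigree, gamma, subset=gids, include_metafounders=False
    )
    ag22 = RelationshipMatrix(ag22.entity_ids, ag22.to_dense(), "A")  # ref for blend
    g05 = g_vanraden(genotypes, center="half")
    g05b = blend_g(g05, ag22, blend_weight)
    hginv = h_gamma_inverse(aginv, ag22, g05b, gids)
    return RelationshipBundle(
        pedigree=pedigree,
        genotyped_ids=gids,
        q=q_full,
        gamma=gamma,
        k=k_scalar(gamma),
        a_inv=ainv,
        a22=a22,
        g_blend=gb,
        h_inv=hinv,
        a_gamma_inv=aginv,
        a_gamma22=ag22,
        g05_blend=g05b,
        h_gamma_inv=hginv,
    )


def variant_inputs(
    bundle: RelationshipBundle, spec: ModelSpec
) -> tuple[RelationshipMatrix, dict]:
    """The relationship inverse and extras (gamma/q) a model variant needs."""
    v = spec.variant
    if v == "ABLUP":
        return bundle.a_inv, {}
    if v == "ABLUP_UPG":
        return bundle.a_inv, {"q": bundle.q}
    if v == "ABLUP_MF":
        return bundle.a_gamma_inv, {"gamma": bundle.gamma}
    if v == "HBLUP":
        return bundle.h_inv, {}
    if v == "HBLUP_MF":
        return bundle.h_gamma_inv, {"gamma": bundle.gamma}
    raise ValueError(f"unknown variant {v!r}")


def h_diagonal(
    pedigree: Pedigree,
    genotypes_or_gids,
    g_blend: RelationshipMatrix,
    ids: list[str],
) -> pd.Series:
    """Diagonal of the (group-free) H matrix for selected individuals.

    ``H22 = G`` for genotyped ids; for ungenotyped ids
    ``H11 = A11 + A12 A22^{-1} (G - A22) A22^{-1} A21`` is evaluated
    row-wise, so no full dense H is formed.
    """
    gids = (
        list(genotypes_or_gids.individual_ids)
        if hasattr(genotypes_or_gids, "individual_ids")
        else [str(i) for i in genotypes_or_gids]
    )
    if list(g_blend.entity_ids) != gids:
        raise ValueError("g_blend must be ordered over the genotyped ids")
    ids = [str(i) for i in ids]
    gset = set(gids)
    out = pd.Series(np.nan, index=ids, dtype=float, name="h_diag")
    geno_part = [i for i in ids if i in gset]
    if geno_part:
        gi = g_blend.index_of(geno_part)
        out[geno_part] = g_blend.to_dense()[gi, gi]
    rest = [i for i in ids if i not in gset]
    if rest:
        sub = a_matrix(pedigree, subset=rest + gids).to_dense()
        n1 = len(rest)
        A11d = np.diag(sub)[:n1]
        A12 = sub[:n1, n1:]
        A22 = sub[n1:, n1:]
        W = np.linalg.solve(A22, A12.T).T
        mid = g_blend.to_dense() - A22
        out[rest] = A11d + np.einsum("ij,jk,ik->i", W, mid, W)
    return out
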