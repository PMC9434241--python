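"""Single-step combined relationship matrices.

``H^{-1}`` merges the sparse pedigree inverse with a genomic correction on
the genotyped block: ``H^{-1} = A^{-1} + [0 0; 0 G^{-1} - A22^{-1}]``. The
metafounder variant applies the same correction around the Gamma-augmented
pedigree inverse, with ``G05`` and ``A_gamma22`` sharing the 0.5-frequency
base; metafounder rows of the correction stay zero.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .relmat import RelationshipMatrix

_DENSE_GUARD = 20_000


def _genotyped_correction(
    a_ref22: RelationshipMatrix,
    g_blend: RelationshipMatrix,
    genotyped_ids: Sequence[str],
) -> np.ndarray:
    gids = [str(i) for i in genotyped_ids]
    if list(g_blend.entity_ids) != gids or list(a_ref22.entity_ids) != gids:
        raise ValueError(
            "g and a22 must be ordered exactly over genotyped_ids"
        )
    G = g_blend.to_dense()
    A22 = a_ref22.to_dense()
    try:
        Ginv = np.linalg.inv(G)
        if np.linalg.cond(G) > 1e10:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        raise ValueError(
            "G is singular or ill-conditioned; blend with the pedigree "
            "reference (blend_g) before assembling H^-1"
        ) from None
    A22inv = np.linalg.inv(A22)
    corr = Ginv - A22inv
    return 0.5 * (corr + corr.T)


def _add_correction(
    base_inv: RelationshipMatrix,
    corr: np.ndarray,
    genotyped_ids: Sequence[str],
    kind: str,
) -> RelationshipMatrix:
    idx = base_inv.index_of(genotyped_ids)
    n = base_inv.n
    corr_sparse = sp.coo_array(
        (
            corr.ravel(),
            (np.repeat(idx, len(idx)), np.tile(idx, len(idx))),
        ),
        shape=(n, n),
    )
    values = (sp.csr_array(base_inv.values) + sp.csr_array(corr_sparse)).tocsr()
    return RelationshipMatrix(list(base_inv.entity_ids), values, kind)


def h_inverse(
    a_inv: RelationshipMatrix,
    a22: RelationshipMatrix,
    g_blend: RelationshipMatrix,
    genotyped_ids: Sequence[str],
) -> RelationshipMatrix:
    """Plain single-step inverse ``H^{-1}`` (no base-population structure)."""
    corr = _genotyped_correction(a22, g_blend, genotyped_ids)
    return _add_correction(a_inv, corr, genotyped_ids, "H_inv")


def h_gamma_inverse(
    a_gamma_inv: RelationshipMatrix,
    a_gamma22: RelationshipMatrix,
    g05_blend: RelationshipMatrix,
    genotyped_ids: Sequence[str],
) -> RelationshipMatrix:
    """Gamma-augmented single-step inverse ``H_gamma^{-1}``.

    The genomic correction touches only the genotyped block; metafounder
    rows/columns of the correction are structurally zero.
    """
    corr = _genotyped_correction(a_gamma22, g05_blend, genotyped_ids)
    return _add_correction(a_gamma_inv, corr, genotyped_ids, "H_gamma_inv")


def h_direct(
    a: RelationshipMatrix,
    a22: RelationshipMatrix,
    g: RelationshipMatrix,
    genotyped_ids: Sequence[str],
) -> RelationshipMatrix:
    """Dense ``H`` for inspection/testing (inverse of the ``H^{-1}`` assembly).

    ``H11 = A11 + A12 A22^{-1} (G - A22) A22^{-1} A21``,
    ``H12 = A12 A22^{-1} G``, ``H22 = G``. Pass ``A`` or ``A_gamma`` (with
    metafounder rows) as appropriate.
    """
    if a.n > _DENSE_GUARD:
        raise MemoryError(
            f"refusing to build dense H over {a.n} entities (> {_DENSE_GUARD})"
        )
    gids = [str(i) for i in genotyped_ids]
    if not gids:
        return RelationshipMatrix(list(a.entity_ids), a.to_dense(), "H_direct")
    if list(g.entity_ids) != gids or list(a22.entity_ids) != gids:
        raise ValueError("g and a22 must be ordered exactly over genotyped_ids")
    A = a.to_dense()
    idx2 = a.index_of(gids)
    mask = np.ones(a.n, dtype=bool)
    mask[idx2] = False
    idx1 = np.flatnonzero(mask)
    G = g.to_dense()
    A22 = a22.to_dense()
    H = A.copy()
    if idx1.size:
        A12 = A[np.ix_(idx1, idx2)]
        W = np.linalg.solve(A22, A12.T).T  # A12 A22^{-1}
        H[np.ix_(idx1, idx1)] = A[np.ix_(idx1, idx1)] + W @ (G - A22) @ W.T
        H12 = W @ G
        H[np.ix_(idx1, idx2)] = H12
        H[np.ix_(idx2, idx1)] = H12.T
    H[np.ix_(idx2, idx2)] = G
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(list(a.entity_ids), H, "H_direct")


def inbreeding_from_h(
    h: RelationshipMatrix, ids: Sequence[str] | None = None
) -> tuple[pd.Series, float]:
    """Per-individual inbreeding ``F_i = H_ii - 1`` and its mean over ``ids``."""
    if ids is None:
        ids = list(h.entity_ids)
    idx = h.index_of(ids)
    F = h.diagonal()[idx] - 1.0
    series = pd.Series(F, index=[str(i) for i in ids], name="F")
    return series, float(np.mean(F))
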