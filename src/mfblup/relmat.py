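"""Relationship-matrix container shared across the pipeline.

Every relationship matrix (pedigree ``A``, genomic ``G``, combined ``H`` and
their inverses) is carried together with the ordered list of entities it is
defined over, so that algebraic operations can refuse to combine matrices
whose orderings disagree instead of silently misaligning individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

#: Recognised matrix kinds. ``A_gamma`` matrices include metafounder rows.
KINDS = (
    "A",
    "A_inv",
    "A_gamma",
    "A_gamma_inv",
    "A_star_inv",
    "G_obs",
    "G_scaled",
    "G_blend",
    "G05",
    "H_inv",
    "H_gamma_inv",
    "H_direct",
)

#: Kinds that are relationship (not inverse) matrices and must have
#: nonnegative diagonals.
_COVARIANCE_KINDS = {"A", "A_gamma", "G_obs", "G_scaled", "G_blend", "G05", "H_direct"}

SYMMETRY_TOL = 1e-10


@dataclass
class RelationshipMatrix:
    """A symmetric matrix over an ordered entity list.

    Parameters
    ----------
    entity_ids
        Ordered labels: individuals, optionally followed by metafounders.
    values
        Symmetric matrix, dense ``ndarray`` or scipy sparse.
    kind
        One of :data:`KINDS`.
    """

    entity_ids: list[str]
    values: np.ndarray | sp.spmatrix
    kind: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.entity_ids = [str(e) for e in self.entity_ids]
        if self.kind not in KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if not sp.issparse(self.values):
            self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{n} entity ids"
            )
        if len(set(self.entity_ids)) != n:
            raise ValueError("duplicate entity ids")
        self._index = {e: i for i, e in enumerate(self.entity_ids)}
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if sp.issparse(v):
            asym = abs(v - v.T)
            max_asym = asym.max() if asym.nnz else 0.0
        else:
            max_asym = float(np.max(np.abs(v - v.T))) if v.size else 0.0
        if max_asym > SYMMETRY_TOL:
            raise ValueError(f"matrix not symmetric (max asymmetry {max_asym:g})")
        if self.kind in _COVARIANCE_KINDS:
            d = v.diagonal()
            if np.any(np.asarray(d) < 0):
                raise ValueError(f"{self.kind} has a negative diagonal entry")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[str(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"entity id {exc.args[0]!r} not present") from None

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def submatrix(self, ids: Sequence[str], kind: str | None = None) -> "RelationshipMatrix":
        """Restrict to ``ids`` (in the order given)."""
        idx = self.index_of(ids)
        dense = self.to_dense()
        return RelationshipMatrix(
            [str(i) for i in ids], dense[np.ix_(idx, idx)], kind or self.kind
        )

    def diagonal(self) -> np.ndarray:
        return np.asarray(self.values.diagonal()).ravel()

    def same_ordering(self, other: "RelationshipMatrix") -> bool:
        return self.entity_ids == other.entity_ids


def require_same_ordering(*mats: RelationshipMatrix) -> None:
    first = mats[0]
    for m in mats[1:]:
        if not first.same_ordering(m):
            raise ValueError(
                f"entity orderings differ between {first.kind} and {m.kind} matrices"
            )
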