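"""Pedigree handling and numerator relationship matrix algebra.

Implements the tabular method for ``A`` and its metafounder-augmented
counterpart ``A_gamma`` (metafounders enter the recursion as base
pseudo-individuals whose mutual relationships are the Gamma matrix), plus
Henderson-rule sparse inverses with Mendelian-sampling variances computed
from pedigree (or Gamma-augmented) inbreeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .relmat import RelationshipMatrix

MISSING_PARENT_CODES = {"", "0", "NA", "na", ".", "None"}


class PedigreeError(ValueError):
    pass


def _norm_parent(p) -> str | None:
    if p is None:
        return None
    p = str(p).strip()
    return None if p in MISSING_PARENT_CODES else p


@dataclass
class Pedigree:
    """Ordered pedigree records with optional metafounder labels.

    ``sire_group[i]`` / ``dam_group[i]`` give the metafounder label assigned
    to a missing parent slot of individual ``i``; slots with a known parent
    carry ``None``.
    """

    ids: list[str]
    sires: list[str | None]
    dams: list[str | None]
    sire_groups: list[str | None] = field(default_factory=list)
    dam_groups: list[str | None] = field(default_factory=list)
    is_sorted: bool = False
    phantoms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.ids = [str(i) for i in self.ids]
        self.sires = [_norm_parent(s) for s in self.sires]
        self.dams = [_norm_parent(d) for d in self.dams]
        if not self.sire_groups:
            self.sire_groups = [None] * n
        if not self.dam_groups:
            self.dam_groups = [None] * n
        if not (len(self.sires) == len(self.dams) == n):
            raise PedigreeError("ids/sires/dams length mismatch")
        if len(set(self.ids)) != n:
            dup = pd.Series(self.ids).value_counts()
            raise PedigreeError(f"duplicate id: {dup.index[0]!r}")
        self._index = {v: i for i, v in enumerate(self.ids)}

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def metafounder_labels(self) -> list[str]:
        """Ordered unique metafounder labels (order of first appearance)."""
        seen: dict[str, None] = {}
        for g in list(self.sire_groups) + list(self.dam_groups):
            if g is not None and g not in seen:
                seen[g] = None
        return list(seen)

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[str(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise PedigreeError(f"unknown individual id {exc.args[0]!r}") from None

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire_idx, dam_idx) with -1 for a missing parent. Requires sorted."""
        self._require_sorted()
        s = np.array([self._index[p] if p is not None else -1 for p in self.sires])
        d = np.array([self._index[p] if p is not None else -1 for p in self.dams])
        return s, d

    def _require_sorted(self) -> None:
        if not self.is_sorted:
            raise PedigreeError("pedigree must pass sort_and_validate first")


# ----------------------------------------------------------------------
# sorting / validation
# ----------------------------------------------------------------------

def sort_and_validate(pedigree: Pedigree) -> Pedigree:
    """Topologically sort a pedigree, materializing phantom parents.

    Parents referenced but never listed as records are added as founders
    (reported in ``phantoms``). Raises on cycles (naming one individual on
    the cycle) and on duplicate ids (at construction).
    """
    if pedigree.n == 0:
        raise PedigreeError("empty pedigree")
    known = set(pedigree.ids)
    phantoms: list[str] = []
    for p in list(pedigree.sires) + list(pedigree.dams):
        if p is not None and p not in known:
            known.add(p)
            phantoms.append(p)

    ids = phantoms + pedigree.ids
    sires = [None] * len(phantoms) + list(pedigree.sires)
    dams = [None] * len(phantoms) + list(pedigree.dams)
    sgrp = [None] * len(phantoms) + list(pedigree.sire_groups)
    dgrp = [None] * len(phantoms) + list(pedigree.dam_groups)

    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sires[i], dams[i]):
            if p is not None:
                children[index[p]].append(i)
                indeg[i] += 1

    # Kahn's algorithm, stable in input order
    order: list[int] = []
    queue = [i for i in range(n) if indeg[i] == 0]
    head = 0
    while head < len(queue):
        i = queue[head]
        head += 1
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) < n:
        on_cycle = next(ids[i] for i in range(n) if indeg[i] > 0)
        raise PedigreeError(f"pedigree cycle detected involving {on_cycle!r}")

    sorted_ped = Pedigree(
        ids=[ids[i] for i in order],
        sires=[sires[i] for i in order],
        dams=[dams[i] for i in order],
        sire_groups=[sgrp[i] for i in order],
        dam_groups=[dgrp[i] for i in order],
        is_sorted=True,
        phantoms=phantoms,
    )
    return sorted_ped


# ----------------------------------------------------------------------
# tabular relationship matrices
# ----------------------------------------------------------------------

def _ancestor_closure(pedigree: Pedigree, idx: Iterable[int]) -> np.ndarray:
    """Indices of ``idx`` plus all their ancestors, in pedigree order."""
    s, d = pedigree.parent_indices()
    keep = np.zeros(pedigree.n, dtype=bool)
    stack = list(idx)
    while stack:
        i = stack.pop()
        if keep[i]:
            continue
        keep[i] = True
        for p in (s[i], d[i]):
            if p >= 0 and not keep[p]:
                stack.append(p)
    return np.flatnonzero(keep)


def _tabular(
    pedigree: Pedigree,
    closure: np.ndarray,
    gamma_values: np.ndarray | None = None,
    mf_index: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Dense tabular relationship matrix over ``closure`` individuals.

    When ``gamma_values`` is given the matrix is Gamma-augmented: the first
    K rows/columns are metafounders with base block Gamma, and every missing
    parent slot points at its metafounder.
    """
    s_all, d_all = pedigree.parent_indices()
    K = 0 if gamma_values is None else gamma_values.shape[0]
    pos = {g: K + t for t, g in enumerate(closure)}  # global ped idx -> local
    n = K + len(closure)
    A = np.zeros((n, n))
    if K:
        A[:K, :K] = gamma_values

    for t, g in enumerate(closure):
        i = K + t
        parents: list[int] = []
        for pidx, grp in (
            (s_all[g], pedigree.sire_groups[g]),
            (d_all[g], pedigree.dam_groups[g]),
        ):
            if pidx >= 0:
                parents.append(pos[pidx])
            elif gamma_values is not None:
                if grp is None:
                    raise PedigreeError(
                        f"missing parent of {pedigree.ids[g]!r} has no "
                        "metafounder label"
                    )
                parents.append(mf_index[grp])  # type: ignore[index]
        if parents:
            row = A[parents, :i].sum(axis=0) * 0.5
            A[i, :i] = row
            A[:i, i] = row
        if len(parents) == 2:
            A[i, i] = 1.0 + 0.5 * A[parents[0], parents[1]]
        else:
            A[i, i] = 1.0
    return A


def a_matrix(
    pedigree: Pedigree, subset: Sequence[str] | None = None
) -> RelationshipMatrix:
    """Pedigree numerator relationship matrix by the tabular method.

    ``diag(A) = 1 + F`` with ``F`` the classical inbreeding coefficient.
    With ``subset``, the full recursion is run over the subset's ancestor
    closure and then restricted, so values match the full matrix.
    """
    pedigree._require_sorted()
    if subset is None:
        target = np.arange(pedigree.n)
        out_ids = list(pedigree.ids)
    else:
        target = pedigree.index_of(subset)
        out_ids = [str(i) for i in subset]
    closure = _ancestor_closure(pedigree, target)
    A = _tabular(pedigree, closure)
    local = {g: t for t, g in enumerate(closure)}
    take = np.array([local[g] for g in target])
    return RelationshipMatrix(out_ids, A[np.ix_(take, take)], "A")


def a_gamma_matrix(
    pedigree: Pedigree,
    gamma: "GammaMatrix",
    subset: Sequence[str] | None = None,
    include_metafounders: bool = True,
) -> RelationshipMatrix:
    """Gamma-augmented relationship matrix ``A_gamma``.

    Metafounders act as base pseudo-individuals related by Gamma; each base
    individual is treated as offspring of its metafounder(s), so a founder
    with both unknown parents in group ``g`` has diagonal ``1 + Gamma_gg/2``.
    Entity order: individuals, then metafounders.
    """
    pedigree._require_sorted()
    labels = list(gamma.labels)
    mf_index = {g: t for t, g in enumerate(labels)}
    for g in pedigree.metafounder_labels:
        if g not in mf_index:
            raise PedigreeError(f"pedigree group {g!r} absent from gamma matrix")
    K = len(labels)
    if subset is None:
        target = np.arange(pedigree.n)
        out_ids = list(pedigree.ids)
    else:
        target = pedigree.index_of(subset)
        out_ids = [str(i) for i in subset]
    closure = _ancestor_closure(pedigree, target)
    A = _tabular(pedigree, closure, gamma_values=gamma.values, mf_index=mf_index)
    local = {g: K + t for t, g in enumerate(closure)}
    take = [local[g] for g in target]
    if include_metafounders:
        take += list(range(K))
        out_ids = out_ids + labels
    take = np.array(take)
    return RelationshipMatrix(out_ids, A[np.ix_(take, take)], "A_gamma")


# ----------------------------------------------------------------------
# sparse inverses (Henderson rules)
# ----------------------------------------------------------------------

def _parent_set_relationships(
    pedigree: Pedigree, gamma: "GammaMatrix | None" = None
) -> tuple[np.ndarray, dict[int, int], int]:
    """Dense (Gamma-augmented) relationships over everyone who is a parent.

    Mendelian-sampling variances only require relationships among parents,
    so the dense tabular recursion is run over the parent set's ancestor
    closure — small even for large pedigrees.
    Returns (matrix, map global index -> local index, K).
    """
    s, d = pedigree.parent_indices()
    parents = np.unique(np.concatenate([s[s >= 0], d[d >= 0]]))
    closure = _ancestor_closure(pedigree, parents) if parents.size else parents
    if gamma is None:
        A = _tabular(pedigree, closure)
        K = 0
    else:
        mf_index = {g: t for t, g in enumerate(gamma.labels)}
        A = _tabular(pedigree, closure, gamma_values=gamma.values, mf_index=mf_index)
        K = len(gamma.labels)
    local = {g: K + t for t, g in enumerate(closure)}
    return A, local, K


def inbreeding(pedigree: Pedigree) -> pd.Series:
    """Classical pedigree inbreeding coefficients ``F`` for all individuals."""
    pedigree._require_sorted()
    s, d = pedigree.parent_indices()
    A, local, _ = _parent_set_relationships(pedigree)
    F = np.zeros(pedigree.n)
    for i in range(pedigree.n):
        if s[i] >= 0 and d[i] >= 0:
            F[i] = 0.5 * A[local[s[i]], local[d[i]]]
    return pd.Series(F, index=pedigree.ids, name="F")


def a_inverse(pedigree: Pedigree) -> RelationshipMatrix:
    """Sparse ``A^{-1}`` by Henderson's rules with inbreeding.

    Mendelian-sampling variances use parental inbreeding computed by the
    tabular recursion over the parent set (equivalent to the
    Meuwissen–Luo recursion).
    """
    pedigree._require_sorted()
    s, d = pedigree.parent_indices()
    A, local, _ = _parent_set_relationships(pedigree)
    n = pedigree.n

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        ps = [p for p in (s[i], d[i]) if p >= 0]
        if len(ps) == 2:
            dq = 0.5 - 0.25 * (
                (A[local[ps[0]], local[ps[0]]] - 1.0)
                + (A[local[ps[1]], local[ps[1]]] - 1.0)
            )
        elif len(ps) == 1:
            dq = 0.75 - 0.25 * (A[local[ps[0]], local[ps[0]]] - 1.0)
        else:
            dq = 1.0
        b = 1.0 / dq
        rows.append(i), cols.append(i), vals.append(b)
        for p in ps:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * b, -0.5 * b]
        for p in ps:
            for q in ps:
                rows.append(p), cols.append(q), vals.append(0.25 * b)
    Ainv = sp.csr_array(
        sp.coo_array((vals, (rows, cols)), shape=(n, n))
    )
    return RelationshipMatrix(list(pedigree.ids), Ainv, "A_inv")


def a_gamma_inverse(pedigree: Pedigree, gamma: "GammaMatrix") -> RelationshipMatrix:
    """Sparse Gamma-augmented inverse (metafounder block carries ``Gamma^{-1}``).

    Henderson-style assembly in which every individual has two parent slots
    (a known parent or its metafounder) and Mendelian-sampling variances come
    from the Gamma-augmented tabular recursion over the parent set.
    """
    pedigree._require_sorted()
    labels = list(gamma.labels)
    K = len(labels)
    mf_index = {g: t for t, g in enumerate(labels)}
    try:
        gamma_inv = np.linalg.inv(gamma.values)
        if not np.all(np.isfinite(gamma_inv)) or np.linalg.cond(gamma.values) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        raise ValueError(
            "gamma matrix is singular; apply PSD repair (psd_repair) first"
        ) from None

    s, d = pedigree.parent_indices()
    A, local, _ = _parent_set_relationships(pedigree, gamma)
    n = pedigree.n
    # entity order: individuals 0..n-1, metafounders n..n+K-1
    def slot(pidx: int, grp: str | None, who: str) -> int:
        if pidx >= 0:
            return pidx
        if grp is None:
            raise PedigreeError(
                f"missing parent of {who!r} has no metafounder label"
            )
        return n + mf_index[grp]

    # local (parent-set) position of an entity, for relationship lookups
    def rel(e1: int, e2: int) -> float:
        l1 = e1 - n if e1 >= n else local[e1]
        l2 = e2 - n if e2 >= n else local[e2]
        return A[l1, l2]

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        p1 = slot(s[i], pedigree.sire_groups[i], pedigree.ids[i])
        p2 = slot(d[i], pedigree.dam_groups[i], pedigree.ids[i])
        a12 = rel(p1, p2)
        dq = (1.0 + 0.5 * a12) - 0.25 * (rel(p1, p1) + 2.0 * a12 + rel(p2, p2))
        b = 1.0 / dq
        rows.append(i), cols.append(i), vals.append(b)
        for p in (p1, p2):
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * b, -0.5 * b]
        for p in (p1, p2):
            for q in (p1, p2):
                rows.append(p), cols.append(q), vals.append(0.25 * b)
    for a_ in range(K):
        for b_ in range(K):
            if gamma_inv[a_, b_] != 0.0:
                rows.append(n + a_), cols.append(n + b_)
                vals.append(gamma_inv[a_, b_])
    m = n + K
    Aginv = sp.csr_array(sp.coo_array((vals, (rows, cols)), shape=(m, m)))
    return RelationshipMatrix(list(pedigree.ids) + labels, Aginv, "A_gamma_inv")


# ----------------------------------------------------------------------
# unknown-parent-group design
# ----------------------------------------------------------------------

def upg_design(pedigree: Pedigree) -> pd.DataFrame:
    """Expected group (metafounder) contributions ``Q`` per individual.

    Founder rows are group indicators; every offspring row is the mean of
    its parents' rows (a missing slot contributes its group's indicator).
    Rows sum to 1 exactly.
    """
    pedigree._require_sorted()
    labels = pedigree.metafounder_labels
    if not labels:
        raise PedigreeError("no metafounder labels assigned in pedigree")
    mf_index = {g: t for t, g in enumerate(labels)}
    s, d = pedigree.parent_indices()
    Q = np.zeros((pedigree.n, len(labels)))
    for i in range(pedigree.n):
        row = np.zeros(len(labels))
        for pidx, grp in (
            (s[i], pedigree.sire_groups[i]),
            (d[i], pedigree.dam_groups[i]),
        ):
            if pidx >= 0:
                row += 0.5 * Q[pidx]
            else:
                if grp is None:
                    raise PedigreeError(
                        f"missing parent of {pedigree.ids[i]!r} has no "
                        "metafounder label"
                    )
                row[mf_index[grp]] += 0.5
        Q[i] = row
    return pd.DataFrame(Q, index=pedigree.ids, columns=labels)


# ----------------------------------------------------------------------
# genotype/pedigree consistency
# ----------------------------------------------------------------------

def genotype_pedigree_conflicts(
    pedigree: Pedigree, genotypes: "GenotypeMatrix", threshold: float = 0.02
) -> pd.DataFrame:
    """Opposing-homozygote screen of declared parent-offspring pairs.

    For every pedigree link where both members are genotyped, counts loci at
    which parent and offspring are opposite homozygotes (0 vs 2). True
    parent-offspring pairs have rate 0 up to genotyping error; pairs above
    ``threshold`` are flagged as probable pedigree errors.
    """
    pedigree._require_sorted()
    geno_index = {g: i for i, g in enumerate(genotypes.individual_ids)}
    shared = [i for i in pedigree.ids if i in geno_index]
    if not shared:
        raise ValueError("no ids shared between pedigree and genotypes")
    M = np.ma.masked_invalid(genotypes.gene_content.astype(float))

    out = []
    for i, ind in enumerate(pedigree.ids):
        if ind not in geno_index:
            continue
        gi = M[geno_index[ind]]
        for parent, role in ((pedigree.sires[i], "sire"), (pedigree.dams[i], "dam")):
            if parent is None or parent not in geno_index:
                continue
            gp = M[geno_index[parent]]
            both = ~(gi.mask | gp.mask) if np.ma.is_masked(gi) or np.ma.is_masked(gp) \
                else np.ones(M.shape[1], dtype=bool)
            n_loci = int(np.sum(both))
            opposing = int(
                np.sum(((gi == 0) & (gp == 2) | (gi == 2) & (gp == 0)) & both)
            )
            rate = opposing / n_loci if n_loci else np.nan
            out.append(
                {
                    "individual": ind,
                    "parent": parent,
                    "role": role,
                    "n_loci": n_loci,
                    "n_opposing": opposing,
                    "rate": rate,
                    "flagged": bool(rate > threshold) if n_loci else False,
                }
            )
    return pd.DataFrame(
        out,
        columns=[
            "individual", "parent", "role", "n_loci", "n_opposing", "rate", "flagged",
        ],
    )
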