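"""Mixed-model equations and BLUP solving.

The linear mixed model is ``y = Xb + Z1 a + Z2 f + e`` with site fixed
effects ``b``, additive genetic effects ``a`` (pedigree, genomic or combined
relationship structure, optionally with metafounders or unknown-parent
groups), full-sib family effects ``f ~ N(0, I sigma_f2)`` and residual
``e ~ N(0, I sigma_e2)`` (optionally per-site residual variances).

Model variants differ only in ``var(a)``:

========== ==========================================
ABLUP      ``A sigma_a2`` (founders unrelated)
ABLUP_UPG  ``A`` plus fixed unknown-parent groups (Quaas-Pollak device)
ABLUP_MF   ``A_gamma sigma_a2`` (metafounders, random)
HBLUP      ``H sigma_a2`` (single-step, blended G)
HBLUP_MF   ``H_gamma sigma_a2`` (single-step with metafounders, G05)
========== ==========================================

For metafounder variants the additive variance is divided by the scalar
``k = 1 + mean(diag(Gamma))/2 - mean(Gamma)`` so it is comparable with the
classical parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .gamma import GammaMatrix, k_scalar
from .relmat import RelationshipMatrix

VARIANTS = ("ABLUP", "ABLUP_UPG", "ABLUP_MF", "HBLUP", "HBLUP_MF")
MF_VARIANTS = ("ABLUP_MF", "HBLUP_MF")

#: relationship-inverse kind expected for each variant
VARIANT_KINDS: dict[str, tuple[str, ...]] = {
    "ABLUP": ("A_inv",),
    "ABLUP_UPG": ("A_inv", "A_star_inv"),
    "ABLUP_MF": ("A_gamma_inv",),
    "HBLUP": ("H_inv",),
    "HBLUP_MF": ("H_gamma_inv",),
}


@dataclass
class ModelSpec:
    """Model variant plus (fixed) variance components.

    Variances are on the per-trial-standardized phenotype scale
    (phenotypic SD^2 units).
    """

    variant: str
    sigma_a2: float
    sigma_f2: float
    sigma_e2: float
    apply_k: bool = True
    residual_mode: str = "homogeneous"
    site_sigma_e2: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown model variant {self.variant!r}")
        for name in ("sigma_a2", "sigma_f2", "sigma_e2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.apply_k and self.variant not in MF_VARIANTS:
            # silently meaningless for non-MF variants; normalize
            self.apply_k = False
        if self.residual_mode not in ("homogeneous", "per-site"):
            raise ValueError("residual_mode must be 'homogeneous' or 'per-site'")
        if self.residual_mode == "per-site" and not self.site_sigma_e2:
            raise ValueError("per-site residual mode needs site_sigma_e2")


@dataclass
class Solutions:
    """Solved effects from one model fit."""

    fixed_effects: pd.Series
    additive: pd.Series            # individual-level (G)EBVs
    metafounders: pd.Series        # MF solutions (MF variants), else empty
    groups: pd.Series              # UPG solutions (UPG variant), else empty
    family: pd.Series
    convergence_meta: dict = field(default_factory=dict)

    @property
    def all_additive(self) -> pd.Series:
        """Individual plus metafounder solutions, in system order."""
        return pd.concat([self.additive, self.metafounders])


@dataclass
class MMESystem:
    """Assembled symmetric sparse mixed-model equations."""

    coeff: sp.csr_array
    rhs: np.ndarray
    spec: ModelSpec
    site_labels: list[str]
    entity_ids: list[str]          # additive entities (individuals [+ MFs])
    n_individuals: int             # leading entities that are individuals
    family_labels: list[str]
    group_labels: list[str]        # UPG only (reference level dropped)
    dropped_group: str | None = None
    k_used: float = 1.0


def _validate_phenotypes(
    phenotypes: pd.DataFrame, known_ids: set[str]
) -> pd.DataFrame:
    required = {"id", "site", "family", "value"}
    missing_cols = required - set(phenotypes.columns)
    if missing_cols:
        raise ValueError(f"phenotype table missing columns: {sorted(missing_cols)}")
    ph = phenotypes.copy()
    for c in ("id", "site", "family"):
        ph[c] = ph[c].astype(str)
    unknown = sorted(set(ph["id"]) - known_ids)
    if unknown:
        raise ValueError(
            f"{len(unknown)} phenotyped ids missing from the relationship "
            f"structure, e.g. {unknown[:10]}"
        )
    return ph


def build_mme(
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    k_inv: RelationshipMatrix,
    gamma: GammaMatrix | None = None,
    q: pd.DataFrame | None = None,
) -> MMESystem:
    """Assemble the sparse mixed-model equations.

    Parameters
    ----------
    phenotypes
        Records with columns ``id, site, family, value``.
    k_inv
        Relationship-structure inverse matching the variant (``A_inv``,
        ``H_inv``, ``A_gamma_inv``, ...). For metafounder variants its
        entity list carries the metafounder labels at the end.
    gamma
        Needed when ``spec.apply_k`` to compute the k scalar.
    q
        Unknown-parent-group contribution matrix (individuals x groups);
        required for ``ABLUP_UPG``. Group effects enter unpenalized via the
        Quaas-Pollak device, with the last group dropped as reference level.
    """
    if k_inv.kind not in VARIANT_KINDS[spec.variant]:
        raise ValueError(
            f"variant {spec.variant} expects a relationship inverse of kind "
            f"{VARIANT_KINDS[spec.variant]}, got {k_inv.kind}"
        )
    entity_ids = list(k_inv.entity_ids)
    if spec.variant in MF_VARIANTS:
        if gamma is None:
            raise ValueError("metafounder variants need the gamma matrix")
        n_mf = gamma.k
        if entity_ids[-n_mf:] != list(gamma.labels):
            raise ValueError(
                "relationship inverse must end with the metafounder labels"
            )
        n_ind = len(entity_ids) - n_mf
    else:
        n_ind = len(entity_ids)

    ph = _validate_phenotypes(phenotypes, set(entity_ids[:n_ind]))
    nrec = len(ph)
    site_labels = sorted(ph["site"].unique())
    family_labels = sorted(ph["family"].unique())
    ent_index = {e: i for i, e in enumerate(entity_ids)}
    site_index = {s: i for i, s in enumerate(site_labels)}
    fam_index = {f: i for i, f in enumerate(family_labels)}

    rows = np.arange(nrec)
    ones = np.ones(nrec)
    X = sp.csr_array(
        (ones, (rows, ph["site"].map(site_index).to_numpy())),
        shape=(nrec, len(site_labels)),
    )
    Z1 = sp.csr_array(
        (ones, (rows, ph["id"].map(ent_index).to_numpy())),
        shape=(nrec, len(entity_ids)),
    )
    Z2 = sp.csr_array(
        (ones, (rows, ph["family"].map(fam_index).to_numpy())),
        shape=(nrec, len(family_labels)),
    )
    y = ph["value"].to_numpy(dtype=float)

    if spec.residual_mode == "per-site":
        missing = set(site_labels) - set(spec.site_sigma_e2)
        if missing:
            raise ValueError(f"no residual variance for sites {sorted(missing)}")
        w = 1.0 / ph["site"].map(spec.site_sigma_e2).to_numpy(dtype=float)
    else:
        w = np.full(nrec, 1.0 / spec.sigma_e2)
    Rinv = sp.dia_array((w, 0), shape=(nrec, nrec))

    k = k_scalar(gamma) if (spec.apply_k and gamma is not None) else 1.0
    prec_a = 1.0 / (spec.sigma_a2 / k)
    prec_f = 1.0 / spec.sigma_f2

    W = sp.hstack([X, Z1, Z2], format="csr")
    C = (W.T @ Rinv @ W).tolil()
    nb, na, nf = len(site_labels), len(entity_ids), len(family_labels)
    Kinv = sp.csr_array(k_inv.values) * prec_a
    C[nb : nb + na, nb : nb + na] = C[nb : nb + na, nb : nb + na] + Kinv
    fam_block = sp.identity(nf, format="csr") * prec_f
    C[nb + na :, nb + na :] = C[nb + na :, nb + na :] + fam_block
    rhs = W.T @ (Rinv @ y)

    group_labels: list[str] = []
    dropped: str | None = None
    if spec.variant == "ABLUP_UPG":
        if q is None:
            raise ValueError("ABLUP_UPG needs the group contribution matrix q")
        if list(q.index) != entity_ids:
            raise ValueError("q rows must match the relationship entity ordering")
        all_groups = [str(c) for c in q.columns]
        if len(all_groups) < 2:
            raise ValueError("UPG model needs at least 2 groups")
        dropped = all_groups[-1]
        group_labels = all_groups[:-1]
        Qm = sp.csr_array(q[group_labels].to_numpy(dtype=float))
        Ainv = sp.csr_array(k_inv.values) * prec_a
        AinvQ = Ainv @ Qm
        QAinvQ = Qm.T @ AinvQ
        ng = len(group_labels)
        C = sp.bmat(
            [
                [C, sp.vstack(
                    [sp.csr_array((nb, ng)), -AinvQ, sp.csr_array((nf, ng))]
                )],
                [
                    sp.hstack(
                        [sp.csr_array((ng, nb)), -AinvQ.T, sp.csr_array((ng, nf))]
                    ),
                    QAinvQ,
                ],
            ],
            format="lil",
        )
        rhs = np.concatenate([rhs, np.zeros(ng)])

    return MMESystem(
        coeff=sp.csr_array(C),
        rhs=rhs,
        spec=spec,
        site_labels=site_labels,
        entity_ids=entity_ids,
        n_individuals=n_ind,
        family_labels=family_labels,
        group_labels=group_labels,
        dropped_group=dropped,
        k_used=k,
    )


def solve_blup(system: MMESystem, method: str = "direct") -> Solutions:
    """Solve the mixed-model equations.

    ``direct`` uses a sparse LU factorization; ``cg`` uses Jacobi-
    preconditioned conjugate gradients from a zero start. The relative
    residual of the returned solution is checked (1e-10 direct, 1e-8
    iterative).
    """
    C = sp.csc_matrix(system.coeff)
    rhs = system.rhs
    rhs_norm = float(np.linalg.norm(rhs))
    meta: dict = {"method": method}
    if method == "direct":
        x = spla.spsolve(C, rhs)
        tol = 1e-10
    elif method == "cg":
        diag = C.diagonal()
        Mpre = spla.LinearOperator(C.shape, matvec=lambda v: v / diag)
        residuals: list[float] = []

        def cb(xk):
            residuals.append(float(np.linalg.norm(rhs - C @ xk)))

        x, info = spla.cg(
            C, rhs, x0=np.zeros_like(rhs), rtol=1e-12, atol=0.0,
            maxiter=20000, M=Mpre, callback=cb,
        )
        if info != 0:
            raise RuntimeError(
                f"CG failed to converge (info={info}); residual history tail: "
                f"{[f'{r:.3e}' for r in residuals[-5:]]}"
            )
        meta["iterations"] = len(residuals)
        tol = 1e-8
    else:
        raise ValueError(f"unknown solve method {method!r}")

    rel_res = float(np.linalg.norm(rhs - C @ x)) / max(rhs_norm, 1e-300)
    if rel_res > tol:
        raise RuntimeError(f"solver residual {rel_res:.3e} exceeds {tol:.0e}")
    meta["relative_residual"] = rel_res

    nb = len(system.site_labels)
    na = len(system.entity_ids)
    nf = len(system.family_labels)
    n_ind = system.n_individuals
    fixed = pd.Series(x[:nb], index=system.site_labels, name="site")
    add_all = x[nb : nb + na]
    additive = pd.Series(
        add_all[:n_ind], index=system.entity_ids[:n_ind], name="ebv"
    )
    mf = pd.Series(
        add_all[n_ind:], index=system.entity_ids[n_ind:], name="mf", dtype=float
    )
    family = pd.Series(
        x[nb + na : nb + na + nf], index=system.family_labels, name="family"
    )
    if system.group_labels:
        g = pd.Series(
            x[nb + na + nf :], index=system.group_labels, name="group", dtype=float
        )
        g[system.dropped_group] = 0.0
    else:
        g = pd.Series(dtype=float, name="group")
    return Solutions(
        fixed_effects=fixed,
        additive=additive,
        metafounders=mf,
        groups=g,
        family=family,
        convergence_meta=meta,
    )


def fit(
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    k_inv: RelationshipMatrix,
    gamma: GammaMatrix | None = None,
    q: pd.DataFrame | None = None,
    method: str = "direct",
) -> Solutions:
    """Convenience wrapper: assemble and solve in one call."""
    return solve_blup(build_mme(phenotypes, spec, k_inv, gamma=gamma, q=q), method)
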