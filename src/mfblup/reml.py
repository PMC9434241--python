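"""EM-REML estimation of variance components for the site/additive/family model.

Intended for desk-scale estimation runs: variance components are estimated
once on a base model and then fixed for all model variants of a population
set. The E-step needs traces of blocks of the inverse mixed-model
coefficient matrix; these are computed exactly (dense inverse) on small
systems and by a seeded Hutchinson (Rademacher-probe) estimator on a sparse
LU factorization for large ones, with probes held fixed across iterations so
the iteration has a deterministic fixed point for a given seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import ModelSpec, _validate_phenotypes
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-8
_EXACT_LIMIT = 2500


@dataclass
class VarianceEstimates:
    sigma_a2: float
    sigma_f2: float
    sigma_e2: float
    h2: float
    n_iter: int
    converged: bool
    trace_mode: str
    history: list[tuple[float, float, float]] = field(default_factory=list)


def em_reml(
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    k_inv: RelationshipMatrix,
    max_iter: int = 400,
    tol: float = 1e-5,
    n_probes: int = 64,
    seed: int = 2023,
    trace_mode: str = "auto",
) -> VarianceEstimates:
    """Estimate ``(sigma_a2, sigma_f2, sigma_e2)`` by EM-REML.

    ``spec`` provides the model variant and starting values. Heritability is
    reported on the cross-site scale ``h2 = sa2 / (sa2 + sf2 + se2)``.
    """
    ph = _validate_phenotypes(phenotypes, set(k_inv.entity_ids))
    nrec = len(ph)
    entity_ids = list(k_inv.entity_ids)
    site_labels = sorted(ph["site"].unique())
    family_labels = sorted(ph["family"].unique())
    ent_index = {e: i for i, e in enumerate(entity_ids)}
    site_index = {s: i for i, s in enumerate(site_labels)}
    fam_index = {f: i for i, f in enumerate(family_labels)}
    nb, na, nf = len(site_labels), len(entity_ids), len(family_labels)

    rows = np.arange(nrec)
    ones = np.ones(nrec)
    X = sp.csr_array((ones, (rows, ph["site"].map(site_index).to_numpy())), shape=(nrec, nb))
    Z1 = sp.csr_array((ones, (rows, ph["id"].map(ent_index).to_numpy())), shape=(nrec, na))
    Z2 = sp.csr_array((ones, (rows, ph["family"].map(fam_index).to_numpy())), shape=(nrec, nf))
    y = ph["value"].to_numpy(dtype=float)
    W = sp.csc_matrix(sp.hstack([X, Z1, Z2]))
    WtW = (W.T @ W).tocsc()
    Wty = W.T @ y
    yty = float(y @ y)
    Ainv = sp.csc_matrix(k_inv.values)
    # penalty patterns embedded at full system size (scaled per iteration)
    pad_a = sp.block_diag(
        [sp.csr_array((nb, nb)), Ainv, sp.csr_array((nf, nf))], format="csc"
    )
    pad_f = sp.block_diag(
        [sp.csr_array((nb + na, nb + na)), sp.identity(nf)], format="csc"
    )

    ntot = nb + na + nf
    if trace_mode == "auto":
        trace_mode = "exact" if ntot <= _EXACT_LIMIT else "mc"
    if trace_mode not in ("exact", "mc"):
        raise ValueError("trace_mode must be 'auto', 'exact' or 'mc'")

    if trace_mode == "mc":
        rng = np.random.default_rng(seed)
        Pa = rng.choice([-1.0, 1.0], size=(na, n_probes))
        Pf = rng.choice([-1.0, 1.0], size=(nf, n_probes))
        RHSa = np.zeros((ntot, n_probes))
        RHSa[nb : nb + na] = Pa
        RHSf = np.zeros((ntot, n_probes))
        RHSf[nb + na :] = Pf
        AinvPa = Ainv @ Pa

    sa2, sf2, se2 = spec.sigma_a2, spec.sigma_f2, spec.sigma_e2
    a_slice = slice(nb, nb + na)
    f_slice = slice(nb + na, ntot)
    history: list[tuple[float, float, float]] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        lam_a = se2 / sa2
        lam_f = se2 / sf2
        M = (WtW + lam_a * pad_a + lam_f * pad_f).tocsc()
        try:
            lu = spla.splu(M)
        except RuntimeError as exc:
            raise ValueError(f"MME coefficient matrix not factorizable: {exc}")
        theta = lu.solve(Wty)
        a_hat = theta[a_slice]
        f_hat = theta[f_slice]

        if trace_mode == "exact":
            Cinv = lu.solve(np.eye(ntot))
            tr_a = float(np.trace(Ainv.toarray() @ Cinv[a_slice, a_slice]))
            tr_f = float(np.trace(Cinv[f_slice, f_slice]))
        else:
            Ua = lu.solve(RHSa)
            Uf = lu.solve(RHSf)
            tr_a = float(np.mean(np.sum(AinvPa * Ua[a_slice], axis=0)))
            tr_f = float(np.mean(np.sum(Pf * Uf[f_slice], axis=0)))

        sa2_new = (float(a_hat @ (Ainv @ a_hat)) + tr_a * se2) / na
        sf2_new = (float(f_hat @ f_hat) + tr_f * se2) / nf
        se2_new = (yty - float(theta @ Wty)) / (nrec - nb)
        sa2_new = max(sa2_new, _VAR_FLOOR)
        if sf2_new <= _VAR_FLOOR:
            logger.info("family variance hit lower bound %.0e", _VAR_FLOOR)
            sf2_new = _VAR_FLOOR
        se2_new = max(se2_new, _VAR_FLOOR)
        history.append((sa2_new, sf2_new, se2_new))

        rel = max(
            abs(sa2_new - sa2) / max(sa2, _VAR_FLOOR),
            abs(sf2_new - sf2) / max(sf2, _VAR_FLOOR),
            abs(se2_new - se2) / max(se2, _VAR_FLOOR),
        )
        sa2, sf2, se2 = sa2_new, sf2_new, se2_new
        if rel < tol:
            converged = True
            break

    h2 = sa2 / (sa2 + sf2 + se2)
    if not converged:
        logger.warning("EM-REML reached max_iter=%d without convergence", max_iter)
    return VarianceEstimates(
        sigma_a2=sa2,
        sigma_f2=sf2,
        sigma_e2=se2,
        h2=h2,
        n_iter=n_iter,
        converged=converged,
        trace_mode=trace_mode,
        history=history,
    )
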