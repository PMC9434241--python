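"""LR-method cross-validation of breeding value predictions.

Phenotypes of a focal group (all phenotyped progeny of a chosen parent set)
are deleted to form a partial dataset; the same model is refit and the focal
group's whole- vs partial-data solutions are compared:

- accuracy  ``ACC  = sqrt( cov(aw, ap) / ((1 - Fbar) sigma_a2) )``
- stability ``STAB = corr(aw, ap)`` (the "ratio of accuracies")
- dispersion ``DISP = cov(aw, ap) / var(ap)`` (1 = none; <1 over-dispersed)
- bias      ``BIAS = mean(ap) - mean(aw)`` (0 = none)

``Fbar`` is the focal group's mean inbreeding from the group-free H matrix
and ``sigma_a2`` the additive variance used in the fit. Covariances use the
unbiased (n-1) divisor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelSpec, Solutions, fit
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)


@dataclass
class LRResult:
    variant: str
    focal_ids: list[str]
    acc: float
    acc_raw_ratio: float
    stab: float
    disp: float
    bias: float
    bias_genetic_sd: float
    f_bar: float
    sigma_a2_used: float

    def as_row(self) -> dict:
        return {
            "variant": self.variant,
            "n_focal": len(self.focal_ids),
            "acc": self.acc,
            "stab": self.stab,
            "disp": self.disp,
            "bias": self.bias,
            "bias_sd_a": self.bias_genetic_sd,
            "f_bar": self.f_bar,
        }


def select_focal_parents(
    pedigree, n: int, seed: int = 0
) -> list[str]:
    """Seeded focal-parent sample stratified by base-population origin.

    Origin is each parent's dominant metafounder contribution (its largest
    entry in the group-contribution matrix), so the focal group represents a
    diversity of origins. Falls back to a plain random sample when the
    pedigree carries no group labels.
    """
    from .pedigree import upg_design

    rng = np.random.default_rng(seed)
    parents = sorted({p for p in pedigree.sires + pedigree.dams if p is not None})
    if n >= len(parents):
        return parents
    if not pedigree.metafounder_labels:
        return sorted(rng.choice(parents, size=n, replace=False))
    origin = upg_design(pedigree).loc[parents].idxmax(axis=1)
    chosen: list[str] = []
    strata = sorted(origin.unique())
    by_stratum = {g: list(origin.index[origin == g]) for g in strata}
    for g in by_stratum:
        by_stratum[g] = list(rng.permutation(by_stratum[g]))
    i = 0
    while len(chosen) < n:
        g = strata[i % len(strata)]
        if by_stratum[g]:
            chosen.append(by_stratum[g].pop())
        i += 1
        if all(not v for v in by_stratum.values()):
            break
    return sorted(chosen)


def make_partial(
    phenotypes: pd.DataFrame,
    focal_parents: list[str],
    pedigree,
) -> tuple[pd.DataFrame, list[str]]:
    """Delete all phenotyped progeny of any focal parent.

    Returns the partial phenotype table and the focal group (the removed
    individuals, each counted once). Focal parents with no progeny only
    trigger a warning.
    """
    focal_parents = [str(p) for p in focal_parents]
    parent_set = set(focal_parents)
    progeny = {
        pedigree.ids[i]
        for i in range(pedigree.n)
        if (pedigree.sires[i] in parent_set or pedigree.dams[i] in parent_set)
    }
    childless = parent_set - {
        p for i in range(pedigree.n) for p in (pedigree.sires[i], pedigree.dams[i])
    }
    if childless:
        logger.warning(
            "focal parents with no pedigree progeny: %s", sorted(childless)
        )
    ph = phenotypes.copy()
    ph["id"] = ph["id"].astype(str)
    mask = ph["id"].isin(progeny)
    focal_ids = sorted(ph.loc[mask, "id"].unique())
    if not focal_ids:
        raise ValueError("focal group is empty: no phenotyped progeny removed")
    return ph.loc[~mask].reset_index(drop=True), focal_ids


def lr_statistics(
    whole: Solutions,
    partial: Solutions,
    focal_ids: list[str],
    f_bar: float,
    sigma_a2: float,
    variant: str = "",
) -> LRResult:
    """LR statistics over the focal group (see module docstring)."""
    if sigma_a2 <= 0:
        raise ValueError("sigma_a2 must be > 0")
    if f_bar >= 1:
        raise ValueError("f_bar must be < 1")
    aw = whole.additive.reindex(focal_ids)
    ap = partial.additive.reindex(focal_ids)
    if aw.isna().any() or ap.isna().any():
        missing = aw.index[aw.isna() | ap.isna()][:10].tolist()
        raise ValueError(f"focal ids missing from solutions, e.g. {missing}")
    aw = aw.to_numpy()
    ap = ap.to_numpy()
    n = len(aw)
    if n < 2:
        raise ValueError("focal group must have at least 2 individuals")
    C = np.cov(aw, ap, ddof=1)  # one computation so whole=partial is exact
    cov_wp = float(C[0, 1])
    var_w = float(C[0, 0])
    var_p = float(C[1, 1])
    raw_ratio = cov_wp / ((1.0 - f_bar) * sigma_a2)
    if cov_wp < 0:
        logger.warning(
            "negative cov(aw, ap)=%g; ACC undefined (raw ratio %g)",
            cov_wp, raw_ratio,
        )
        acc = np.nan
    else:
        acc = float(np.sqrt(raw_ratio))
    if var_p == 0:
        raise ValueError("var(ap) = 0: dispersion undefined")
    stab = cov_wp / np.sqrt(var_w * var_p) if var_w > 0 else np.nan
    disp = cov_wp / var_p
    bias = float(np.mean(ap) - np.mean(aw))
    return LRResult(
        variant=variant,
        focal_ids=list(focal_ids),
        acc=acc,
        acc_raw_ratio=raw_ratio,
        stab=float(stab),
        disp=float(disp),
        bias=bias,
        bias_genetic_sd=bias / float(np.sqrt(sigma_a2)),
        f_bar=f_bar,
        sigma_a2_used=sigma_a2,
    )


def run_lr_suite(
    phenotypes: pd.DataFrame,
    pedigree,
    variants: list[tuple[ModelSpec, RelationshipMatrix, dict]],
    focal_parents: list[str],
    f_bar: float,
) -> pd.DataFrame:
    """One LR validation row per model variant, sharing one focal group.

    ``variants`` holds ``(spec, k_inv, extras)`` triples, where ``extras``
    may carry ``gamma`` and ``q`` for metafounder / UPG variants. ``f_bar``
    is the focal group's mean inbreeding from the group-free H matrix, used
    for every variant of the population set.
    """
    if not variants:
        raise ValueError("no model variants supplied")
    partial_ph, focal_ids = make_partial(phenotypes, focal_parents, pedigree)
    rows = []
    for spec, k_inv, extras in variants:
        gamma = extras.get("gamma")
        q = extras.get("q")
        whole = fit(phenotypes, spec, k_inv, gamma=gamma, q=q)
        part = fit(partial_ph, spec, k_inv, gamma=gamma, q=q)
        res = lr_statistics(
            whole, part, focal_ids, f_bar, spec.sigma_a2, variant=spec.variant
        )
        rows.append(res.as_row())
    return pd.DataFrame(rows)
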