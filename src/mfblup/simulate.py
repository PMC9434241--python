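"""Synthetic structured tree-breeding populations with full truth records.

The generator emulates the statistical structure the analysis assumes:

* ``K`` divergent base populations (races/landraces/plus-tree groups) whose
  allele frequencies drift from a common ancestor along a random bifurcating
  tree (Balding-Nichols steps), so the true Gamma has nested structure;
* a multi-generation pedigree over two breeding programs with occasional
  cross-program matings, genotypes propagated by Mendelian gene dropping;
* a genotyped subset (founders, parents, and a fraction of progeny);
* multi-site phenotypes built as additive + full-sib-family + residual
  effects, standardized per site.

True breeding values come from marker effects on 0.5-centered gene content,
so base-population means diverge with allele frequencies and genomic models
have a genuine information advantage over pedigree-only models. Marker
effects are rescaled so the realized additive variance equals the nominal
``sigma_a2`` (the convention of standard breeding-program simulators).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gamma import GammaMatrix
from .genomic import GenotypeMatrix
from .pedigree import Pedigree, sort_and_validate

DESK_PRESET = dict(
    K=6,
    m=2000,
    fst=0.05,
    tree_depth=3,
    founders_per_pop=12,
    n_generations=3,
    families_per_gen=40,
    progeny_per_family=25,
    programs=2,
    cross_program_prob=0.05,
    genotyped_fraction=0.3,
    n_sites=4,
    variance_components=(0.17, 0.04, 0.80),
)

LARGE_PRESET = dict(DESK_PRESET, founders_per_pop=20, families_per_gen=80)

#: small configuration for fast unit tests
MINI_PRESET = dict(
    K=3,
    m=400,
    fst=0.08,
    tree_depth=2,
    founders_per_pop=8,
    n_generations=2,
    families_per_gen=12,
    progeny_per_family=8,
    programs=2,
    cross_program_prob=0.05,
    genotyped_fraction=0.5,
    n_sites=2,
    variance_components=(0.17, 0.04, 0.80),
)

PRESETS = {"desk": DESK_PRESET, "large": LARGE_PRESET, "mini": MINI_PRESET}


@dataclass
class BasePopulations:
    labels: list[str]
    freqs: np.ndarray                   # K x m true base frequencies
    marker_ids: list[str]
    divergence_level: np.ndarray        # K x K split depth (larger = sisters)
    true_gamma: GammaMatrix
    founder_ids: list[str]
    founder_pop: pd.Series              # founder id -> population label
    founder_genotypes: GenotypeMatrix


@dataclass
class SimulatedPopulation:
    pedigree: Pedigree
    gene_content: np.ndarray            # all individuals x markers
    marker_ids: list[str]
    program: pd.Series                  # individual -> program index
    generation: pd.Series               # individual -> generation (0=founder)
    genotyped_ids: list[str]
    base: BasePopulations

    @property
    def genotypes(self) -> GenotypeMatrix:
        """Gene contents of the genotyped subset."""
        index = {v: i for i, v in enumerate(self.pedigree.ids)}
        rows = [index[i] for i in self.genotyped_ids]
        return GenotypeMatrix(
            list(self.genotyped_ids), list(self.marker_ids),
            self.gene_content[rows],
        )


@dataclass
class SimulationTruth:
    true_base_frequencies: np.ndarray
    true_gamma: GammaMatrix
    tbv: pd.Series
    variance_components: tuple[float, float, float]
    seed: int


@dataclass
class SimulatedDataset:
    population: SimulatedPopulation
    phenotypes: pd.DataFrame
    truth: SimulationTruth
    params: dict = field(default_factory=dict)

    @property
    def pedigree(self) -> Pedigree:
        return self.population.pedigree

    @property
    def genotypes(self) -> GenotypeMatrix:
        return self.population.genotypes


# ----------------------------------------------------------------------
def _bn_drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)


def simulate_base_populations(
    K: int,
    m: int,
    fst: float | list[float] = 0.05,
    tree_depth: int = 3,
    founders_per_pop: int = 12,
    seed: int = 0,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
    star: bool = False,
) -> BasePopulations:
    """Divergent base populations with founder genotypes.

    Ancestral frequencies are uniform on ``ancestral_range``; population
    frequencies drift along a random bifurcating tree (or a star phylogeny
    when ``star``), one Balding-Nichols step per tree level with per-level
    ``F`` from ``fst`` (scalar = same at each level). Founder genotypes are
    Binomial(2, p). ``true_gamma`` is 8x the second moment of the base
    frequencies about 0.5.
    """
    if K < 2:
        raise ValueError("need at least 2 base populations")
    if m < 100:
        raise ValueError("need at least 100 markers")
    fst_vec = [fst] * tree_depth if np.isscalar(fst) else list(fst)
    if any(not (0.0 < f < 0.5) for f in fst_vec):
        raise ValueError("fst values must be in (0, 0.5)")
    if len(fst_vec) < tree_depth:
        fst_vec = (fst_vec * tree_depth)[:tree_depth]
    rng = np.random.default_rng(seed)
    lo, hi = ancestral_range
    p0 = rng.uniform(lo, hi, size=m)

    labels = [f"MF{k + 1}" for k in range(K)]
    freqs = np.zeros((K, m))
    div_level = np.zeros((K, K))

    def fst_at(level: int) -> float:
        return fst_vec[min(level, len(fst_vec) - 1)]

    if star:
        for k in range(K):
            p = p0
            for level in range(tree_depth):
                p = _bn_drift(p, fst_at(level), rng)
            freqs[k] = p
    else:
        def build(pops: list[int], p: np.ndarray, level: int) -> None:
            if len(pops) == 1:
                k = pops[0]
                while level < tree_depth:
                    p = _bn_drift(p, fst_at(level), rng)
                    level += 1
                freqs[k] = p
                return
            for a in pops:
                for b in pops:
                    if a != b:
                        div_level[a, b] = max(div_level[a, b], level)
            cut = int(rng.integers(1, len(pops)))
            perm = list(rng.permutation(pops))
            left, right = perm[:cut], perm[cut:]
            for side in (left, right):
                build(side, _bn_drift(p, fst_at(min(level, tree_depth - 1)), rng),
                      level + 1)

        build(list(range(K)), p0, 0)

    d = freqs - 0.5
    true_gamma = GammaMatrix(labels, 8.0 * (d @ d.T) / m, {"true": True})

    marker_ids = [f"m{j + 1}" for j in range(m)]
    founder_ids: list[str] = []
    founder_pop: list[str] = []
    geno = np.zeros((K * founders_per_pop, m))
    for k in range(K):
        block = rng.binomial(2, freqs[k], size=(founders_per_pop, m)).astype(float)
        geno[k * founders_per_pop : (k + 1) * founders_per_pop] = block
        for t in range(founders_per_pop):
            founder_ids.append(f"F{k + 1}_{t + 1}")
            founder_pop.append(labels[k])
    return BasePopulations(
        labels=labels,
        freqs=freqs,
        marker_ids=marker_ids,
        divergence_level=div_level,
        true_gamma=true_gamma,
        founder_ids=founder_ids,
        founder_pop=pd.Series(founder_pop, index=founder_ids, name="population"),
        founder_genotypes=GenotypeMatrix(founder_ids, marker_ids, geno),
    )


# ----------------------------------------------------------------------
def simulate_pedigree_and_genedrop(
    base: BasePopulations,
    n_generations: int = 3,
    families_per_gen: int = 40,
    progeny_per_family: int = 25,
    programs: int = 2,
    cross_program_prob: float = 0.05,
    genotyped_fraction: float = 0.3,
    seed: int = 0,
) -> SimulatedPopulation:
    """Multi-generation pedigree over breeding programs, with gene dropping.

    Each generation mates random parent pairs drawn within a program (with
    probability ``cross_program_prob`` the dam comes from the other
    program); progeny alleles are sampled from each parent's gene content.
    Founders are assigned to programs with population-dependent odds, so
    programs have distinct but overlapping base-population profiles.
    The genotyped subset is: every founder, every parent, plus a random
    ``genotyped_fraction`` of the remaining progeny.
    """
    rng = np.random.default_rng(seed)
    K = len(base.labels)
    founders = list(base.founder_ids)
    nF = len(founders)
    if nF < 2 * programs:
        raise ValueError("insufficient founders for the requested programs")

    pop_of = base.founder_pop
    # population-dependent program assignment (overlapping profiles)
    prog_assign = {}
    for fid in founders:
        k = base.labels.index(pop_of[fid])
        p0 = 0.9 if k < K / 2 else 0.1
        prog_assign[fid] = 0 if rng.random() < p0 else 1
    for pr in range(programs):
        if sum(1 for f in founders if prog_assign[f] == pr) < 2:
            # guarantee a usable pool in degenerate draws
            for fid in rng.choice(founders, size=2, replace=False):
                prog_assign[fid] = pr

    ids = list(founders)
    sires: list[str | None] = [None] * nF
    dams: list[str | None] = [None] * nF
    sgrp: list[str | None] = [pop_of[f] for f in founders]
    dgrp: list[str | None] = [pop_of[f] for f in founders]
    program = {f: prog_assign[f] for f in founders}
    generation = {f: 0 for f in founders}

    content = [base.founder_genotypes.gene_content]
    row_of = {f: i for i, f in enumerate(founders)}
    m = len(base.marker_ids)

    fam_per_prog = max(1, families_per_gen // programs)
    counter = 0
    pools = {
        pr: [f for f in founders if program[f] == pr] for pr in range(programs)
    }
    for gen in range(1, n_generations + 1):
        new_pools: dict[int, list[str]] = {pr: [] for pr in range(programs)}
        gen_rows: list[np.ndarray] = []
        for pr in range(programs):
            pool = pools[pr]
            other = pools[1 - pr] if programs == 2 else pool
            if len(pool) < 2:
                raise ValueError(f"insufficient parents in program {pr}")
            for _ in range(fam_per_prog):
                sire, dam = (str(x) for x in rng.choice(pool, 2, replace=False))
                if programs == 2 and other and rng.random() < cross_program_prob:
                    dam = str(rng.choice(other))
                ms = content_lookup(content, row_of, sire)
                md = content_lookup(content, row_of, dam)
                kids = (
                    rng.binomial(1, np.tile(ms / 2.0, (progeny_per_family, 1)))
                    + rng.binomial(1, np.tile(md / 2.0, (progeny_per_family, 1)))
                ).astype(float)
                for t in range(progeny_per_family):
                    counter += 1
                    cid = f"I{counter:05d}"
                    ids.append(cid)
                    sires.append(sire)
                    dams.append(dam)
                    sgrp.append(None)
                    dgrp.append(None)
                    program[cid] = pr
                    generation[cid] = gen
                    row_of[cid] = sum(c.shape[0] for c in content) + len(gen_rows)
                    gen_rows.append(kids[t])
                    new_pools[pr].append(cid)
        content.append(np.vstack(gen_rows))
        pools = new_pools

    gene_content = np.vstack(content)
    pedigree = Pedigree(ids, sires, dams, sgrp, dgrp)
    pedigree = sort_and_validate(pedigree)
    # gene content in sorted order
    order = [row_of[i] for i in pedigree.ids]
    gene_content = gene_content[order]

    parent_ids = {p for p in (pedigree.sires + pedigree.dams) if p is not None}
    genotyped = set(founders) | parent_ids
    rest = [i for i in pedigree.ids if i not in genotyped]
    n_extra = int(round(genotyped_fraction * len(rest)))
    if n_extra:
        genotyped |= set(rng.choice(rest, size=n_extra, replace=False))
    genotyped_ids = [i for i in pedigree.ids if i in genotyped]

    return SimulatedPopulation(
        pedigree=pedigree,
        gene_content=gene_content,
        marker_ids=list(base.marker_ids),
        program=pd.Series({i: program[i] for i in pedigree.ids}, name="program"),
        generation=pd.Series(
            {i: generation[i] for i in pedigree.ids}, name="generation"
        ),
        genotyped_ids=genotyped_ids,
        base=base,
    )


def content_lookup(blocks: list[np.ndarray], row_of: dict, ind: str) -> np.ndarray:
    """Row of an individual's gene content across stacked generation blocks."""
    r = row_of[ind]
    for b in blocks:
        if r < b.shape[0]:
            return b[r]
        r -= b.shape[0]
    raise KeyError(ind)


# ----------------------------------------------------------------------
def simulate_phenotypes(
    population: SimulatedPopulation,
    n_sites: int = 4,
    variance_components: tuple[float, float, float] = (0.17, 0.04, 0.80),
    seed: int = 0,
    standardize: bool = True,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Multi-site phenotypes: additive + full-sib family + residual.

    TBV is built from normal marker effects on 0.5-centered gene content and
    rescaled so the realized TBV variance equals ``sigma_a2`` exactly.
    All non-founder individuals are phenotyped, assigned to sites at random;
    each site column is standardized to mean 0, SD 1 (n-1 divisor).
    """
    if n_sites < 1:
        raise ValueError("site count must be >= 1")
    sa2, sf2, se2 = variance_components
    if min(variance_components) <= 0:
        raise ValueError("variance components must be positive")
    rng = np.random.default_rng(seed)
    ped = population.pedigree
    m = len(population.marker_ids)
    alpha = rng.normal(0.0, np.sqrt(sa2 / (m / 2.0)), size=m)
    Z = population.gene_content - 1.0
    tbv = Z @ alpha
    sd_real = float(np.std(tbv, ddof=1))
    tbv *= np.sqrt(sa2) / sd_real

    tbv_s = pd.Series(tbv, index=ped.ids, name="tbv")
    progeny = [
        i for t, i in enumerate(ped.ids)
        if ped.sires[t] is not None or ped.dams[t] is not None
    ]
    fam_label = {}
    for t, i in enumerate(ped.ids):
        if ped.sires[t] is not None or ped.dams[t] is not None:
            fam_label[i] = f"{ped.sires[t]}x{ped.dams[t]}"
    families = sorted(set(fam_label.values()))
    fam_eff = dict(zip(families, rng.normal(0.0, np.sqrt(sf2), size=len(families))))

    sites = [f"S{j + 1}" for j in range(n_sites)]
    site_assign = rng.choice(sites, size=len(progeny))
    values = (
        tbv_s[progeny].to_numpy()
        + np.array([fam_eff[fam_label[i]] for i in progeny])
        + rng.normal(0.0, np.sqrt(se2), size=len(progeny))
    )
    ph = pd.DataFrame(
        {
            "id": progeny,
            "site": site_assign,
            "family": [fam_label[i] for i in progeny],
            "value": values,
        }
    )
    if standardize:
        from .io import standardize_by_trial

        ph = standardize_by_trial(ph)
    truth = SimulationTruth(
        true_base_frequencies=population.base.freqs,
        true_gamma=population.base.true_gamma,
        tbv=tbv_s,
        variance_components=(sa2, sf2, se2),
        seed=seed,
    )
    return ph, truth


# ----------------------------------------------------------------------
def simulate_dataset(
    preset: str = "desk", seed: int = 0, **overrides
) -> SimulatedDataset:
    """Generate a complete dataset (pedigree, genotypes, phenotypes, truth)."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[preset])
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
    params.update(overrides)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=3)
    base = simulate_base_populations(
        K=params["K"],
        m=params["m"],
        fst=params["fst"],
        tree_depth=params["tree_depth"],
        founders_per_pop=params["founders_per_pop"],
        seed=int(seeds[0]),
    )
    population = simulate_pedigree_and_genedrop(
        base,
        n_generations=params["n_generations"],
        families_per_gen=params["families_per_gen"],
        progeny_per_family=params["progeny_per_family"],
        programs=params["programs"],
        cross_program_prob=params["cross_program_prob"],
        genotyped_fraction=params["genotyped_fraction"],
        seed=int(seeds[1]),
    )
    phenotypes, truth = simulate_phenotypes(
        population,
        n_sites=params["n_sites"],
        variance_components=tuple(params["variance_components"]),
        seed=int(seeds[2]),
    )
    return SimulatedDataset(
        population=population, phenotypes=phenotypes, truth=truth, params=params
    )
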