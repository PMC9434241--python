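"""Delimited-text readers/writers, per-trial standardization, config, manifest.

All numeric output uses 17-significant-digit decimal so write/read round
trips are byte-stable. Delimiter auto-detection is limited to comma, tab and
whitespace; an ambiguous first line is an error, never a guess.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gamma import GammaMatrix
from .genomic import GenotypeMatrix
from .pedigree import Pedigree
from .relmat import RelationshipMatrix

_FMT = "%.17g"


class ParseError(ValueError):
    pass


def _fmt(x: float) -> str:
    return _FMT % x


def detect_delimiter(first_line: str) -> str:
    has_comma = "," in first_line
    has_tab = "\t" in first_line
    if has_comma and has_tab:
        raise ParseError("ambiguous delimiter: line contains both comma and tab")
    if has_comma:
        return ","
    if has_tab:
        return "\t"
    return r"\s+"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ParseError(f"{path}: empty file")
    sep = detect_delimiter(first)
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


# ----------------------------------------------------------------------
# pedigree
# ----------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    """Read `id,sire,dam[,sire_group,dam_group]`; missing parent = 0 or empty."""
    df = _read_table(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for need in ("id", "sire", "dam"):
        if need not in cols:
            raise ParseError(f"{path}: pedigree file missing column {need!r}")
    def grp(col: str) -> list:
        if col in cols:
            return [g if g not in ("", "0", "NA") else None for g in df[col]]
        return []
    return Pedigree(
        ids=list(df["id"]),
        sires=list(df["sire"]),
        dams=list(df["dam"]),
        sire_groups=grp("sire_group"),
        dam_groups=grp("dam_group"),
    )


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    has_groups = any(
        g is not None for g in pedigree.sire_groups + pedigree.dam_groups
    )
    with open(path, "w") as fh:
        header = "id,sire,dam" + (",sire_group,dam_group" if has_groups else "")
        fh.write(header + "\n")
        for i in range(pedigree.n):
            row = [
                pedigree.ids[i],
                pedigree.sires[i] or "0",
                pedigree.dams[i] or "0",
            ]
            if has_groups:
                row += [pedigree.sire_groups[i] or "", pedigree.dam_groups[i] or ""]
            fh.write(",".join(row) + "\n")


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

_MISSING_GENO = {"NA", "na", "5", "."}


def read_genotypes(path: str | Path, marker_file: str | Path | None = None) -> GenotypeMatrix:
    """One row per individual: `id` then gene-content codes (0/1/2; NA/5 missing).

    A header starting with `id` supplies marker names; otherwise markers are
    numbered (or read from ``marker_file``, one marker id per line).
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    sep = detect_delimiter(lines[0])
    import re

    def split(ln: str) -> list[str]:
        return re.split(sep, ln.strip()) if sep == r"\s+" else ln.split(sep)

    first = split(lines[0])
    marker_ids: list[str] | None = None
    start = 0
    if first and first[0].lower() == "id":
        marker_ids = first[1:]
        start = 1
    rows = []
    ids = []
    for lineno, ln in enumerate(lines[start:], start=start + 1):
        parts = split(ln)
        ids.append(parts[0])
        row = []
        for col, tok in enumerate(parts[1:], start=2):
            if tok in _MISSING_GENO:
                row.append(np.nan)
            elif tok in ("0", "1", "2"):
                row.append(float(tok))
            else:
                raise ParseError(
                    f"{path}: invalid gene content {tok!r} at line {lineno}, "
                    f"column {col}"
                )
        rows.append(row)
    m = len(rows[0])
    if any(len(r) != m for r in rows):
        bad = next(i for i, r in enumerate(rows) if len(r) != m)
        raise ParseError(f"{path}: ragged genotype row at line {bad + start + 1}")
    if marker_file is not None:
        marker_ids = [
            ln.strip() for ln in open(marker_file) if ln.strip()
        ]
    if marker_ids is None:
        marker_ids = [f"m{j + 1}" for j in range(m)]
    if len(marker_ids) != m:
        raise ParseError(f"{path}: {len(marker_ids)} marker ids for {m} columns")
    return GenotypeMatrix(ids, marker_ids, np.array(rows))


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id," + ",".join(genotypes.marker_ids) + "\n")
        for i, ind in enumerate(genotypes.individual_ids):
            row = genotypes.gene_content[i]
            toks = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(ind + "," + ",".join(toks) + "\n")


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"id", "site", "family", "value"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: phenotype file missing columns {sorted(missing)}")
    try:
        df["value"] = df["value"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric phenotype value ({exc})") from None
    return df[["id", "site", "family", "value"]]


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id,site,family,value\n")
        for r in phenotypes.itertuples(index=False):
            fh.write(f"{r.id},{r.site},{r.family},{_fmt(r.value)}\n")


def standardize_by_trial(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Standardize `value` to mean 0, SD 1 (n-1 divisor) within each site."""
    ph = phenotypes.copy()
    out = []
    for site, grp in ph.groupby("site", sort=False):
        if len(grp) < 2:
            raise ValueError(f"site {site!r} has fewer than 2 records")
        sd = grp["value"].std(ddof=1)
        if sd == 0:
            raise ValueError(f"site {site!r} has constant phenotype values")
        g = grp.copy()
        g["value"] = (grp["value"] - grp["value"].mean()) / sd
        out.append(g)
    return pd.concat(out).loc[ph.index]


# ----------------------------------------------------------------------
# matrices
# ----------------------------------------------------------------------

def write_matrix(
    mat: RelationshipMatrix, path: str | Path, fmt: str = "long"
) -> None:
    """Write a relationship matrix: `long` lower triangle or `dense` CSV."""
    if fmt == "long":
        dense = mat.to_dense()
        with open(path, "w") as fh:
            fh.write("id_i,id_j,value\n")
            for i in range(mat.n):
                for j in range(i + 1):
                    v = dense[i, j]
                    if v != 0.0:
                        fh.write(
                            f"{mat.entity_ids[i]},{mat.entity_ids[j]},{_fmt(v)}\n"
                        )
    elif fmt == "dense":
        dense = mat.to_dense()
        with open(path, "w") as fh:
            fh.write("id," + ",".join(mat.entity_ids) + "\n")
            for i, e in enumerate(mat.entity_ids):
                fh.write(e + "," + ",".join(_fmt(v) for v in dense[i]) + "\n")
    else:
        raise ValueError(f"unknown matrix format {fmt!r}")


def read_matrix(path: str | Path, kind: str) -> RelationshipMatrix:
    """Read a matrix written by :func:`write_matrix` (format auto-detected)."""
    with open(path) as fh:
        header = fh.readline().strip()
    if header.startswith("id_i"):
        df = pd.read_csv(path, dtype={"id_i": str, "id_j": str})
        ids = list(dict.fromkeys(pd.concat([df["id_i"], df["id_j"]])))
        index = {e: i for i, e in enumerate(ids)}
        n = len(ids)
        M = np.zeros((n, n))
        for r in df.itertuples(index=False):
            i, j = index[r.id_i], index[r.id_j]
            M[i, j] = M[j, i] = r.value
        return RelationshipMatrix(ids, M, kind)
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(
        [str(c) for c in df.columns], df.to_numpy(dtype=float), kind
    )


def write_gamma(gamma: GammaMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mf," + ",".join(gamma.labels) + "\n")
        for i, g in enumerate(gamma.labels):
            fh.write(g + "," + ",".join(_fmt(v) for v in gamma.values[i]) + "\n")


def read_gamma(path: str | Path) -> GammaMatrix:
    df = pd.read_csv(path, index_col=0)
    return GammaMatrix([str(c) for c in df.columns], df.to_numpy(dtype=float))


def write_newick(newick: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip("\n") + "\n")


# ----------------------------------------------------------------------
# config / manifest
# ----------------------------------------------------------------------

CONFIG_SCHEMA: dict[str, object] = {
    "variant": "HBLUP",
    "sigma_a2": 0.17,
    "sigma_f2": 0.04,
    "sigma_e2": 0.80,
    "apply_k": True,
    "residual_mode": "homogeneous",
    "blend_weight": 0.95,
    "gamma_center": "half",
    "psd_repair": False,
    "solver": "direct",
    "conflict_threshold": 0.02,
}


def read_config(path: str | Path) -> dict:
    """YAML config validated against the known-key schema (defaults filled)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a key-value mapping")
    unknown = set(raw) - set(CONFIG_SCHEMA)
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = dict(CONFIG_SCHEMA)
    cfg.update(raw)
    return cfg


def cross_reference(ids_a: list[str], ids_b: list[str], what: str) -> None:
    """Error if any id in ``ids_a`` is absent from ``ids_b`` (first 10 listed)."""
    missing = sorted(set(map(str, ids_a)) - set(map(str, ids_b)))
    if missing:
        raise ValueError(
            f"{len(missing)} ids in {what} are unknown, e.g. {missing[:10]}"
        )


def write_manifest(path: str | Path, inputs: dict, config: dict | None = None) -> None:
    """Machine-readable run manifest: inputs, config hash, versions."""
    import mfblup

    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "inputs": {k: str(v) for k, v in inputs.items()},
        "config": config or {},
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "versions": {
            "mfblup": mfblup.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
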