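"""Readers and writers for the pipeline's on-disk formats.

Count matrices travel as a Matrix-Market triplet bundle — ``matrix.mtx``
(genes x cells, CellRanger orientation), ``features.tsv`` and
``barcodes.tsv``, optionally gzipped — or as a dense genes-x-cells CSV.
Mitochondrial genes are flagged either by an explicit 0/1 ``is_mito``
column in the features file or, failing that, by a case-insensitive gene-id
prefix (default ``mt-``). Gene sets use the standard GMT layout (name,
description, then tab-separated genes). Output tables are TSV with a
``#``-prefixed provenance header.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .enrichment import GeneSetCollection
from .errors import FormatError, InputError

log = logging.getLogger(__name__)

MITO_PREFIX = "mt-"


def _find(dirpath: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dirpath / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {dirpath}")


def _read_tsv_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_matrix_bundle(path, mito_prefix: str = MITO_PREFIX) -> ad.AnnData:
    """Read a matrix.mtx + features.tsv + barcodes.tsv bundle into AnnData.

    The mtx stores genes x cells; the returned AnnData is cells x genes
    with ``var['is_mito']`` from the features file's third column when it is
    0/1-valued, otherwise inferred from the gene-id prefix.
    """
    dirpath = Path(path)
    if not dirpath.is_dir():
        raise FormatError(f"{dirpath} is not a directory")
    mtx = _find(dirpath, "matrix.mtx")
    features = _read_tsv_lines(_find(dirpath, "features.tsv"))
    barcodes = _read_tsv_lines(_find(dirpath, "barcodes.tsv"))

    M = spio.mmread(mtx)
    n_genes, n_cells = M.shape
    if len(features) != n_genes:
        raise FormatError(
            f"features.tsv has {len(features)} rows but matrix.mtx declares {n_genes} genes"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"barcodes.tsv has {len(barcodes)} rows but matrix.mtx declares {n_cells} cells"
        )
    gene_ids = [line.split("\t")[0] for line in features]
    flags = [line.split("\t")[2] if len(line.split("\t")) > 2 else None for line in features]
    if all(f in ("0", "1") for f in flags):
        is_mito = np.array([f == "1" for f in flags])
    else:
        is_mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in gene_ids])
    cell_ids = [line.split("\t")[0] for line in barcodes]
    return _build_adata(sparse.csr_matrix(M.T), gene_ids, cell_ids, is_mito)


def read_counts_csv(path, mito_prefix: str = MITO_PREFIX) -> ad.AnnData:
    """Dense CSV fallback: genes as rows (first column gene id), cells as columns."""
    df = pd.read_csv(path, index_col=0)
    gene_ids = [str(g) for g in df.index]
    is_mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in gene_ids])
    return _build_adata(
        sparse.csr_matrix(df.to_numpy().T), gene_ids, [str(c) for c in df.columns], is_mito
    )


def read_counts(path, mito_prefix: str = MITO_PREFIX) -> ad.AnnData:
    """Dispatch on path: a directory is a Matrix-Market bundle, a .csv is dense."""
    p = Path(path)
    if p.is_dir():
        return read_matrix_bundle(p, mito_prefix=mito_prefix)
    if p.suffix == ".csv":
        return read_counts_csv(p, mito_prefix=mito_prefix)
    raise FormatError(f"cannot infer count format of {p}: expected a bundle directory or .csv")


def _build_adata(X, gene_ids, cell_ids, is_mito) -> ad.AnnData:
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError("gene ids are not unique")
    if len(set(cell_ids)) != len(cell_ids):
        raise FormatError("cell ids are not unique")
    if X.min() < 0:
        raise FormatError("count matrix has negative entries")
    var = pd.DataFrame({"is_mito": is_mito}, index=pd.Index(gene_ids, name="gene_id"))
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    return ad.AnnData(X=X, obs=obs, var=var)


def write_matrix_bundle(adata: ad.AnnData, path) -> Path:
    """Write counts as matrix.mtx (genes x cells) + features.tsv + barcodes.tsv."""
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    X = adata.X
    M = (X.T if sparse.issparse(X) else np.asarray(X).T)
    spio.mmwrite(dirpath / "matrix.mtx", sparse.coo_matrix(M), field="integer")
    is_mito = (
        np.asarray(adata.var["is_mito"], dtype=bool)
        if "is_mito" in adata.var.columns
        else np.zeros(adata.n_vars, dtype=bool)
    )
    with open(dirpath / "features.tsv", "w") as fh:
        for g, m in zip(adata.var_names, is_mito):
            fh.write(f"{g}\t{g}\t{int(m)}\n")
    with open(dirpath / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{c}\n" for c in adata.obs_names)
    return dirpath


def read_annotation(path) -> pd.DataFrame:
    """Cell annotation TSV with columns cell_id, group, cluster."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("cell_id", "group", "cluster"):
        if col not in df.columns:
            raise FormatError(f"annotation {path} is missing column {col!r}")
    if df["cell_id"].duplicated().any():
        raise FormatError(f"annotation {path} has duplicate cell ids")
    return df.set_index("cell_id")


def attach_annotation(adata: ad.AnnData, ann: pd.DataFrame) -> ad.AnnData:
    missing = adata.obs_names.difference(ann.index)
    if len(missing):
        raise InputError(f"{len(missing)} cell(s) lack annotation (e.g. {missing[0]})")
    adata = adata.copy()
    adata.obs["group"] = ann.loc[adata.obs_names, "group"].astype(str).values
    adata.obs["cluster"] = ann.loc[adata.obs_names, "cluster"].astype(str).values
    return adata


def read_gmt(path) -> GeneSetCollection:
    """Standard GMT: one set per line — name, description, tab-separated genes.

    Duplicate set names and lines with fewer than three fields are format
    errors; duplicated genes within a line are collapsed with a warning.
    The collection universe is the union of all sets.
    """
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(_read_tsv_lines(Path(path)), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: set {name!r} is empty")
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        if len(set(genes)) != len(genes):
            log.warning("%s:%d: duplicate genes within set %r collapsed", path, lineno, name)
        sets[name] = frozenset(genes)
    universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets=sets, universe=universe)


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\tscrescue\t{genes}\n")
    return path


def provenance_header(config: dict | None = None, seed: int | None = None) -> str:
    cfg_hash = (
        hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
        if config is not None
        else "none"
    )
    return (
        f"# screscue version={__version__}\n"
        f"# config_hash={cfg_hash}\n"
        f"# seed={seed if seed is not None else 'none'}\n"
    )


def write_tsv(df: pd.DataFrame, path, config: dict | None = None, seed: int | None = None,
              index: bool = False) -> Path:
    """TSV writer that prepends the provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(config, seed))
        df.to_csv(fh, sep="\t", index=index)
    return path


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
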