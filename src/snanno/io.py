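"""Reading and writing 10x-style sparse triplet matrices with metadata.

A count matrix is stored as four plain-text files in one directory:

- ``matrix.mtx`` — MatrixMarket triplet, genes x nuclei (10x orientation)
- ``features.tsv`` — one gene name per line
- ``barcodes.tsv`` — one nucleus barcode per line
- ``metadata.tsv`` — sidecar with columns barcode, condition, pct_exonic,
  pct_mito (plus any further per-nucleus columns)

In memory the matrix is an :class:`anndata.AnnData` with obs = nuclei and
var = genes (the transpose of the on-disk orientation), raw integer counts
in ``.X`` and the sidecar columns in ``.obs``.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

METADATA_COLUMNS = ("condition", "pct_exonic", "pct_mito")


class TenxParseError(ValueError):
    """Raised when a triplet matrix file cannot be parsed."""


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _find(path: Path, stem: str) -> Path:
    for cand in (path / stem, path / f"{stem}.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing {stem}(.gz) under {path}")


def write_10x(adata: ad.AnnData, path: str | Path) -> Path:
    """Write counts + metadata sidecar as a 10x-style directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    x = adata.X
    if not sp.issparse(x):
        x = sp.csr_matrix(x)
    mat = sp.coo_matrix(x.T)  # genes x nuclei on disk
    if not np.issubdtype(mat.dtype, np.integer):
        if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
            raise ValueError("write_10x expects integer raw counts")
        mat = mat.astype(np.int64)
    scipy.io.mmwrite(str(path / "matrix.mtx"), mat, field="integer")
    (path / "features.tsv").write_text(
        "".join(f"{g}\n" for g in adata.var_names)
    )
    (path / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in adata.obs_names)
    )
    meta = adata.obs.copy()
    meta.insert(0, "barcode", adata.obs_names)
    meta.to_csv(path / "metadata.tsv", sep="\t", index=False)
    return path


def _validate_triplets(mtx_path: Path) -> None:
    """Locate the offending line of a malformed triplet file."""
    with _open_maybe_gzip(mtx_path) as fh:
        lineno = 0
        header_seen = False
        dims_seen = False
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if lineno == 1:
                if not line.startswith("%%MatrixMarket"):
                    raise TenxParseError(
                        f"{mtx_path}: line {lineno}: missing MatrixMarket header"
                    )
                header_seen = True
                continue
            if not line or line.startswith("%"):
                continue
            tokens = line.split()
            if not dims_seen:
                ok = len(tokens) == 3 and all(t.isdigit() for t in tokens)
                if not ok:
                    raise TenxParseError(
                        f"{mtx_path}: line {lineno}: malformed dimension line {line!r}"
                    )
                dims_seen = True
                continue
            try:
                int(tokens[0]), int(tokens[1]), float(tokens[2])
                if len(tokens) != 3:
                    raise ValueError
            except (ValueError, IndexError):
                raise TenxParseError(
                    f"{mtx_path}: line {lineno}: malformed triplet {line!r}"
                ) from None
    if not header_seen or not dims_seen:
        raise TenxParseError(f"{mtx_path}: truncated matrix file")


def read_10x(path: str | Path) -> ad.AnnData:
    """Read a directory written by :func:`write_10x` back into an AnnData."""
    path = Path(path)
    mtx_path = _find(path, "matrix.mtx")
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception:
        _validate_triplets(mtx_path)  # raises with line number when malformed
        raise
    mat = sp.csr_matrix(mat.T).astype(np.int64)  # nuclei x genes in memory

    with _open_maybe_gzip(_find(path, "features.tsv")) as fh:
        genes = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    with _open_maybe_gzip(_find(path, "barcodes.tsv")) as fh:
        barcodes = [ln.strip().split("\t")[0] for ln in fh if ln.strip()]
    if mat.shape != (len(barcodes), len(genes)):
        raise TenxParseError(
            f"{path}: matrix is {mat.shape[::-1]} (genes x nuclei) but found "
            f"{len(genes)} features and {len(barcodes)} barcodes"
        )

    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    meta_path = path / "metadata.tsv"
    if meta_path.exists() or (path / "metadata.tsv.gz").exists():
        meta = pd.read_csv(_find(path, "metadata.tsv"), sep="\t")
        if len(meta) != adata.n_obs and not (adata.n_obs == 0 and meta.empty):
            raise TenxParseError(
                f"{meta_path}: {len(meta)} metadata rows for {adata.n_obs} barcodes"
            )
        if adata.n_obs:
            meta = meta.set_index("barcode").loc[adata.obs_names]
            for col in meta.columns:
                adata.obs[col] = meta[col].values
        else:
            for col in meta.columns:
                if col != "barcode":
                    adata.obs[col] = pd.Series(dtype=meta[col].dtype)
    return adata


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    with _open_maybe_gzip(Path(path)) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need name, description, genes"
                )
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")
    return path
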