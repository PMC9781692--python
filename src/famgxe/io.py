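"""Readers and writers for the pipeline's plain-text formats.

Count matrices travel either as TSV (gene IDs in the first column, one
column per sample, tab separated, no quoting) or as MatrixMarket
coordinate files with ``<stem>.genes.tsv`` / ``<stem>.samples.tsv``
sidecars holding the row and column IDs.  Metadata, phenotype and result
tables are TSV.  Floats in result tables are rendered at 6 significant
digits and missing values as ``NA``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import CountMatrix, FormatError, validate_metadata

__all__ = [
    "read_counts",
    "write_counts",
    "read_metadata",
    "read_traces",
    "write_results",
    "read_phenotypes",
    "write_phenotypes",
]


def _sidecar_paths(path: str) -> tuple[str, str]:
    stem = path[:-4] if str(path).endswith(".mtx") else str(path)
    return f"{stem}.genes.tsv", f"{stem}.samples.tsv"


def read_counts(path, format: str | None = None, meta: pd.DataFrame | None = None) -> CountMatrix:
    """Read a genes x samples count matrix.

    ``format`` is ``"tsv"`` or ``"mtx"``; when omitted it is inferred from
    the file extension.  MatrixMarket input is a coordinate triplet file
    (zero cells implicit) with gene/sample ID sidecars next to it.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, header=0)
        except pd.errors.EmptyDataError:
            raise FormatError(f"no genes parsed from {path}") from None
        if df.shape[0] == 0:
            raise FormatError(f"no genes parsed from {path}")
        gene_ids = [str(g) for g in df.index]
        sample_ids = [str(s) for s in df.columns]
        values = df.to_numpy()
        if values.dtype == object or not np.issubdtype(values.dtype, np.number):
            bad = df.columns[
                [not np.issubdtype(df[c].dtype, np.number) for c in df.columns]
            ]
            raise FormatError(
                f"non-numeric counts in sample column(s) {list(bad)[:5]} of {path}"
            )
        counts = values
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes_path, samples_path = _sidecar_paths(path)
        for p in (genes_path, samples_path):
            if not os.path.exists(p):
                raise FormatError(f"missing MatrixMarket ID sidecar {p}")
        gene_ids = [line.strip() for line in open(genes_path) if line.strip()]
        sample_ids = [line.strip() for line in open(samples_path) if line.strip()]
        if not gene_ids:
            raise FormatError(f"no genes parsed from {genes_path}")
        counts = np.asarray(mat)
    else:
        raise FormatError(f"unknown count-matrix format {format!r}")
    return CountMatrix(gene_ids, sample_ids, counts,
                       meta if meta is not None else pd.DataFrame())


def write_counts(cm: CountMatrix, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "mtx" if path.endswith(".mtx") else "tsv"
    if format == "tsv":
        cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts))
        genes_path, samples_path = _sidecar_paths(path)
        with open(genes_path, "w") as fh:
            fh.write("\n".join(cm.gene_ids) + "\n")
        with open(samples_path, "w") as fh:
            fh.write("\n".join(cm.sample_ids) + "\n")
    else:
        raise FormatError(f"unknown count-matrix format {format!r}")


def read_metadata(path, allowed_exposures=None) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV.

    Columns: ``individual_id, family_id, exposure, excluded``.  The nested
    design (each family under exactly one exposure) is checked; crossed
    input raises :class:`~famgxe.types.CrossedDesignWarning` and sets
    ``meta.attrs['crossed']``.
    """
    meta = pd.read_csv(path, sep="\t", dtype={
        "individual_id": str, "family_id": str, "exposure": str,
    })
    return validate_metadata(meta, allowed_exposures=allowed_exposures)


def read_traces(path) -> pd.DataFrame:
    """Read a long-format movement trace TSV.

    Columns: ``individual_id, bin_index, distance``.  Phase and cycle are
    derived downstream from the assay schedule, not stored in the file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    missing = [c for c in ("individual_id", "bin_index", "distance")
               if c not in df.columns]
    if missing:
        raise FormatError(f"trace file missing column(s) {missing}")
    if (df["distance"].to_numpy(dtype=float) < 0).any():
        raise FormatError("negative distance in trace file")
    df["bin_index"] = df["bin_index"].astype(int)
    return df


def read_phenotypes(path) -> pd.DataFrame:
    from .types import validate_phenotypes

    df = pd.read_csv(path, sep="\t", dtype={
        "individual_id": str, "family_id": str, "exposure": str,
    })
    return validate_phenotypes(df)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    write_results(table, path, sort_by="individual_id")


def write_results(table: pd.DataFrame, path, sort_by: str | None = None) -> None:
    """Write a result table as TSV.

    Deterministic row order (sorted by the first ``*_id`` column unless
    ``sort_by`` is given), floats at 6 significant digits, NaN as ``NA``.
    """
    table = table.copy()
    if sort_by is None:
        id_cols = [c for c in table.columns if str(c).endswith("_id")]
        sort_by = id_cols[0] if id_cols else None
    if sort_by is not None and sort_by in table.columns:
        table = table.sort_values(sort_by, kind="mergesort")
    table.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
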