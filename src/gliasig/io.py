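"""Readers and writers for the plain-text formats used across the pipeline.

Count matrices and metadata travel as TSV, gene sets as GMT, single-cell
matrices as MatrixMarket triplets with sidecar gene/barcode lists. All
writers produce files that round-trip through the corresponding reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a gene x sample count matrix; first column is ``gene_id``."""
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    """Write gene sets in GMT layout: name, description, then gene ids."""
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *list(genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    """Write a sparse matrix as <prefix>.mtx with gene/barcode sidecars."""
    prefix = Path(prefix)
    sparse = scipy.sparse.csr_matrix(counts.to_numpy())
    scipy.io.mmwrite(str(prefix) + ".mtx", sparse)
    pd.Series(counts.index).to_csv(str(prefix) + ".genes.tsv",
                                   sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(str(prefix) + ".barcodes.tsv",
                                     sep="\t", index=False, header=False)


def read_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = scipy.io.mmread(str(prefix) + ".mtx").toarray()
    genes = pd.read_csv(str(prefix) + ".genes.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(str(prefix) + ".barcodes.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(mat, index=genes.astype(str), columns=cells.astype(str))


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
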