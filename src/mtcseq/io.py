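"""Reading and writing the pipeline's on-disk formats.

Counts travel as TSV (genes in rows, ``gene_id`` first column, sample ids
as header) or MatrixMarket with side files of gene and sample ids; sample
metadata and clinical tables as TSV; models and reports as JSON; run
configuration as YAML.  All round-trips are lossless for integer counts,
and model JSON round-trips scores to well under 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .classify import TrainedClassifier
from .containers import CountMatrix, META_COLUMNS


def write_counts(cm: CountMatrix, counts_path, meta_path) -> None:
    df = pd.DataFrame(cm.counts, index=pd.Index(cm.gene_ids, name="gene_id"),
                      columns=cm.sample_ids)
    df.to_csv(counts_path, sep="\t")
    cm.sample_meta.to_csv(meta_path, sep="\t", index=False)


def read_counts(counts_path, meta_path) -> CountMatrix:
    """Read a counts TSV + metadata TSV pair, validating integer counts.

    A malformed row raises an error naming its (1-based) file line.
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0, dtype=str)
    n_cols = raw.shape[1]
    values = np.empty(raw.shape, dtype=np.int64)
    for i, (gene, row) in enumerate(raw.iterrows()):
        try:
            vals = row.to_numpy(dtype=np.float64)
            if np.any(np.isnan(vals)) or np.any(vals != np.round(vals)) \
                    or np.any(vals < 0) or len(vals) != n_cols:
                raise ValueError
            values[i] = vals.astype(np.int64)
        except (ValueError, TypeError):
            raise ValueError(
                f"{counts_path}: malformed row at line {i + 2} "
                f"(gene {gene!r}): expected {n_cols} non-negative integers"
            ) from None
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str,
                                                   "bethesda": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{meta_path}: missing metadata columns {missing}")
    if list(meta["sample_id"]) != list(raw.columns):
        raise ValueError("metadata sample order does not match count columns")
    return CountMatrix(counts=values, gene_ids=list(raw.index),
                       sample_meta=meta)


def write_counts_mtx(cm: CountMatrix, mtx_path, genes_path,
                     samples_path, meta_path=None) -> None:
    spio.mmwrite(str(mtx_path), sparse.csr_matrix(cm.counts))
    Path(genes_path).write_text("\n".join(cm.gene_ids) + "\n")
    Path(samples_path).write_text("\n".join(cm.sample_ids) + "\n")
    if meta_path is not None:
        cm.sample_meta.to_csv(meta_path, sep="\t", index=False)


def read_counts_mtx(mtx_path, genes_path, samples_path,
                    meta_path) -> CountMatrix:
    counts = np.asarray(spio.mmread(str(mtx_path)).todense()).astype(np.int64)
    genes = Path(genes_path).read_text().splitlines()
    samples = Path(samples_path).read_text().splitlines()
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str,
                                                   "bethesda": str})
    if list(meta["sample_id"]) != samples:
        raise ValueError("metadata sample order does not match MTX columns")
    if counts.shape != (len(genes), len(samples)):
        raise ValueError("MTX dimensions do not match id files")
    return CountMatrix(counts=counts, gene_ids=genes, sample_meta=meta)


def write_model(clf: TrainedClassifier, path) -> None:
    Path(path).write_text(json.dumps(clf.to_dict(), indent=1))


def read_model(path) -> TrainedClassifier:
    return TrainedClassifier.from_dict(json.loads(Path(path).read_text()))


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip()]
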