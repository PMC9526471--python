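"""Core in-memory containers shared across the pipeline.

The pipeline's sample universe is a gene-by-sample integer count matrix with
per-sample metadata (cohort, diagnostic label, Bethesda cytology category,
replicate-group id for technical controls, and an optional benign-RNA
dilution fraction for in-silico mixing experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Metadata columns every CountMatrix carries, in canonical order.
META_COLUMNS = [
    "sample_id",
    "cohort",
    "label",
    "bethesda",
    "replicate_group",
    "dilution_fraction",
]

COHORTS = ("train_fnab", "tissue", "valid_fnab", "control")
LABELS = ("MTC", "non-MTC")


@dataclass
class CountMatrix:
    """Integer RNA-seq counts (genes x samples) plus per-sample metadata.

    Attributes
    ----------
    counts : ndarray of shape (n_genes, n_samples)
        Non-negative integer read counts.
    gene_ids : list of str
        One identifier per row.
    sample_meta : DataFrame
        One row per column of ``counts`` with the columns in
        :data:`META_COLUMNS`.  ``cohort`` is one of ``train_fnab``,
        ``tissue``, ``valid_fnab`` or ``control``; ``label`` is ``MTC``
        or ``non-MTC``.
    """

    counts: np.ndarray
    gene_ids: list[str]
    sample_meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError("gene_ids length does not match count rows")
        if len(self.sample_meta) != self.counts.shape[1]:
            raise ValueError("sample_meta rows do not match count columns")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        bad = set(self.sample_meta["label"]) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        self.sample_meta = self.sample_meta.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta["sample_id"])

    def labels(self) -> np.ndarray:
        return self.sample_meta["label"].to_numpy()

    def select_samples(self, mask) -> "CountMatrix":
        """Return a new matrix restricted to samples where ``mask`` is true."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx],
            gene_ids=list(self.gene_ids),
            sample_meta=self.sample_meta.iloc[idx].reset_index(drop=True),
        )

    def cohort(self, name: str) -> "CountMatrix":
        if name not in COHORTS:
            raise ValueError(f"unknown cohort {name!r}; expected one of {COHORTS}")
        return self.select_samples(self.sample_meta["cohort"].to_numpy() == name)

    def concat(self, other: "CountMatrix") -> "CountMatrix":
        if self.gene_ids != other.gene_ids:
            raise ValueError("gene ids differ; cannot concatenate")
        return CountMatrix(
            counts=np.hstack([self.counts, other.counts]),
            gene_ids=list(self.gene_ids),
            sample_meta=pd.concat(
                [self.sample_meta, other.sample_meta], ignore_index=True
            ),
        )

    def gene_index(self, genes: list[str]) -> np.ndarray:
        """Row indices for ``genes``; raises listing any that are absent."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)
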