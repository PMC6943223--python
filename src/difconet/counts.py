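"""Count-matrix container and on-disk formats.

The count matrix is the sole entry point of the pipeline: a gene x sample
table of non-negative integer read counts with a two-level condition label
(``A`` = control, ``B`` = treatment) attached to every sample.  Supported
on-disk representations are a plain TSV (first column gene id, header row of
sample ids) plus a two-column condition map, or a MatrixMarket ``.mtx``
triplet with sidecar row/column name files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

CONDITIONS = ("A", "B")


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a per-sample condition label.

    Parameters
    ----------
    counts:
        DataFrame indexed by gene id with one column per sample id.
    condition:
        Series mapping sample id -> condition label in ``{"A", "B"}``,
        covering exactly the columns of ``counts``.
    """

    counts: pd.DataFrame
    condition: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            missing = list(self.condition.index[self.condition.isna()])
            raise ValueError(f"samples without condition label: {missing}")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"condition labels must be in {CONDITIONS}, got {sorted(bad)}")
        values = self.counts.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("counts must be finite")
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        for label in CONDITIONS:
            if (self.condition == label).sum() < 2:
                raise ValueError(f"need >= 2 samples in condition {label}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, label: str) -> pd.Index:
        """Sample ids belonging to one condition."""
        return self.condition.index[self.condition == label]

    def swap_conditions(self) -> "CountMatrix":
        """Return a copy with the A/B labels exchanged (for symmetry checks)."""
        swapped = self.condition.map({"A": "B", "B": "A"})
        return CountMatrix(self.counts.copy(), swapped)


# ---------------------------------------------------------------------------
# TSV representation

def write_counts_tsv(cm: CountMatrix, counts_path: str | Path, conditions_path: str | Path) -> None:
    counts = cm.counts.copy()
    counts.index.name = "gene"
    counts.to_csv(counts_path, sep="\t")
    cond = cm.condition.rename("condition").rename_axis("sample")
    cond.to_frame().to_csv(conditions_path, sep="\t")


def read_counts_tsv(counts_path: str | Path, conditions_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    cond = pd.read_csv(conditions_path, sep="\t", index_col=0)["condition"]
    return CountMatrix(counts, cond)


# ---------------------------------------------------------------------------
# MatrixMarket representation (counts.mtx + genes.txt + samples.txt)

def write_counts_mtx(cm: CountMatrix, mtx_path: str | Path,
                     genes_path: str | Path, samples_path: str | Path,
                     conditions_path: str | Path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(cm.counts.to_numpy()))
    Path(genes_path).write_text("\n".join(cm.gene_ids) + "\n")
    Path(samples_path).write_text("\n".join(cm.sample_ids) + "\n")
    cond = cm.condition.rename("condition").rename_axis("sample")
    cond.to_frame().to_csv(conditions_path, sep="\t")


def read_counts_mtx(mtx_path: str | Path, genes_path: str | Path,
                    samples_path: str | Path, conditions_path: str | Path) -> CountMatrix:
    matrix = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(matrix):
        matrix = matrix.toarray()
    genes = Path(genes_path).read_text().split()
    samples = Path(samples_path).read_text().split()
    counts = pd.DataFrame(np.asarray(matrix), index=genes, columns=samples)
    cond = pd.read_csv(conditions_path, sep="\t", index_col=0)["condition"]
    return CountMatrix(counts, cond)
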