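"""Shared in-memory containers used across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FRACTION_LABELS = ("BS_e", "I_e", "M_e")
SAMPLE_LABELS = ("BS_e", "I_e", "M_e", "BS", "M", "unseparated")

#: columns of a per-study differential-expression / tissue-specificity table
STUDY_RESULT_COLUMNS = ("gene_id", "log2fc", "p_value", "fdr", "mean_tpm")


@dataclass
class CountMatrix:
    """A genes x samples matrix of non-negative integer read counts.

    Parameters
    ----------
    counts:
        DataFrame indexed by gene id with one column per sample id.
    lengths:
        Per-gene transcript length in nucleotides, indexed like ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()]
            raise ValueError(f"missing lengths for genes: {list(missing[:5])}")
        if (self.lengths < 1).any():
            raise ValueError("gene lengths must be >= 1 nt")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def make_study_result(
    gene_ids,
    log2fc,
    p_value,
    fdr,
    mean_tpm,
    study_id: str = "",
    stage_id: str = "",
) -> pd.DataFrame:
    """Assemble a per-(gene, stage) tissue-specificity result table.

    One row per gene: BS-vs-M log2 fold change, p-value, BH FDR and the
    mean TPM of the stage. ``study_id``/``stage_id`` are carried as columns
    so tables from several studies can be concatenated.
    """
    df = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_ids),
            "log2fc": np.asarray(log2fc, dtype=float),
            "p_value": np.asarray(p_value, dtype=float),
            "fdr": np.asarray(fdr, dtype=float),
            "mean_tpm": np.asarray(mean_tpm, dtype=float),
        }
    )
    if (df["mean_tpm"] < 0).any():
        raise ValueError("mean_tpm must be non-negative")
    df.insert(0, "study_id", study_id)
    df.insert(1, "stage_id", stage_id)
    if df.duplicated(["gene_id", "stage_id"]).any():
        raise ValueError("duplicate (gene, stage) rows in study result")
    return df
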