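"""FPKM quantification, retention filtering and count normalisation.

FPKM is computed from subgenome-assigned counts, with the per-sample
denominator equal to the sum of assigned counts for that sample.  The
retention rule follows the pipeline-wide convention: a gene is kept for a
lineage when its FPKM exceeds 1 (strictly) in at least one sample of that
lineage.  Cross-sample normalisation uses DESeq-style median-of-ratios size
factors; within-sample homoeologue comparisons divide counts by gene length
first (length-corrected pseudo-counts).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def fpkm(count, gene_length_bp, sample_total_mapped):
    """Fragments per kilobase of model per million mapped fragments.

    ``count / ((length/1e3) * (total/1e6))``; scalar or vectorised.
    """
    length = np.asarray(gene_length_bp, dtype=float)
    total = np.asarray(sample_total_mapped, dtype=float)
    if np.any(length <= 0):
        raise ValueError("gene length must be positive")
    if np.any(total <= 0):
        raise ValueError("sample total must be positive")
    return np.asarray(count, dtype=float) / ((length / 1e3) * (total / 1e6))


def fpkm_matrix(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM for a genes x samples count matrix.

    Per-sample totals are the column sums of the assigned counts.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index[:3].tolist()
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total counts")
    out = counts.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    return out


def retention_filter(fpkm_table: pd.DataFrame, lineage_samples=None,
                     threshold: float = 1.0) -> pd.Series:
    """Boolean retained flag per gene: max FPKM over the lineage's samples
    strictly exceeds ``threshold``.

    ``lineage_samples`` defaults to every column (one cross = one lineage).
    """
    cols = list(fpkm_table.columns) if lineage_samples is None \
        else list(lineage_samples)
    return fpkm_table[cols].max(axis=1) > threshold


def length_normalized_abundance(counts: pd.DataFrame,
                                lengths: pd.Series,
                                ref_length: float | None = None) -> pd.DataFrame:
    """Counts rescaled to a common gene length for homoeologue-vs-homoeologue
    comparison within a sample.

    Each gene's counts are multiplied by ``ref_length / length``; the
    reference defaults to the geometric mean length of the genes involved.
    Cross-sample normalisation still requires size factors.
    """
    lengths = lengths.reindex(counts.index).astype(float)
    if ref_length is None:
        ref_length = float(np.exp(np.log(lengths).mean()))
    return counts.mul(ref_length / lengths, axis=0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq median-of-ratios size factors, normalised to geometric mean 1.

    For every gene positive in all samples, the ratio of each sample's count
    to the gene's geometric mean is formed; the factor is the per-sample
    median ratio.  If no gene is positive in every sample the function falls
    back to total-count scaling (with a warning), which is the only
    information left.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least two samples")
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        log.warning("no gene positive in all samples; "
                    "falling back to total-count size factors")
        totals = mat.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("cannot scale a sample with zero total")
        factors = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(factors, index=counts.columns)
    sub = mat[allpos]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)
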