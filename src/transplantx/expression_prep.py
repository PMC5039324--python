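"""Isoform collapsing, median-of-ratios normalization and gene filters.

The preprocessing chain mirrors a standard pool-seq RNA-seq workflow for a
de-novo transcriptome: transcript isoforms that share an assembly component
and an annotation are summed into "Unigene" rows; library sizes are equalized
with the median-of-ratios size-factor estimator; and genes that are too noisy
(sample SD exceeding the mean) or incompletely observed (a zero count in any
sample) are excluded before any hypothesis testing.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .errors import CrossReferenceError, EstimationError, ParameterError


def unigene_id(component_id: str, annotation: str) -> str:
    """Stable Unigene identifier: component plus a short annotation digest."""
    digest = hashlib.blake2b(annotation.encode("utf-8"), digest_size=4).hexdigest()
    return f"{component_id}_{digest}"


def collapse_isoforms(contig_counts: pd.DataFrame, annot: pd.DataFrame) -> pd.DataFrame:
    """Sum isoform (contig) rows that share (component, annotation) into Unigenes.

    Every contig in ``contig_counts`` must appear in ``annot``.  Column sums
    are conserved exactly.  Unigene rows keep the order in which their first
    isoform appears.
    """
    missing = contig_counts.index.difference(annot.index)
    if len(missing):
        raise CrossReferenceError(
            f"contigs without annotation: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    meta = annot.loc[contig_counts.index]
    ids = [
        unigene_id(c, a) for c, a in zip(meta["component_id"], meta["annotation"])
    ]
    grouped = contig_counts.groupby(pd.Index(ids, name="gene_id"), sort=False).sum()
    return grouped


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq scale-normalization estimator).

    For each gene with strictly positive counts in every sample, the ratio of
    each sample's count to the gene's geometric mean is formed; a sample's
    size factor is the median of those ratios.  Genes containing a zero are
    excluded from the pseudo-reference.  Computed in log space.
    """
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise EstimationError(
            "no gene has positive counts in every sample; size factors undefined"
        )
    logs = np.log(arr[positive])
    log_ratios = logs - logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide every sample column by its size factor."""
    factors = factors.reindex(counts.columns)
    if factors.isna().any():
        missing = list(factors.index[factors.isna()])
        raise ParameterError(f"no size factor for samples {missing}")
    if not np.isfinite(factors).all() or (factors <= 0).any():
        raise ParameterError("size factors must be finite and > 0")
    return counts / factors


def filter_genes(
    normalized: pd.DataFrame, use_variance: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop genes with SD > mean and/or a zero count in any sample.

    ``use_variance=True`` switches the noise rule to variance > mean.
    Returns the kept matrix and a per-gene report of which rule fired
    (``""`` kept, ``"zero"``, ``"sd>mean"`` / ``"var>mean"``, or both joined
    with ``;``).  The filter is idempotent.
    """
    arr = normalized.to_numpy(dtype=float)
    means = arr.mean(axis=1)
    if arr.shape[1] > 1:
        spread = arr.var(axis=1, ddof=1) if use_variance else arr.std(axis=1, ddof=1)
    else:
        spread = np.zeros(arr.shape[0])
    noisy = spread > means
    has_zero = (arr == 0).any(axis=1)
    noise_label = "var>mean" if use_variance else "sd>mean"
    reasons = []
    for z, s in zip(has_zero, noisy):
        tags = []
        if z:
            tags.append("zero")
        if s:
            tags.append(noise_label)
        reasons.append(";".join(tags))
    report = pd.DataFrame(
        {"gene_id": normalized.index, "kept": ~(noisy | has_zero), "reason": reasons}
    ).set_index("gene_id")
    kept = normalized.loc[report["kept"]]
    return kept, report
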