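"""Count-matrix filtering, normalization, transformation and aggregation.

Implements the preprocessing rules applied upstream of every analysis stage:
prevalence/abundance filters, relative abundance, the centered log-ratio
(CLR) transform, median-of-ratios size-factor normalization, rarefaction by
subsampling without replacement, and gene-to-pathway aggregation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrices import AbundanceMatrix, CountMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterRule:
    """Keep a feature iff it has >= min_count reads in >= min_samples samples."""

    min_count: int
    min_samples: int

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_samples < 0:
            raise ValueError("filter thresholds must be non-negative")


# Rules used by the reference workflow.
PLANT_GENE_RULE = FilterRule(min_count=75, min_samples=4)
MICROBIAL_GENE_RULE = FilterRule(min_count=250, min_samples=3)


def filter_low_expression(counts: CountMatrix, rule: FilterRule) -> CountMatrix:
    """Drop features lacking ``rule.min_count`` reads in ``rule.min_samples`` samples.

    Sample set and feature order are preserved.  An empty result is returned
    (with a warning), not raised.
    """
    qualifying = (counts.data >= rule.min_count).sum(axis=1)
    keep = qualifying >= rule.min_samples
    if not keep.any():
        warnings.warn("low-expression filter removed every feature", stacklevel=2)
        return _empty_like(counts)
    return CountMatrix(data=counts.data.loc[keep], kind=counts.kind)


def _empty_like(counts: CountMatrix) -> CountMatrix:
    # CountMatrix forbids zero features, so an "empty" result bypasses the
    # constructor deliberately.
    out = CountMatrix.__new__(CountMatrix)
    out.data = counts.data.iloc[0:0]
    out.kind = counts.kind
    return out


def filter_taxa(counts: CountMatrix, min_reads: int = 10, min_samples: int = 2) -> CountMatrix:
    """Remove rare, low-abundance taxa.

    A taxon is kept iff it is present (count > 0) in >= ``min_samples`` samples
    AND has >= ``min_reads`` reads in >= ``min_samples`` samples.
    """
    if counts.kind != "taxon":
        raise ValueError(f"filter_taxa expects a taxon matrix, got kind={counts.kind!r}")
    present = (counts.data > 0).sum(axis=1) >= min_samples
    abundant = (counts.data >= min_reads).sum(axis=1) >= min_samples
    keep = present & abundant
    if not keep.any():
        warnings.warn("taxa filter removed every taxon", stacklevel=2)
        return _empty_like(counts)
    return CountMatrix(data=counts.data.loc[keep], kind=counts.kind)


def relative_abundance(counts: CountMatrix) -> AbundanceMatrix:
    """Divide every column by its total so columns sum to one."""
    totals = counts.data.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero) > 0:
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    rel = counts.data / totals
    return AbundanceMatrix(data=rel, transform="relative")


def clr_transform(
    matrix: AbundanceMatrix | CountMatrix, pseudocount: float = 0.5
) -> AbundanceMatrix:
    """Centered log-ratio transform per sample (column).

    Each column becomes ``ln(x + pc) - mean(ln(x + pc))`` and therefore sums
    to zero.  ``pseudocount`` must be positive whenever zeros are present.
    """
    data = matrix.data.astype(float)
    values = data.to_numpy()
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (values <= 0).any():
        raise ValueError("non-positive values require a positive pseudocount")
    logged = np.log(values + pseudocount)
    clr = logged - logged.mean(axis=0, keepdims=True)
    return AbundanceMatrix(
        data=pd.DataFrame(clr, index=data.index, columns=data.columns),
        transform="clr",
    )


def median_ratio_normalize(
    counts: CountMatrix,
) -> tuple[AbundanceMatrix, pd.Series]:
    """Median-of-ratios size-factor normalization.

    Reference features are those with positive counts in every sample.  The
    size factor of sample *j* is the median over reference features of
    ``k_ij / geomean_j(k_ij)``; size factors are rescaled to geometric mean 1
    and each column is divided by its factor.
    """
    data = counts.data.astype(float)
    reference = (data > 0).all(axis=1)
    if not reference.any():
        raise ValueError("no feature has positive counts in every sample")
    ref = data.loc[reference]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geomean, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    size_factors = size_factors / np.exp(np.log(size_factors).mean())
    normalized = data / size_factors
    return (
        AbundanceMatrix(data=normalized, transform="median_ratio"),
        size_factors.rename("size_factor"),
    )


def rarefy(counts: CountMatrix, depth: int, seed: int = 0) -> CountMatrix:
    """Subsample each column without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a warning.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.data.sum(axis=0)
    kept_cols = []
    dropped = []
    columns = {}
    for sample in counts.sample_ids:
        col = counts.data[sample].to_numpy(dtype=np.int64)
        total = int(totals[sample])
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            columns[sample] = col
        else:
            columns[sample] = rng.multivariate_hypergeometric(col, depth)
        kept_cols.append(sample)
    if dropped:
        warnings.warn(
            f"rarefy dropped {len(dropped)} sample(s) below depth {depth}: {dropped}",
            stacklevel=2,
        )
        logger.info("rarefy dropped samples: %s", dropped)
    if not kept_cols:
        warnings.warn("all samples below rarefaction depth", stacklevel=2)
        out = CountMatrix.__new__(CountMatrix)
        out.data = counts.data.iloc[:, 0:0]
        out.kind = counts.kind
        return out
    data = pd.DataFrame(columns, index=counts.feature_ids)[kept_cols]
    return CountMatrix(data=data, kind=counts.kind)


def collapse_pathways(counts: CountMatrix, annotation: pd.DataFrame) -> CountMatrix:
    """Aggregate microbial gene counts into pathway counts.

    ``annotation`` maps gene id -> pathway id and may be many-to-many: a gene
    annotated to several pathways contributes its full counts to each.  Genes
    absent from the mapping are pooled into an ``unassigned`` pathway.
    """
    if counts.kind != "microbial_gene":
        raise ValueError("collapse_pathways expects a microbial_gene matrix")
    if annotation.empty:
        raise ValueError("annotation mapping is empty")
    ann = annotation[["gene_id", "pathway_id"]].drop_duplicates()
    ann = ann[ann["gene_id"].isin(counts.feature_ids)]
    annotated_genes = set(ann["gene_id"])
    pieces = []
    if not ann.empty:
        joined = counts.data.loc[ann["gene_id"]].copy()
        joined.index = pd.Index(ann["pathway_id"], name="pathway_id")
        pieces.append(joined.groupby(level=0).sum())
    unassigned = [g for g in counts.feature_ids if g not in annotated_genes]
    if unassigned:
        pooled = counts.data.loc[unassigned].sum(axis=0).to_frame("unassigned").T
        pieces.append(pooled)
    collapsed = pd.concat(pieces)
    collapsed = collapsed.groupby(level=0).sum()
    return CountMatrix(data=collapsed.astype(np.int64), kind="pathway")
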