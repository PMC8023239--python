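"""Count normalization: depth subsampling, RPKM, presence calls, HV rollup.

The normalization chain mirrors standard virome practice: raw per-contig read
counts are rarefied to a constant depth (multivariate hypergeometric draw,
i.e. subsampling reads without replacement), converted to RPKM
(reads per contig-kilobase per million mapped reads), thresholded into
presence/absence (strictly > 7 RPKM by default), and summed into HV-group
abundances.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .hv import HVGrouping
from .io import AbundanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_DEPTH = 1_367_462
DEFAULT_PRESENCE_RPKM = 7.0


def subsample_counts(
    counts: AbundanceMatrix,
    depth: int = DEFAULT_DEPTH,
    seed: int | np.random.Generator | None = None,
) -> AbundanceMatrix:
    """Rarefy each sample to exactly ``depth`` reads without replacement.

    Columns whose total is already <= ``depth`` pass through unchanged (with a
    warning); the draw is a multivariate hypergeometric, so the subsample is
    an exact uniform subset of the original reads. Deterministic given seed.
    """
    if depth <= 0:
        raise ValueError("subsampling depth must be positive")
    if counts.unit != "raw_count":
        raise ValueError("subsampling requires raw counts")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = counts.values.copy()
    for col in out.columns:
        column = out[col].to_numpy(dtype=np.int64)
        total = int(column.sum())
        if total <= depth:
            if total < depth:
                logger.warning(
                    "sample %s has %d < %d reads; kept unsubsampled", col, total, depth
                )
            continue
        out[col] = rng.multivariate_hypergeometric(column, depth)
    return counts.copy_with(out)


def compute_rpkm(counts: AbundanceMatrix) -> AbundanceMatrix:
    """RPKM[i, s] = count[i, s] / (length_i / 1e3) / (total_s / 1e6)."""
    if counts.unit != "raw_count":
        raise ValueError("RPKM is computed from raw counts only")
    if counts.lengths is None:
        raise ValueError("contig lengths are required to compute RPKM")
    if counts.values.empty:
        raise ValueError("cannot compute RPKM of an empty matrix")
    lengths = counts.lengths.loc[counts.values.index].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("zero-length contig in catalog")
    totals = counts.values.sum(axis=0).to_numpy(dtype=float)
    zero = totals == 0
    if zero.any():
        logger.warning("samples with zero total reads: %s",
                       list(counts.values.columns[zero]))
        totals[zero] = 1.0  # column stays all-zero
    rpkm = counts.values.to_numpy(dtype=float) / (lengths[:, None] / 1e3) / (totals[None, :] / 1e6)
    values = pd.DataFrame(rpkm, index=counts.values.index, columns=counts.values.columns)
    return AbundanceMatrix(values, unit="rpkm", lengths=counts.lengths)


def apply_presence(rpkm: AbundanceMatrix, threshold: float = DEFAULT_PRESENCE_RPKM) -> pd.DataFrame:
    """Boolean presence mask: present iff RPKM strictly exceeds ``threshold``."""
    if rpkm.unit != "rpkm":
        raise ValueError("presence is defined on RPKM values")
    return rpkm.values > threshold


def drop_16s(matrix: AbundanceMatrix, flags: set[str]) -> AbundanceMatrix:
    """Remove contigs flagged as 16S rDNA carriers from the matrix."""
    unknown = flags - set(matrix.values.index)
    if unknown:
        logger.warning("16S flags not in matrix (ignored): %s", sorted(unknown)[:5])
    keep = [c for c in matrix.values.index if c not in flags]
    if not keep:
        raise ValueError("all contigs flagged as 16S; nothing left to analyze")
    return AbundanceMatrix(matrix.values.loc[keep], matrix.unit, matrix.lengths)


def drop_16s_catalog(lengths: pd.Series, flags: set[str]) -> pd.Series:
    unknown = flags - set(lengths.index)
    if unknown:
        logger.warning("16S flags not in catalog (ignored): %s", sorted(unknown)[:5])
    return lengths.drop(index=[c for c in flags if c in lengths.index])


def aggregate_to_hv(
    rpkm: AbundanceMatrix,
    grouping: HVGrouping,
    include_singletons: bool = True,
) -> AbundanceMatrix:
    """Sum member-contig RPKM into HV-group rows.

    Members of a group are fragments/variants of the same virus, so their
    mass adds. Singletons are optionally carried through as their own rows.
    """
    mapping = grouping.group_of()
    missing = set(rpkm.values.index) - set(mapping)
    if missing:
        raise KeyError(f"contigs not covered by grouping: {sorted(missing)[:5]}")
    labels = rpkm.values.index.map(mapping)
    agg = rpkm.values.groupby(labels).sum()
    # groups with no contig in the matrix contribute an explicit zero row
    rows = sorted(grouping.groups, key=lambda g: (len(g), g))
    if include_singletons:
        rows += sorted(s for s in grouping.singletons if s in agg.index)
    out = agg.reindex(rows, fill_value=0.0)
    return AbundanceMatrix(out, unit=rpkm.unit)
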