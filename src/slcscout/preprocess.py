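"""Count normalisation and tissue-wise metabolite standardisation.

Expression counts are normalised with the median-of-ratios (DESeq2-style)
size factors: every sample is scaled by the median, over genes with a
strictly positive geometric mean, of its count divided by that gene's
geometric mean across samples.  Metabolite concentrations are converted
to z-scores within each tissue to remove tissue-specific abundance
before they meet the CRISPR dependency contrast.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data_model import OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Degrees-of-freedom convention for every standard deviation in the
#: package (z-scores and the transformed-rho denominator).  1 = sample SD.
SD_DDOF = 1


class NormalizationError(ValueError):
    """Median-of-ratios size factors could not be estimated."""


def mrn_normalize(
    counts: OmicsMatrix, min_total: int = 10
) -> tuple[OmicsMatrix, pd.Series]:
    """Median-ratio normalisation of a count matrix.

    Genes whose total across samples is below ``min_total`` are dropped
    before factor estimation.  Genes containing any zero (or missing)
    count are excluded from factor estimation but kept in the output.
    Returns the pseudocount matrix (count / per-sample size factor) and
    the size factors.
    """
    if counts.kind != "counts":
        raise ValidationError(f"expected counts matrix, got {counts.kind!r}")
    if counts.shape[1] < 2:
        raise NormalizationError("need at least 2 samples for size factors")
    vals = counts.values
    totals = vals.sum(axis=1, skipna=True)
    kept = vals.loc[totals >= min_total]
    if kept.empty:
        raise NormalizationError("no gene passes the minimum-total filter")

    arr = kept.to_numpy()
    # geometric means in log space; only all-positive, fully observed genes
    usable = np.all(np.isfinite(arr), axis=1) & np.all(arr > 0, axis=1)
    if not usable.any():
        raise NormalizationError("no gene with strictly positive geometric mean")
    log_arr = np.log(arr[usable])
    log_geomean = log_arr.mean(axis=1)
    log_ratios = log_arr - log_geomean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    for sample, f in zip(kept.columns, factors):
        if f <= 0 or not np.isfinite(f):
            raise NormalizationError(f"sample {sample!r}: ratio median is not positive")

    size_factors = pd.Series(factors, index=kept.columns, name="size_factor")
    pseudo = kept / factors
    out = OmicsMatrix(pseudo, "pseudocounts", counts.sample_annotations)
    return out, size_factors


def tissue_zscore(
    metab: OmicsMatrix, tissue_map: dict[str, str] | None = None
) -> OmicsMatrix:
    """Z-score metabolite levels within each tissue group.

    For each (tissue, metabolite) the values become
    ``(x - group mean) / group sample-SD`` over non-missing samples.
    Groups of size 1 or with zero spread yield missing z-scores with a
    logged warning rather than an exception.
    """
    if tissue_map is None:
        tissue_map = metab.sample_annotations
    if tissue_map is None:
        raise ValidationError("tissue_zscore requires a tissue label per sample")
    missing = [s for s in metab.sample_ids if s not in tissue_map]
    if missing:
        raise ValidationError(f"samples without tissue label: {missing[:5]}")

    vals = metab.values
    out = pd.DataFrame(np.nan, index=vals.index, columns=vals.columns)
    tissues = pd.Series({s: tissue_map[s] for s in vals.columns})
    n_degenerate = 0
    for tissue, samples in tissues.groupby(tissues).groups.items():
        block = vals[list(samples)]
        mean = block.mean(axis=1, skipna=True)
        sd = block.std(axis=1, ddof=SD_DDOF, skipna=True)
        n_finite = block.notna().sum(axis=1)
        ok = (n_finite >= 2) & (sd > 0)
        n_degenerate += int((~ok).sum())
        z = block.sub(mean, axis=0).div(sd.where(ok), axis=0)
        out[list(samples)] = z
    if n_degenerate:
        logger.warning(
            "tissue_zscore: %d (tissue, metabolite) groups degenerate; set missing",
            n_degenerate,
        )
    ann = {s: tissue_map[s] for s in vals.columns}
    return OmicsMatrix(out, "metabolite_zscore", ann)
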