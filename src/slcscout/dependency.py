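"""CRISPR gene-dependency contrasts.

For one transporter, cell lines with a negative gene-effect score (i.e.
lines whose growth suffers when the gene is knocked out) are ranked by
effect.  The most-dependent 20% and least-dependent 20% are compared per
metabolite with a two-sided Wilcoxon rank-sum test on tissue z-scored
levels, BH-adjusted across metabolites within the transporter.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

DEPENDENCY_COLUMNS = [
    "slc_id", "metabolite_id", "n_top", "n_bottom", "p", "p_adj", "direction",
]

MIN_ELIGIBLE_LINES = 10


def _rank_sum_p(top: np.ndarray, bottom: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact null distribution for tie-free groups of at most 10 each;
    normal approximation with tie correction otherwise.
    """
    pooled = np.concatenate([top, bottom])
    if np.all(pooled == pooled[0]):
        return 1.0
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (not ties and max(len(top), len(bottom)) <= 10) else "asymptotic"
    _, p = stats.mannwhitneyu(top, bottom, alternative="two-sided", method=method)
    return float(p)


def dependency_groups(
    effect: OmicsMatrix, slc_id: str, samples, frac: float = 0.2
) -> tuple[list[str], list[str]] | None:
    """Split eligible lines into most- and least-dependent groups.

    Eligible = shared lines with a strictly negative effect score, ranked
    ascending (ties broken by sample id so grouping is deterministic).
    Returns None when fewer than 10 lines are eligible.
    """
    if slc_id not in effect.values.index:
        return None
    scores = effect.values.loc[slc_id, [s for s in samples if s in effect.values.columns]]
    scores = scores[np.isfinite(scores) & (scores < 0)]
    n = len(scores)
    if n < MIN_ELIGIBLE_LINES:
        return None
    order = sorted(scores.index, key=lambda s: (scores[s], s))
    k = math.floor(frac * n)
    if k < 1:
        return None
    return order[:k], order[-k:]


def dependency_scan(
    effect: OmicsMatrix,
    metab_z: OmicsMatrix,
    slc_id: str,
    frac: float = 0.2,
) -> pd.DataFrame:
    """Per-metabolite dependency contrast for one transporter.

    Returns an empty table (with a logged reason) when the transporter
    has fewer than 10 eligible cell lines.
    """
    if metab_z.kind != "metabolite_zscore":
        raise ValidationError(f"expected metabolite_zscore matrix, got {metab_z.kind!r}")
    groups = dependency_groups(effect, slc_id, metab_z.sample_ids, frac)
    if groups is None:
        logger.info("dependency_scan: %s skipped (<%d eligible lines)",
                    slc_id, MIN_ELIGIBLE_LINES)
        return pd.DataFrame(columns=DEPENDENCY_COLUMNS)
    top_ids, bottom_ids = groups

    rows = []
    n_degenerate = 0
    top_block = metab_z.values[top_ids].to_numpy()
    bottom_block = metab_z.values[bottom_ids].to_numpy()
    for i, met in enumerate(metab_z.feature_ids):
        top = top_block[i][np.isfinite(top_block[i])]
        bottom = bottom_block[i][np.isfinite(bottom_block[i])]
        if len(top) < 2 or len(bottom) < 2:
            n_degenerate += 1
            rows.append((slc_id, met, len(top_ids), len(bottom_ids), np.nan, np.nan, 0))
            continue
        p = _rank_sum_p(top, bottom)
        direction = int(np.sign(np.median(top) - np.median(bottom)))
        rows.append((slc_id, met, len(top_ids), len(bottom_ids), p, np.nan, direction))
    if n_degenerate:
        logger.warning("dependency_scan[%s]: %d metabolites with <2 finite values per group",
                       slc_id, n_degenerate)
    out = pd.DataFrame(rows, columns=DEPENDENCY_COLUMNS)
    finite = out["p"].notna()
    if finite.any():
        _, adj, _, _ = multipletests(out.loc[finite, "p"].to_numpy(), method="fdr_bh")
        out.loc[finite, "p_adj"] = adj
    return out


def dependency_scan_all(
    effect: OmicsMatrix,
    metab_z: OmicsMatrix,
    slc_ids,
    frac: float = 0.2,
) -> pd.DataFrame:
    """Run :func:`dependency_scan` for a list of transporters."""
    parts = [dependency_scan(effect, metab_z, s, frac) for s in slc_ids]
    parts = [p for p in parts if not p.empty]
    if not parts:
        return pd.DataFrame(columns=DEPENDENCY_COLUMNS)
    return pd.concat(parts, ignore_index=True)
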