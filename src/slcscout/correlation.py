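"""Panel-wise transporter-metabolite rank correlations.

For each (SLC, metabolite) pair measured in a panel, Spearman's rho is
computed across the cell lines shared by the expression and metabolite
matrices (pairwise-complete, average ranks for ties, p-value from the
large-sample t approximation).  p-values are then Benjamini-Hochberg
adjusted within each transporter, and rho is mapped onto the
transformed scale

    rho~(a, z) = (|rho(a, z)| - mean_a' |rho(a', z)|) / sd_a' |rho(a', z)|

i.e. each metabolite's absolute correlations across all transporters are
standardised, making correlation strength comparable between metabolites
whose |rho| distributions differ.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import OmicsMatrix, ValidationError
from .preprocess import SD_DDOF

logger = logging.getLogger(__name__)

CORRELATION_COLUMNS = [
    "slc_id", "metabolite_id", "dataset_id", "n_samples", "rho", "p",
]


def _spearman_p(rho: float, n: int) -> float:
    """Two-sided p from the t approximation, as R's cor.test uses at scale."""
    if not np.isfinite(rho) or n < 3:
        return np.nan
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_panel(
    expr: OmicsMatrix,
    metab: OmicsMatrix,
    slc_ids,
    dataset_id: str = "panel",
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Spearman correlation of every SLC against every metabolite.

    Pairs with fewer than ``min_overlap`` mutually complete cell lines
    are omitted (a count is logged).  A pair whose overlap is constant in
    either variable yields a row with missing rho/p.
    """
    shared = [s for s in expr.sample_ids if s in set(metab.sample_ids)]
    if not shared:
        raise ValidationError("expression and metabolite matrices share no samples")
    slc_ids = [s for s in slc_ids if s in expr.values.index]
    e = expr.values.loc[slc_ids, shared].to_numpy()
    m = metab.values.loc[:, shared].to_numpy()
    met_ids = metab.feature_ids

    rows = []
    n_dropped = 0
    e_finite = np.isfinite(e)
    m_finite = np.isfinite(m)

    # fast path: columns fully observed in both matrices
    complete = e_finite.all(axis=0).all() and m_finite.all(axis=0).all() if e.size and m.size else False
    if complete:
        n = len(shared)
        if n >= min_overlap:
            er = np.apply_along_axis(stats.rankdata, 1, e)
            mr = np.apply_along_axis(stats.rankdata, 1, m)
            ez = er - er.mean(axis=1, keepdims=True)
            mz = mr - mr.mean(axis=1, keepdims=True)
            es = np.sqrt((ez**2).sum(axis=1))
            ms = np.sqrt((mz**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = (ez @ mz.T) / np.outer(es, ms)
            for i, slc in enumerate(slc_ids):
                for j, met in enumerate(met_ids):
                    rho = corr[i, j]
                    rho = float(rho) if np.isfinite(rho) else np.nan
                    rows.append((slc, met, dataset_id, n, rho, _spearman_p(rho, n)))
        else:
            n_dropped = len(slc_ids) * len(met_ids)
    else:
        for i, slc in enumerate(slc_ids):
            for j, met in enumerate(met_ids):
                mask = e_finite[i] & m_finite[j]
                n = int(mask.sum())
                if n < min_overlap:
                    n_dropped += 1
                    continue
                x, y = e[i, mask], m[j, mask]
                if np.all(x == x[0]) or np.all(y == y[0]):
                    rows.append((slc, met, dataset_id, n, np.nan, np.nan))
                    continue
                rho, _ = stats.spearmanr(x, y)
                rho = float(rho)
                rows.append((slc, met, dataset_id, n, rho, _spearman_p(rho, n)))
    if n_dropped:
        logger.info(
            "correlate_panel[%s]: %d pairs dropped below min_overlap=%d",
            dataset_id, n_dropped, min_overlap,
        )
    out = pd.DataFrame(rows, columns=CORRELATION_COLUMNS)
    n_const = int(out["rho"].isna().sum())
    if n_const:
        logger.warning(
            "correlate_panel[%s]: %d pairs constant over overlap; rho missing",
            dataset_id, n_const,
        )
    return out


def bh_adjust(table: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment within each (slc_id, dataset_id) family."""
    out = table.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby(["slc_id", "dataset_id"]).groups.items():
        p = out.loc[idx, "p"]
        finite = p.notna()
        if finite.any():
            _, adj, _, _ = multipletests(p[finite].to_numpy(), method="fdr_bh")
            out.loc[p[finite].index, "p_adj"] = adj
    return out


def transform_rho(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardise |rho| within each (metabolite, dataset) across SLCs.

    Returns the table with a ``rho_transformed`` column plus the per-group
    mean/SD statistics for reuse (e.g. interpreting thresholds).
    Groups with fewer than 3 finite correlations, or zero spread, yield
    missing transformed values with a warning.
    """
    out = table.copy()
    out["abs_rho"] = out["rho"].abs()
    grp = out.groupby(["metabolite_id", "dataset_id"])["abs_rho"]
    stats_df = grp.agg(
        mean_abs_rho="mean",
        sd_abs_rho=lambda s: s.std(ddof=SD_DDOF),
        n_slcs="count",
    ).reset_index()
    merged = out.merge(stats_df, on=["metabolite_id", "dataset_id"], how="left")
    # treat numerically-zero spread (identical |rho|) as degenerate
    sd_floor = 1e-12 * np.maximum(1.0, merged["mean_abs_rho"].abs())
    ok = (merged["n_slcs"] >= 3) & (merged["sd_abs_rho"] > sd_floor)
    n_bad = int((~ok & merged["abs_rho"].notna()).sum())
    if n_bad:
        logger.warning("transform_rho: %d rows in degenerate groups; set missing", n_bad)
    out["rho_transformed"] = np.where(
        ok, (merged["abs_rho"] - merged["mean_abs_rho"]) / merged["sd_abs_rho"], np.nan
    )
    out = out.drop(columns=["abs_rho"])
    return out, stats_df


def dataset_concordance(
    a: pd.DataFrame, b: pd.DataFrame, subset=None
) -> tuple[float, float, int]:
    """Spearman correlation of raw rho between two panels.

    Only (slc, metabolite) pairs measured in both panels contribute;
    ``subset`` optionally restricts to a list of (slc_id, metabolite_id)
    tuples (e.g. the known pairs).
    """
    merged = a.merge(b, on=["slc_id", "metabolite_id"], suffixes=("_a", "_b"))
    if subset is not None:
        keys = set((str(s), str(m)) for s, m in subset)
        mask = [
            (s, m) in keys
            for s, m in zip(merged["slc_id"], merged["metabolite_id"])
        ]
        merged = merged.loc[mask]
    merged = merged.dropna(subset=["rho_a", "rho_b"])
    if len(merged) < 3:
        raise ValidationError(
            f"dataset_concordance: only {len(merged)} overlapping pairs (<3)"
        )
    rho, p = stats.spearmanr(merged["rho_a"], merged["rho_b"])
    return float(rho), float(p), len(merged)
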