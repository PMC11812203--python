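"""Benchmarking machinery: permutation nulls, threshold optimisation,
recovery curves, ROC/PR, ranking and pathway over-representation.

The permutation null keeps the transporter column of the known-pair
table fixed and reassigns each row a metabolite the transporter is not
known to transport; 100 such tables give the false-positive reference
used everywhere.  The optimisation objective for a Threshold of
Discovery is the mean, over confidence-score cutoffs 1..100, of the
known-set recovery fraction minus the mean simulated-random recovery
fraction ("mean fractional difference").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as _skm
from statsmodels.stats.multitest import multipletests

from .data_model import ValidationError, make_known_pairs
from .scoring import ScoreParams, confidence_scores, known_quantiles, subscore

logger = logging.getLogger(__name__)

#: Confidence-score cutoffs swept by recovery curves and optimisation.
CUTOFF_GRID = np.arange(1, 101)

#: "Better than cutoff" is read strictly.
STRICTLY_GREATER = True


def simulate_random_pairs(
    known: pd.DataFrame,
    universe,
    n: int = 100,
    seed: int = 0,
    max_attempts: int = 1000,
) -> list[pd.DataFrame]:
    """Simulated random pair tables: same SLC column, shuffled metabolites.

    Every generated row is guaranteed absent from the known table; rows
    are redrawn from the metabolite universe until that holds.
    """
    universe = [str(m) for m in universe]
    known_keys = set(zip(known["slc_id"], known["target_id"]))
    allowed = {
        slc: [m for m in universe if (slc, m) not in known_keys]
        for slc in known["slc_id"].unique()
    }
    for slc, opts in allowed.items():
        if not opts:
            raise ValidationError(
                f"simulate_random_pairs: no allowed metabolite for SLC {slc!r}"
            )
    rng = np.random.default_rng(seed)
    tables = []
    slcs = known["slc_id"].to_numpy()
    for _ in range(n):
        mets = []
        # start from a permutation of the universe draw, then repair clashes
        for slc in slcs:
            opts = allowed[slc]
            mets.append(opts[rng.integers(len(opts))])
        table = make_known_pairs(list(zip(slcs, mets)) )
        tables.append(table)
    return tables


def recovery_curve(scores, cutoffs=CUTOFF_GRID) -> pd.DataFrame:
    """Fraction of scores better than each cutoff (strictly greater)."""
    arr = np.asarray(list(scores), dtype=float)
    cutoffs = np.asarray(cutoffs)
    if arr.size == 0:
        frac = np.zeros(len(cutoffs))
    elif STRICTLY_GREATER:
        frac = (arr[None, :] > cutoffs[:, None]).mean(axis=1)
    else:
        frac = (arr[None, :] >= cutoffs[:, None]).mean(axis=1)
    return pd.DataFrame({"cutoff": cutoffs, "fraction": frac})


def fractional_difference(known_scores, random_score_sets, cutoffs=CUTOFF_GRID) -> float:
    """Mean over cutoffs of (known fraction - mean random fraction)."""
    kf = recovery_curve(known_scores, cutoffs)["fraction"].to_numpy()
    rf = np.mean(
        [recovery_curve(r, cutoffs)["fraction"].to_numpy() for r in random_score_sets],
        axis=0,
    )
    return float(np.mean(kf - rf))


def optimize_tod(
    known_values,
    random_value_sets,
    grid,
    weight: float = 3.0,
    cutoffs=CUTOFF_GRID,
) -> tuple[float, pd.DataFrame]:
    """Choose the Threshold of Discovery maximising the mean fractional
    difference for a single source.

    For each candidate ToD the known values define the decile knots; the
    known set and every random table are sub-scored against them and the
    weighted sub-scores enter the recovery comparison.  Ties break
    toward the smaller candidate.
    """
    grid = list(grid)
    if not grid:
        raise ValidationError("optimize_tod: empty candidate grid")
    diag = []
    for tod in grid:
        try:
            q = known_quantiles(known_values, tod)
        except ValidationError:
            diag.append({"tod": tod, "objective": -math.inf})
            continue
        ks = [weight * subscore(v, tod, q) for v in known_values]
        rs = [
            [weight * subscore(v, tod, q) for v in rvals]
            for rvals in random_value_sets
        ]
        diag.append({"tod": tod, "objective": fractional_difference(ks, rs, cutoffs)})
    diag_df = pd.DataFrame(diag)
    best_obj = diag_df["objective"].max()
    best = diag_df.loc[diag_df["objective"] == best_obj, "tod"].min()
    return float(best), diag_df


def bootstrap_stat(values, B: int = 100, stat: str = "mean", seed: int = 0) -> np.ndarray:
    """B bootstrap resamples (with replacement) of a statistic."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("bootstrap_stat: empty values")
    fn = {"mean": np.mean, "median": np.median, "median_rank": np.median}[stat]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(B, arr.size))
    return np.array([fn(arr[i]) for i in idx])


def roc_pr(pos_scores, neg_scores) -> tuple[float, float]:
    """ROC and precision-recall AUC by the trapezoidal rule.

    Thresholds sweep the pooled score set; tied scores enter together.
    """
    pos = np.asarray(list(pos_scores), dtype=float)
    neg = np.asarray(list(neg_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("roc_pr: both score lists must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, _ = _skm.roc_curve(y, s)
    roc_auc = float(_skm.auc(fpr, tpr))
    prec, rec, _ = _skm.precision_recall_curve(y, s)
    pr_auc = float(_skm.auc(rec[::-1], prec[::-1]))
    return roc_auc, pr_auc


def rank_predictions(conf: pd.DataFrame) -> pd.DataFrame:
    """Per-SLC descending rank and rank percentile among non-zero scores.

    Tied confidences share the mean rank; zero-score metabolites are
    excluded; SLCs with no non-zero score are dropped with a note.
    """
    out = []
    n_empty = 0
    for slc, grp in conf.groupby("slc_id"):
        nz = grp[grp["confidence"] > 0].copy()
        if nz.empty:
            n_empty += 1
            continue
        nz["rank"] = nz["confidence"].rank(ascending=False, method="average")
        nz["rank_percentile"] = nz["rank"] / len(nz)
        out.append(nz[["slc_id", "metabolite_id", "confidence", "rank", "rank_percentile"]])
    if n_empty:
        logger.info("rank_predictions: %d SLCs with no non-zero score excluded", n_empty)
    if not out:
        return pd.DataFrame(
            columns=["slc_id", "metabolite_id", "confidence", "rank", "rank_percentile"]
        )
    return pd.concat(out, ignore_index=True)


def pathway_enrichment(
    selected, pathways: pd.DataFrame, universe
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per pathway, BH-adjusted.

    ``selected`` must be a subset of ``universe``; pathway membership is
    restricted to the universe before testing.
    """
    selected = {str(m) for m in selected}
    universe = {str(m) for m in universe}
    if not selected:
        raise ValidationError("pathway_enrichment: empty selected set")
    if not selected <= universe:
        raise ValidationError("pathway_enrichment: selected set not within universe")
    N, n = len(universe), len(selected)
    rows = []
    for pw, grp in pathways.groupby("pathway_id"):
        members = set(grp["metabolite_id"]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway_id": pw, "overlap": k, "pathway_size": K, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        _, adj, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["p_adj"] = adj
    return out


def partition_pairs(
    known: pd.DataFrame, split: float = 0.7, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test partition; train size = floor(split * n)."""
    rng = np.random.default_rng(rng)
    n = len(known)
    n_train = math.floor(split * n)
    order = rng.permutation(n)
    train = known.iloc[order[:n_train]].reset_index(drop=True)
    test = known.iloc[order[n_train:]].reset_index(drop=True)
    return train, test


@dataclass
class TrainTestSettings:
    split: float = 0.7
    iters: int = 10
    tod_grid: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_random_tables: int = 20
    top_fraction: float = 0.04


def _known_panel_values(corr: pd.DataFrame, pairs: pd.DataFrame, dataset_id: str):
    keys = set(zip(pairs["slc_id"], pairs["target_id"]))
    sub = corr[corr["dataset_id"] == dataset_id]
    mask = [(s, m) in keys for s, m in zip(sub["slc_id"], sub["metabolite_id"])]
    return sub.loc[mask, "rho_transformed"].dropna().tolist()


def train_test_cycle(
    corr: pd.DataFrame,
    dep: pd.DataFrame | None,
    adj,
    known: pd.DataFrame,
    universe,
    base_params: ScoreParams,
    settings: TrainTestSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated 70/30 partition, per-panel ToD optimisation on the
    training pairs, confidence scoring of the held-out test pairs
    against simulated random tables.

    Reported per iteration: the optimised ToDs, mean known/random test
    scores, recovery fraction at the locally optimal cutoff, fraction of
    test pairs inside the top 4% of their SLC's non-zero predictions,
    and ROC/PR AUC of test vs random scores.
    """
    settings = settings or TrainTestSettings()
    if len(known) < 20:
        raise ValidationError("train_test_cycle: need at least 20 known pairs")
    root = np.random.default_rng(seed)
    datasets = sorted(set(corr["dataset_id"]) & set(base_params.tod))
    records = []
    for it in range(settings.iters):
        it_rng = np.random.default_rng(root.integers(2**31))
        train, test = partition_pairs(known, settings.split, it_rng)
        rand_train = simulate_random_pairs(
            train, universe, n=settings.n_random_tables,
            seed=int(it_rng.integers(2**31)),
        )
        params = base_params
        for ds in datasets:
            kv = _known_panel_values(corr, train, ds)
            if len(kv) < 11:
                continue
            rvs = [_known_panel_values(corr, rt, ds) for rt in rand_train]
            best, _ = optimize_tod(kv, rvs, settings.tod_grid, weight=base_params.weight_a)
            # keep tod_prime consistent with the optimised tod
            tp = min(params.tod_prime.get(ds, 0.0), best)
            params = replace_tod(params, ds, best, tp)
        conf = confidence_scores(corr, dep, adj, train, params)
        conf_keys = dict(
            zip(zip(conf["slc_id"], conf["metabolite_id"]), conf["confidence"])
        )
        test_scores = [
            conf_keys.get((s, m), 0.0)
            for s, m in zip(test["slc_id"], test["target_id"])
        ]
        rand_test = simulate_random_pairs(
            test, universe, n=settings.n_random_tables,
            seed=int(it_rng.integers(2**31)),
        )
        rand_scores_sets = [
            [conf_keys.get((s, m), 0.0) for s, m in zip(rt["slc_id"], rt["target_id"])]
            for rt in rand_test
        ]
        pooled_rand = [v for rs in rand_scores_sets for v in rs]
        roc_auc, pr_auc = roc_pr(test_scores, pooled_rand)
        # locally optimal cutoff: max per-cutoff fractional difference on test
        kf = recovery_curve(test_scores)["fraction"].to_numpy()
        rf = np.mean(
            [recovery_curve(rs)["fraction"].to_numpy() for rs in rand_scores_sets], axis=0
        )
        best_cut = int(CUTOFF_GRID[np.argmax(kf - rf)])
        frac_recovered = float(np.mean(np.asarray(test_scores) > best_cut))
        ranked = rank_predictions(conf)
        top = ranked[ranked["rank_percentile"] <= settings.top_fraction]
        top_keys = set(zip(top["slc_id"], top["metabolite_id"]))
        frac_top = float(
            np.mean([
                (s, m) in top_keys for s, m in zip(test["slc_id"], test["target_id"])
            ])
        )
        records.append({
            "iteration": it,
            "n_train": len(train),
            "n_test": len(test),
            **{f"tod_{ds}": params.tod[ds] for ds in datasets},
            "mean_test_score": float(np.mean(test_scores)),
            "mean_random_score": float(np.mean(pooled_rand)) if pooled_rand else np.nan,
            "best_cutoff": best_cut,
            "frac_recovered": frac_recovered,
            "frac_top": frac_top,
            "roc_auc": roc_auc,
            "pr_auc": pr_auc,
        })
    return pd.DataFrame(records)


def replace_tod(params: ScoreParams, dataset_id: str, tod: float, tod_prime: float) -> ScoreParams:
    new_tod = dict(params.tod)
    new_tp = dict(params.tod_prime)
    new_tod[dataset_id] = tod
    new_tp[dataset_id] = tod_prime
    return ScoreParams(
        tod=new_tod,
        tod_prime=new_tp,
        crispr_p_cutoff=params.crispr_p_cutoff,
        weight_a=params.weight_a,
        weight_b=params.weight_b,
        weight_c=params.weight_c,
        adjacency_radius=params.adjacency_radius,
    )
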