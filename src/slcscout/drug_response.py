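"""Expression-stratified dose-response association.

Cell lines are split into high- and low-expression groups (top and
bottom 20% by the transporter's expression).  Each group's viability
log-fold changes across the 8-dose panel are smoothed with a locally
weighted quadratic regression and evaluated on a dense log10-dose grid;
the two predicted curves are compared with a paired t-test (curve
difference) and the pointwise difference is correlated with dose
(dose-dependent effect).  Drug-specific null thresholds come from
repeatedly comparing two random disjoint 20% groups: a pair is
"predicted" only when both its -log10 p and absolute mean curve
difference exceed the null mean by two null SDs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln

from .data_model import OmicsMatrix, ValidationError

logger = logging.getLogger(__name__)

#: Dense prediction grid in log10 dose (inclusive endpoints).
DOSE_GRID_START = -3.21
DOSE_GRID_END = 1.00
DOSE_GRID_STEP = 0.01
DOSE_GRID = np.round(np.arange(-321, 101), 0) / 100.0
#: Number of grid points of the inclusive grid.
N_GRID_POINTS = 422

#: The 8-dose log10 concentration ladder of the repurposing panel.
PANEL_DOSES = (-3.21, -2.61, -2.01, -1.40, -0.81, -0.20, 0.40, 1.00)

LOESS_SPAN = 0.75
LOESS_DEGREE = 2



@dataclass
class DrugViabilityPanel:
    """Viability log-fold changes per (drug, dose, cell line).

    ``viability`` is a long-format DataFrame with columns
    ``drug_id, dose, sample_id, logfold``; ``drug_meta`` (optional)
    carries per-drug annotation (name, target).
    """

    viability: pd.DataFrame
    drug_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = {"drug_id", "dose", "sample_id", "logfold"} - set(self.viability.columns)
        if missing:
            raise ValidationError(f"viability table missing columns {sorted(missing)}")
        for drug, grp in self.viability.groupby("drug_id"):
            doses = np.sort(grp["dose"].unique())
            if len(doses) < 2:
                raise ValidationError(f"drug {drug!r} has fewer than 2 doses")

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.viability["drug_id"].unique())

    def doses(self, drug_id: str) -> np.ndarray:
        d = self.viability.loc[self.viability["drug_id"] == drug_id, "dose"].unique()
        return np.sort(d)

    def lines_for(self, drug_id: str) -> list[str]:
        sub = self.viability[self.viability["drug_id"] == drug_id]
        return sorted(sub.loc[np.isfinite(sub["logfold"]), "sample_id"].unique())

    def points(self, drug_id: str, sample_ids) -> tuple[np.ndarray, np.ndarray]:
        """All (dose, logfold) observations of a drug over given lines."""
        keep = set(sample_ids)
        sub = self.viability[
            (self.viability["drug_id"] == drug_id)
            & self.viability["sample_id"].isin(keep)
        ]
        sub = sub[np.isfinite(sub["logfold"])]
        return sub["dose"].to_numpy(float), sub["logfold"].to_numpy(float)


def expression_groups(
    expr: OmicsMatrix, slc_id: str, frac: float = 0.2, samples=None
) -> tuple[list[str], list[str]]:
    """Top and bottom expression groups for one transporter.

    Lines are ranked by expression descending, ties broken by sample id
    (stable), and the first/last floor(frac*n) form the high/low groups.
    """
    if slc_id not in expr.values.index:
        raise ValidationError(f"transporter {slc_id!r} absent from expression matrix")
    vals = expr.values.loc[slc_id]
    if samples is not None:
        vals = vals[[s for s in samples if s in vals.index]]
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    if n < 10:
        raise ValidationError(f"expression_groups: only {n} lines (<10)")
    order = sorted(vals.index, key=lambda s: (-vals[s], s))
    k = math.floor(frac * n)
    if 2 * k > n:
        raise ValidationError("expression_groups: groups would overlap")
    return order[:k], order[-k:]


def fit_curve(
    doses: np.ndarray,
    viabilities: np.ndarray,
    grid: np.ndarray = DOSE_GRID,
    span: float = LOESS_SPAN,
    degree: int = LOESS_DEGREE,
) -> np.ndarray:
    """Locally weighted polynomial fit evaluated on the dose grid.

    ``doses``/``viabilities`` are per-observation arrays (all cell lines
    of a group pooled).  At each grid point the span-nearest fraction of
    observations receives tricube weights and a degree-``degree``
    polynomial is fit by weighted least squares; the grid prediction is
    the local intercept.  Observations at repeated doses are aggregated,
    so the cost scales with the number of distinct doses, not points.
    """
    x = np.asarray(doses, float)
    y = np.asarray(viabilities, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    ux = np.unique(x)
    if ux.size < 2:
        raise ValidationError("fit_curve: need at least 2 distinct doses")
    if x.size < 3:
        raise ValidationError("fit_curve: need at least 3 observations")
    if np.all(y == y[0]):
        return np.full(len(grid), y[0])

    # per-unique-dose sufficient statistics
    n_u = np.array([(x == u).sum() for u in ux], float)
    sum_y = np.array([y[x == u].sum() for u in ux])

    k = max(degree + 1, math.ceil(span * x.size))
    k = min(k, x.size)
    grid = np.asarray(grid, float)
    dist = np.abs(grid[:, None] - ux[None, :])  # (G, U)

    # bandwidth per grid point: distance to the k-th nearest observation
    order = np.argsort(dist, axis=1)
    sorted_dist = np.take_along_axis(dist, order, axis=1)
    sorted_n = np.take_along_axis(np.broadcast_to(n_u, dist.shape), order, axis=1)
    cum_n = np.cumsum(sorted_n, axis=1)
    idx = np.argmax(cum_n >= k, axis=1)
    h = sorted_dist[np.arange(len(grid)), idx]
    h = np.maximum(h, 1e-12)

    w = np.clip(1.0 - (dist / h[:, None]) ** 3, 0.0, None) ** 3  # (G, U)
    # keep at least the nearest dose in-weight
    nearest = order[:, 0]
    w[np.arange(len(grid)), nearest] = np.maximum(
        w[np.arange(len(grid)), nearest], 1e-6
    )

    # local basis centred at each grid point: prediction = intercept
    p = degree + 1
    xs = ux[None, :] - grid[:, None]  # (G, U)
    powers = np.stack([xs**j for j in range(p)], axis=-1)  # (G, U, p)
    A = np.einsum("gu,gup,guq,u->gpq", w, powers, powers, n_u)
    b = np.einsum("gu,gup,gu->gp", w, powers, np.broadcast_to(sum_y, xs.shape))
    # ridge jitter guards rank deficiency when few doses fall in the window
    A = A + 1e-10 * np.eye(p)[None, :, :]
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    return coef[:, 0]


@dataclass
class CurveComparison:
    p: float
    mean_diff: float
    neg_log10_p: float = np.nan
    degenerate: bool = False


def compare_curves(pred_high: np.ndarray, pred_low: np.ndarray) -> CurveComparison:
    """Paired two-sided t-test across grid points of the two curves.

    The smoothed curves are nearly noise-free, so the paired t statistic
    can be enormous and its p-value underflows double precision; the
    -log10 p used downstream is therefore computed in log space and
    stays finite.
    """
    high = np.asarray(pred_high, float)
    low = np.asarray(pred_low, float)
    if high.shape != low.shape:
        raise ValidationError("compare_curves: grids differ")
    diff = high - low
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        return CurveComparison(np.nan, mean_diff, degenerate=True)
    n = diff.size
    t = mean_diff / (sd / math.sqrt(n))
    log_p = math.log(2.0) + _log_t_sf(abs(t), n - 1)
    neg_log10_p = -log_p / math.log(10.0)
    p = math.exp(log_p) if log_p > -700 else 0.0
    return CurveComparison(p, mean_diff, neg_log10_p)


def _log_t_sf(t: float, df: int) -> float:
    """log of the Student-t upper tail, exact in log space.

    Uses sf(t) = I_x(df/2, 1/2)/2 with x = df/(df+t^2) and the
    hypergeometric series of the regularized incomplete beta, so it does
    not underflow where scipy's logsf returns -inf.
    """
    if t <= 0:
        return math.log(float(stats.t.sf(t, df)))
    a, b = df / 2.0, 0.5
    x = df / (df + t * t)
    term, s, n = 1.0, 1.0, 1
    while True:
        term *= (a + b + n - 1) / (a + n) * x
        s += term
        if term < 1e-17 * s or n > 100000:
            break
        n += 1
    return (
        math.log(0.5) + a * math.log(x) + b * math.log1p(-x)
        - math.log(a) - betaln(a, b) + math.log(s)
    )


@dataclass
class DoseEffect:
    rho: float
    abs_rho: float
    p: float
    degenerate: bool = False


def dose_effect(pred_high, pred_low, grid=DOSE_GRID) -> DoseEffect:
    """Spearman correlation of the curve difference with dose."""
    diff = np.asarray(pred_high, float) - np.asarray(pred_low, float)
    if np.all(diff == diff[0]):
        return DoseEffect(np.nan, np.nan, np.nan, degenerate=True)
    rho, p = stats.spearmanr(diff, np.asarray(grid, float)[: len(diff)])
    return DoseEffect(float(rho), abs(float(rho)), float(p))


@dataclass
class NullThresholds:
    mean_logp: float
    sd_logp: float
    mean_absdiff: float
    sd_absdiff: float
    n_used: int


def null_thresholds(
    panel: DrugViabilityPanel,
    drug_id: str,
    n_iter: int = 100,
    frac: float = 0.2,
    seed: int = 0,
    grid: np.ndarray = DOSE_GRID,
) -> NullThresholds:
    """Drug-specific null expectation from random group contrasts.

    Each iteration draws two disjoint random groups of floor(frac * n)
    treated lines, fits both curves and records -log10 p and |mean
    difference|.  Degenerate iterations are dropped (more than half
    degenerate raises).
    """
    lines = panel.lines_for(drug_id)
    n = len(lines)
    k = math.floor(frac * n)
    if k < 2 or 2 * k > n:
        raise ValidationError(
            f"null_thresholds: cannot draw two disjoint groups of {k} from {n} lines"
        )
    rng = np.random.default_rng(seed)
    logps, absdiffs = [], []
    n_degenerate = 0
    for _ in range(n_iter):
        perm = rng.permutation(n)
        g1 = [lines[i] for i in perm[:k]]
        g2 = [lines[i] for i in perm[k : 2 * k]]
        d1, v1 = panel.points(drug_id, g1)
        d2, v2 = panel.points(drug_id, g2)
        try:
            c1 = fit_curve(d1, v1, grid)
            c2 = fit_curve(d2, v2, grid)
        except ValidationError:
            n_degenerate += 1
            continue
        cmpres = compare_curves(c1, c2)
        if cmpres.degenerate or not np.isfinite(cmpres.neg_log10_p):
            n_degenerate += 1
            continue
        logps.append(cmpres.neg_log10_p)
        absdiffs.append(abs(cmpres.mean_diff))
    if n_degenerate:
        logger.info("null_thresholds[%s]: %d/%d degenerate iterations dropped",
                    drug_id, n_degenerate, n_iter)
    if n_degenerate > n_iter / 2:
        raise ValidationError(
            f"null_thresholds[{drug_id}]: more than half the iterations degenerate"
        )
    return NullThresholds(
        float(np.mean(logps)), float(np.std(logps, ddof=1)),
        float(np.mean(absdiffs)), float(np.std(absdiffs, ddof=1)),
        len(logps),
    )


DRUG_ASSOCIATION_COLUMNS = [
    "slc_id", "drug_id", "p", "mean_diff", "abs_mean_diff", "dose_rho",
    "dose_p", "null_mean_logp", "null_sd_logp", "null_mean_absdiff",
    "null_sd_absdiff", "predicted", "direction",
]


def predict_drug_interactions(
    expr: OmicsMatrix,
    panel: DrugViabilityPanel,
    slc_ids,
    frac: float = 0.2,
    n_iter: int = 100,
    seed: int = 0,
    top_n: int = 50,
    grid: np.ndarray = DOSE_GRID,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-(SLC, drug) association table plus a ranked shortlist.

    A pair is predicted when both -log10 p and |mean difference| exceed
    the drug's null mean by two null SDs.  ``direction`` is sensitising
    when high expression lowers viability (negative mean difference).
    The shortlist ranks predicted pairs by the sum of descending ranks
    of |mean difference| and |dose rho|, truncated to ``top_n``.
    """
    rows = []
    rng = np.random.default_rng(seed)
    null_cache: dict[str, NullThresholds] = {}
    for drug in panel.drug_ids:
        null_cache[drug] = null_thresholds(
            panel, drug, n_iter=n_iter, frac=frac, seed=int(rng.integers(2**31)), grid=grid
        )
    for slc in slc_ids:
        for drug in panel.drug_ids:
            lines = panel.lines_for(drug)
            try:
                high, low = expression_groups(expr, slc, frac, samples=lines)
            except ValidationError:
                continue
            dh, vh = panel.points(drug, high)
            dl, vl = panel.points(drug, low)
            try:
                ch = fit_curve(dh, vh, grid)
                cl = fit_curve(dl, vl, grid)
            except ValidationError:
                continue
            comp = compare_curves(ch, cl)
            de = dose_effect(ch, cl, grid)
            nt = null_cache[drug]
            logp = comp.neg_log10_p
            predicted = bool(
                np.isfinite(logp)
                and logp > nt.mean_logp + 2 * nt.sd_logp
                and abs(comp.mean_diff) > nt.mean_absdiff + 2 * nt.sd_absdiff
            )
            rows.append({
                "slc_id": slc, "drug_id": drug,
                "p": comp.p, "mean_diff": comp.mean_diff,
                "abs_mean_diff": abs(comp.mean_diff),
                "dose_rho": de.rho, "dose_p": de.p,
                "null_mean_logp": nt.mean_logp, "null_sd_logp": nt.sd_logp,
                "null_mean_absdiff": nt.mean_absdiff, "null_sd_absdiff": nt.sd_absdiff,
                "predicted": predicted,
                "direction": "sensitising" if comp.mean_diff < 0 else "attenuating",
            })
    table = pd.DataFrame(rows, columns=DRUG_ASSOCIATION_COLUMNS)
    shortlist = table[table["predicted"]].copy()
    if not shortlist.empty:
        r1 = shortlist["abs_mean_diff"].rank(ascending=False)
        r2 = shortlist["dose_rho"].abs().rank(ascending=False)
        shortlist["rank_sum"] = r1 + r2
        shortlist = shortlist.sort_values(
            ["rank_sum", "slc_id", "drug_id"]
        ).head(top_n).reset_index(drop=True)
    return table, shortlist
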