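"""The confidence score.

Each (SLC, metabolite) pair earns an integer sub-score of 0-11 per cell
panel by placing its transformed rho inside the decile intervals of the
known-pair distribution for that panel: values below the panel's
Threshold of Discovery (ToD) score 0; values at or above the top known
decile are capped at 11.  A gene-dependency sub-score does the same on
-log10 of the BH-adjusted Wilcoxon p (only when the adjusted p clears
the CRISPR cutoff), and an adjacency score sums piecewise sub-scores of
the transporter's correlations to metabolites within a small conversion
radius of the candidate substrate, with a half-point band between the
adjacency threshold ToD' and ToD.  The total is

    Confidence = a * (sum of panel sub-scores) + b * GeneDep + c * Adjacency
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adjacency import AdjacencyMatrix, neighbors_within
from .data_model import ValidationError

logger = logging.getLogger(__name__)

#: Canonical panel identifiers used by the default parameterisation.
DEFAULT_DATASETS = ("NCI60", "CCLE2019", "CCL180")


@dataclass
class ScoreParams:
    """Tunable parameters of the confidence score.

    ``tod`` maps each panel to its Threshold of Discovery on the
    transformed-rho scale (0.0 = at the metabolite's mean |rho|,
    1.0 = one SD above it); ``tod_prime`` holds the lower adjacency
    thresholds.  ``crispr_p_cutoff`` gates the gene-dependency
    sub-score on adjusted p.  ``weight_a``/``weight_b``/``weight_c``
    weight the panel, gene-dependency and adjacency components;
    ``adjacency_radius`` is the conversion-step radius for neighbours.
    """

    tod: dict[str, float] = field(
        default_factory=lambda: {"NCI60": 0.0, "CCLE2019": 0.0, "CCL180": 1.0}
    )
    tod_prime: dict[str, float] = field(
        default_factory=lambda: {"NCI60": 0.1, "CCLE2019": 0.1, "CCL180": 0.2}
    )
    crispr_p_cutoff: float = 0.16
    weight_a: float = 3.0
    weight_b: float = 1.0
    weight_c: float = 1.0
    adjacency_radius: int = 2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.crispr_p_cutoff <= 1:
            raise ValidationError("crispr_p_cutoff must be in (0, 1]")
        if min(self.weight_a, self.weight_b, self.weight_c) < 0:
            raise ValidationError("weights must be non-negative")
        if self.adjacency_radius < 1:
            raise ValidationError("adjacency_radius must be a positive integer")
        # ToD' may sit above ToD (the published NCI60/CCLE2019 defaults do):
        # the half-point band is then empty and ToD' acts as the hard floor.

    def with_tod(self, dataset_id: str, value: float) -> "ScoreParams":
        tod = dict(self.tod)
        tod[dataset_id] = value
        return replace(self, tod=tod)


def default_params() -> ScoreParams:
    """The published default parameterisation (three panels, a=3, b=c=1)."""
    return ScoreParams()


def known_quantiles(known_values, tod: float) -> np.ndarray:
    """Decile knots of the known-pair value distribution.

    Eleven quantiles from the 0th to the 100th percentile (linear
    interpolation between order statistics) of the known values at or
    above the Threshold of Discovery, with the 0th knot replaced by the
    ToD itself.  Restricting to discoverable known values keeps the
    array monotone for any ToD inside the known distribution (the
    published CCL180 threshold sits one SD above the mean, well inside
    it).  Requires at least 11 finite values at or above the ToD.
    """
    vals = np.asarray(list(known_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    eligible = vals[vals >= tod]
    if eligible.size < 11:
        raise ValidationError(
            f"known_quantiles: need >=11 finite known values at or above "
            f"ToD {tod}, got {eligible.size}"
        )
    q = np.quantile(eligible, np.linspace(0.0, 1.0, 11))
    q[0] = tod
    if np.any(np.diff(q) < 0):
        raise ValidationError(
            f"known_quantiles: ToD {tod} makes the quantile array non-monotone"
        )
    return q


def subscore(v: float, tod: float, q: np.ndarray) -> int:
    """Decile interval index of ``v`` in the known distribution.

    0 below ToD; j when q[j-1] <= v < q[j] (1-based); capped at 11 at or
    above the top knot.  Missing values contribute 0.
    """
    if v is None or not np.isfinite(v):
        return 0
    if v < tod:
        return 0
    if v >= q[10]:
        return 11
    j = int(np.searchsorted(q, v, side="right"))
    return max(j, 1)


def adjacency_subscore(v: float, tod: float, tod_prime: float, q: np.ndarray) -> float:
    """Piecewise neighbour sub-score.

    0 below ToD'; the decile interval index above ToD; a half point in
    the (ToD', ToD] band between them.  When ToD' sits above ToD the
    band is empty and ToD' is simply the hard floor before the index
    branch applies.
    """
    if v is None or not np.isfinite(v) or v <= tod_prime:
        return 0.0
    if v > tod:
        return float(subscore(v, tod, q))
    return 0.5


@dataclass
class KnownDistributions:
    """Per-source quantile knots derived from the known pairs."""

    panel_q: dict[str, np.ndarray]
    gene_dep_q: np.ndarray | None = None


def build_known_distributions(
    corr: pd.DataFrame,
    known: pd.DataFrame,
    params: ScoreParams,
    dep: pd.DataFrame | None = None,
) -> KnownDistributions:
    """Quantile arrays for every panel (on transformed rho) and, when a
    dependency table is given, for -log10 adjusted p of the known pairs."""
    known_keys = set(zip(known["slc_id"], known["target_id"]))
    panel_q: dict[str, np.ndarray] = {}
    for ds in sorted(set(corr["dataset_id"]) & set(params.tod)):
        sub = corr[corr["dataset_id"] == ds]
        mask = [
            (s, m) in known_keys
            for s, m in zip(sub["slc_id"], sub["metabolite_id"])
        ]
        vals = sub.loc[mask, "rho_transformed"].dropna()
        if vals.empty:
            raise ValidationError(f"no known-pair values in dataset {ds!r}")
        panel_q[ds] = known_quantiles(vals, params.tod[ds])
    gene_dep_q = None
    if dep is not None and not dep.empty:
        mask = [
            (s, m) in known_keys
            for s, m in zip(dep["slc_id"], dep["metabolite_id"])
        ]
        padj = dep.loc[mask, "p_adj"].dropna()
        padj = padj[padj > 0]
        if not padj.empty:
            logp = -np.log10(padj)
            try:
                gene_dep_q = known_quantiles(logp, -math.log10(params.crispr_p_cutoff))
            except ValidationError:
                # no known pair clears the CRISPR cutoff: the decile scale
                # is undefined and every candidate is gated to 0 anyway
                logger.warning(
                    "gene-dependency decile scale undefined at cutoff %g; "
                    "sub-score disabled", params.crispr_p_cutoff,
                )
                gene_dep_q = None
    return KnownDistributions(panel_q, gene_dep_q)


def gene_dep_subscore(
    p_adj: float, params: ScoreParams, q: np.ndarray | None
) -> int:
    """Sub-score of the dependency contrast: decile index of -log10(p_adj)
    among known pairs, but only when p_adj clears the CRISPR cutoff."""
    if q is None or p_adj is None or not np.isfinite(p_adj):
        return 0
    if p_adj >= params.crispr_p_cutoff or p_adj <= 0:
        return 0
    return subscore(-math.log10(p_adj), -math.log10(params.crispr_p_cutoff), q)


def confidence_scores(
    corr: pd.DataFrame,
    dep: pd.DataFrame | None,
    adj: AdjacencyMatrix | None,
    known: pd.DataFrame,
    params: ScoreParams,
    pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Confidence score for every (SLC, metabolite) pair.

    ``corr`` must carry ``rho_transformed`` for every panel in
    ``params.tod``; ``dep`` (optional) the BH-adjusted dependency p;
    ``adj`` (optional) the conversion-distance matrix.  ``pairs``
    restricts scoring to given (slc_id, metabolite_id) rows; by default
    every pair appearing in ``corr`` is scored.  Missing inputs
    contribute 0 to the total.
    """
    params.validate()
    datasets = sorted(set(corr["dataset_id"]) & set(params.tod))
    if not datasets:
        raise ValidationError("correlation table shares no dataset with params.tod")
    dists = build_known_distributions(corr, known, params, dep)

    # (slc, met, dataset) -> rho_transformed lookup
    rho_t: dict[str, dict[tuple[str, str], float]] = {}
    for ds in datasets:
        sub = corr[corr["dataset_id"] == ds]
        rho_t[ds] = {
            (s, m): v
            for s, m, v in zip(sub["slc_id"], sub["metabolite_id"], sub["rho_transformed"])
            if np.isfinite(v)
        }
    dep_p: dict[tuple[str, str], float] = {}
    if dep is not None and not dep.empty:
        dep_p = {
            (s, m): v
            for s, m, v in zip(dep["slc_id"], dep["metabolite_id"], dep["p_adj"])
            if np.isfinite(v)
        }

    if pairs is None:
        pair_list = sorted(
            {(s, m) for ds in datasets for (s, m) in rho_t[ds]}
        )
    else:
        pair_list = list(zip(pairs["slc_id"].astype(str), pairs["metabolite_id"].astype(str)))

    neighbor_cache: dict[str, set[str]] = {}
    rows = []
    for slc, met in pair_list:
        row: dict[str, object] = {"slc_id": slc, "metabolite_id": met}
        panel_sum = 0
        for ds in datasets:
            v = rho_t[ds].get((slc, met), np.nan)
            s = subscore(v, params.tod[ds], dists.panel_q[ds])
            row[f"sub_{ds}"] = s
            panel_sum += s
        gdep = gene_dep_subscore(dep_p.get((slc, met), np.nan), params, dists.gene_dep_q)
        row["gene_dep_subscore"] = gdep
        adjacency_score = 0.0
        if adj is not None and met in adj:
            if met not in neighbor_cache:
                neighbor_cache[met] = neighbors_within(adj, met, params.adjacency_radius)
            for ds in datasets:
                tp = params.tod_prime.get(ds, params.tod[ds])
                for nb in neighbor_cache[met]:
                    v = rho_t[ds].get((slc, nb))
                    if v is None:
                        continue  # neighbour not measured in this panel
                    adjacency_score += adjacency_subscore(
                        v, params.tod[ds], tp, dists.panel_q[ds]
                    )
        row["adjacency_score"] = adjacency_score
        row["confidence"] = (
            params.weight_a * panel_sum
            + params.weight_b * gdep
            + params.weight_c * adjacency_score
        )
        rows.append(row)
    cols = (
        ["slc_id", "metabolite_id"]
        + [f"sub_{ds}" for ds in datasets]
        + ["gene_dep_subscore", "adjacency_score", "confidence"]
    )
    return pd.DataFrame(rows, columns=cols)
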