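"""Seeded generator of synthetic multi-omics panels.

The generator emulates the statistical structure the prediction method
relies on, so every stage can be exercised end to end without any
external download: count matrices with library-size variation (making
median-ratio normalisation non-trivial), three partially overlapping
metabolite panels in which each planted (transporter, substrate) pair
carries a monotone expression-metabolite dependence at a target
Spearman |rho|, derivative metabolites whose dependence decays per
conversion step along a known reaction graph, CRISPR gene-effect scores
coupled to the planted substrates, tissue structure, pathway membership
and a dose-response drug panel with expression-dependent viability
shifts for planted (transporter, drug) pairs.

The planted dependence is a rank-preserving linear mix of the
transporter's latent expression and Gaussian noise; the mixing weight
for a target Spearman rho is found by bisection through the bivariate
Gaussian identity rho_s = (6/pi) * arcsin(r/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import OmicsMatrix, ValidationError, make_known_pairs, validate_pathways
from .drug_response import PANEL_DOSES, DrugViabilityPanel

DATASET_IDS = ("NCI60", "CCLE2019", "CCL180")


@dataclass
class SynthConfig:
    """Conditions of the synthetic study.

    Defaults follow the panel-recovery setting the test-suite exercises:
    200 cell lines, 12 planted substrate pairs at target Spearman
    |rho| = 0.6, 50 background metabolites, correlation decaying by 0.6
    per conversion step along the reaction graph.
    """

    n_cell_lines: int = 200
    n_tissues: int = 4
    n_slcs: int = 30
    n_background_metabolites: int = 50
    n_planted_pairs: int = 12
    derivative_branches: int = 2
    derivative_depth: int = 2
    target_abs_rho: float = 0.6
    derivative_decay: float = 0.6
    expression_log_sd: float = 0.8
    base_count_log_mean: float = 6.0
    base_count_log_sd: float = 1.0
    library_size_range: tuple[float, float] = (0.25, 4.0)
    dataset_line_fraction: float = 0.8
    tissue_weight: float = 0.15
    n_drugs: int = 6
    planted_drug_pairs: int = 2
    drug_shift: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    @property
    def n_derivatives_per_substrate(self) -> int:
        return self.derivative_branches * self.derivative_depth

    @property
    def n_metabolites(self) -> int:
        return (
            self.n_planted_pairs * (1 + self.n_derivatives_per_substrate)
            + self.n_background_metabolites
        )

    def validate(self) -> None:
        if not 0 < self.target_abs_rho < 1:
            raise ValidationError("target_abs_rho must be in (0, 1)")
        if not 0 < self.derivative_decay <= 1:
            raise ValidationError("derivative_decay must be in (0, 1]")
        if self.n_planted_pairs > self.n_slcs:
            raise ValidationError("more planted pairs than transporters")
        if self.planted_drug_pairs > min(self.n_drugs, self.n_planted_pairs):
            raise ValidationError("more planted drug pairs than drugs/transporters")
        if self.n_cell_lines < 20:
            raise ValidationError("need at least 20 cell lines")


def mixing_for_spearman(target: float, tol: float = 1e-10) -> float:
    """Mixing weight whose bivariate-Gaussian Spearman rho equals target.

    Bisection on a in rho_s(a) = (6/pi) * asin(a/2); monotone on [0, 1].
    Used as the starting point for the per-pair realized calibration.
    """
    if not 0 <= target < 1:
        raise ValidationError(f"unattainable target Spearman rho {target}")
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if (6 / math.pi) * math.asin(mid / 2) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _fast_abs_spearman(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    return abs(float(np.corrcoef(rx, ry)[0, 1]))


def _calibrate_noise_scale(
    z: np.ndarray, noise: np.ndarray, target: float, tol: float = 0.01
) -> float:
    """Noise scale s such that |spearman(z, z + s*noise)| hits the target.

    The realized rank correlation is (essentially) monotone decreasing in
    the scale of the admixed noise, so bisection on s converges on the
    drawn noise vector itself; the planted pair then carries the target
    correlation exactly as realized, not merely in expectation.
    """
    def realized(s: float) -> float:
        return _fast_abs_spearman(z, z + s * noise)

    hi = 1.0
    while realized(hi) > target:
        hi *= 2.0
        if hi > 1e6:
            raise ValidationError(
                f"unattainable target Spearman rho {target}: noise cannot "
                "dilute the planted signal (is the noise collinear with it?)"
            )
    lo = 0.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if realized(mid) > target:
            lo = mid
        else:
            hi = mid
    s = (lo + hi) / 2.0
    if abs(realized(s) - target) > 5 * tol:
        raise ValidationError(
            f"calibration failed: realized rho {realized(s):.3f} vs target {target}"
        )
    return s


@dataclass
class SyntheticPanel:
    """Everything :func:`synth_panel` produces, plus the planted truth."""

    counts: OmicsMatrix
    metabolites: dict[str, OmicsMatrix]
    tissue_map: dict[str, str]
    known_pairs: pd.DataFrame
    reaction_graph: nx.Graph
    gene_effect: OmicsMatrix
    pathways: pd.DataFrame
    planted: pd.DataFrame = field(default_factory=pd.DataFrame)
    latent_expression: pd.DataFrame | None = None
    config: SynthConfig | None = None


def _metabolite_values(
    z: np.ndarray, rho_target: float, tissue_idx: np.ndarray,
    n_tissues: int, tissue_weight: float, rng: np.random.Generator,
) -> np.ndarray:
    """One metabolite row: planted signal + tissue offsets + iid noise.

    The noise (tissue offset plus iid, unit total variance) is drawn
    once; its admixture scale is then bisected so the *realized*
    |Spearman rho| between the latent expression and the row equals the
    target.  Rows with target 0 are pure noise.
    """
    offsets = rng.normal(size=n_tissues)
    noise = (
        math.sqrt(tissue_weight) * offsets[tissue_idx]
        + math.sqrt(1 - tissue_weight) * rng.normal(size=z.size)
    )
    if rho_target <= 0:
        return noise
    # de-correlate the noise from the signal so heavy dilution can reach
    # arbitrarily small realized correlations even at finite n
    zc = z - z.mean()
    nc = noise - noise.mean()
    nc = nc - (zc @ nc) / (zc @ zc) * zc
    s = _calibrate_noise_scale(z, nc, rho_target)
    vals = z + s * nc
    return vals / vals.std(ddof=0)


def synth_panel(config: SynthConfig | None = None) -> SyntheticPanel:
    """Generate the full multi-omics panel set. Deterministic under seed."""
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    lines = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    tissues = [f"tissue_{i}" for i in range(config.n_tissues)]
    tissue_idx = np.arange(config.n_cell_lines) % config.n_tissues
    tissue_map = {s: tissues[t] for s, t in zip(lines, tissue_idx)}
    slcs = [f"SLC{i:03d}" for i in range(config.n_slcs)]

    # latent per-gene expression z-scores drive counts and planted metabolites
    z = rng.normal(size=(config.n_slcs, config.n_cell_lines))
    base = np.exp(rng.normal(config.base_count_log_mean, config.base_count_log_sd,
                             size=config.n_slcs))
    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(math.log(lo), math.log(hi), size=config.n_cell_lines))
    mu = base[:, None] * np.exp(config.expression_log_sd * z) * lib[None, :]
    counts = OmicsMatrix(
        pd.DataFrame(rng.poisson(mu).astype(float), index=slcs, columns=lines),
        "counts",
        dict(tissue_map),
    )

    # metabolite naming: substrates, derivatives, background
    substrates = [f"MET_S{i:02d}" for i in range(config.n_planted_pairs)]
    background = [f"MET_B{i:02d}" for i in range(config.n_background_metabolites)]
    deriv_names: dict[str, list[tuple[str, int]]] = {}
    graph = nx.Graph()
    graph.add_nodes_from(substrates + background)
    for i, sub in enumerate(substrates):
        chain_nodes = []
        for b in range(config.derivative_branches):
            prev = sub
            for d in range(1, config.derivative_depth + 1):
                node = f"MET_D{i:02d}_{b}{d}"
                graph.add_edge(prev, node)
                chain_nodes.append((node, d))
                prev = node
        deriv_names[sub] = chain_nodes
    # sparse background chemistry far from the planted trees
    n_bg_edges = max(len(background) // 2, 1)
    for _ in range(n_bg_edges):
        a, b = rng.choice(len(background), size=2, replace=False)
        if background[a] != background[b]:
            graph.add_edge(background[a], background[b])

    metabolite_ids = (
        substrates
        + [n for sub in substrates for n, _ in deriv_names[sub]]
        + background
    )

    planted_rows = []
    datasets: dict[str, OmicsMatrix] = {}
    ds_lines: dict[str, list[str]] = {}
    n_sub = math.floor(config.dataset_line_fraction * config.n_cell_lines)
    for ds in DATASET_IDS:
        idx = np.sort(rng.choice(config.n_cell_lines, size=n_sub, replace=False))
        ds_lines[ds] = [lines[i] for i in idx]
        vals = np.empty((len(metabolite_ids), n_sub))
        row = 0
        for i, sub in enumerate(substrates):
            vals[row] = _metabolite_values(
                z[i, idx], config.target_abs_rho, tissue_idx[idx],
                config.n_tissues, config.tissue_weight, rng,
            )
            row += 1
        for i, sub in enumerate(substrates):
            for node, depth in deriv_names[sub]:
                rho_d = config.target_abs_rho * config.derivative_decay**depth
                vals[row] = _metabolite_values(
                    z[i, idx], rho_d, tissue_idx[idx],
                    config.n_tissues, config.tissue_weight, rng,
                )
                row += 1
        for _ in background:
            vals[row] = _metabolite_values(
                z[0, idx] * 0.0, 0.0, tissue_idx[idx],
                config.n_tissues, config.tissue_weight, rng,
            )
            row += 1
        # keep row order: substrates, then all derivatives, then background
        order = (
            substrates
            + [n for sub in substrates for n, _ in deriv_names[sub]]
            + background
        )
        df = pd.DataFrame(vals, index=order, columns=ds_lines[ds])
        ann = {s: tissue_map[s] for s in ds_lines[ds]}
        datasets[ds] = OmicsMatrix(df, "metabolite_level", ann)

    for i, sub in enumerate(substrates):
        planted_rows.append({
            "slc_id": slcs[i], "metabolite_id": sub,
            "target_rho": config.target_abs_rho,
        })
    planted = pd.DataFrame(planted_rows)
    known = make_known_pairs(list(zip(planted["slc_id"], planted["metabolite_id"])))

    # gene effect: planted transporters are essential in proportion to the
    # latent expression (hence substrate level) of each line
    effect = rng.normal(-0.3, 0.3, size=(config.n_slcs, config.n_cell_lines))
    for i in range(config.n_planted_pairs):
        effect[i] = -0.5 - 0.4 * z[i] + 0.15 * rng.normal(size=config.n_cell_lines)
    gene_effect = OmicsMatrix(
        pd.DataFrame(effect, index=slcs, columns=lines), "gene_effect",
        dict(tissue_map),
    )

    # pathways: one per planted substrate (substrate + derivatives),
    # background metabolites grouped in blocks
    pw_rows = []
    for i, sub in enumerate(substrates):
        pw = f"PW_S{i:02d}"
        pw_rows.append({"pathway_id": pw, "metabolite_id": sub})
        for node, _ in deriv_names[sub]:
            pw_rows.append({"pathway_id": pw, "metabolite_id": node})
    for j in range(0, len(background), 10):
        pw = f"PW_B{j // 10:02d}"
        for met in background[j : j + 10]:
            pw_rows.append({"pathway_id": pw, "metabolite_id": met})
    pathways = validate_pathways(pd.DataFrame(pw_rows))

    latent = pd.DataFrame(z, index=slcs, columns=lines)
    return SyntheticPanel(
        counts=counts,
        metabolites=datasets,
        tissue_map=tissue_map,
        known_pairs=known,
        reaction_graph=graph,
        gene_effect=gene_effect,
        pathways=pathways,
        planted=planted,
        latent_expression=latent,
        config=config,
    )


def synth_drug_panel(
    config: SynthConfig, expr: OmicsMatrix, panel: SyntheticPanel | None = None
) -> tuple[DrugViabilityPanel, pd.DataFrame]:
    """Dose-response viability panel with planted expression-linked shifts.

    Viability log-fold follows a logistic kill curve in log10 dose plus
    Gaussian noise.  For each planted (transporter, drug) pair the curve
    receives an additive vertical shift of ``-drug_shift`` in lines with
    high transporter expression (a steep sigmoid of the expression
    z-score), so high-expression lines are sensitised when
    ``drug_shift > 0``.  Returns the panel and the planted truth table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    doses = np.array(PANEL_DOSES)
    lines = expr.sample_ids
    drugs = [f"DRUG{i:02d}" for i in range(config.n_drugs)]

    # standardised expression of each potentially planted transporter
    slc_ids = list(expr.values.index[: config.planted_drug_pairs])
    expr_z = {}
    for slc in slc_ids:
        v = expr.values.loc[slc].to_numpy(float)
        lv = np.log(v + 1.0)
        expr_z[slc] = (lv - lv.mean()) / lv.std(ddof=0)

    max_kill, hill, ec50 = -2.5, 2.2, -1.0
    base = max_kill / (1.0 + np.exp(-hill * (doses - ec50)))  # (8,)

    planted_rows = []
    records = []
    for j, drug in enumerate(drugs):
        shift = np.zeros(len(lines))
        if j < config.planted_drug_pairs:
            slc = slc_ids[j]
            gate = 1.0 / (1.0 + np.exp(-8.0 * expr_z[slc]))
            shift = -config.drug_shift * gate
            planted_rows.append({
                "slc_id": slc, "drug_id": drug, "delta": config.drug_shift,
            })
        noise = rng.normal(0.0, config.noise_sd, size=(len(lines), len(doses)))
        lf = base[None, :] + shift[:, None] + noise
        for li, line in enumerate(lines):
            for di, dose in enumerate(doses):
                records.append((drug, float(dose), line, float(lf[li, di])))
    viability = pd.DataFrame(
        records, columns=["drug_id", "dose", "sample_id", "logfold"]
    )
    meta = pd.DataFrame({"drug_id": drugs, "name": drugs, "target": ""})
    return DrugViabilityPanel(viability, meta), pd.DataFrame(
        planted_rows, columns=["slc_id", "drug_id", "delta"]
    )
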