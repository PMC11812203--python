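"""A compact, fully worked scoring example.

Builds the smallest input set on which every component of the
confidence score is exercised with hand-checkable numbers: eleven
reference (known) transporter-substrate pairs whose transformed-rho
values form the decile knots in each panel, one example pair
(SLC35B1 - glutamate) whose panel values fall below, inside and above
the thresholds, a dependency contrast with a strongly significant
adjusted p, and a ten-neighbour conversion neighbourhood around
glutamate.  With the default parameters the example pair earns a
cell-panel score of 18, a gene-dependency sub-score of 8 (total 26),
an adjacency score of 46.5 and a final confidence of 72.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .adjacency import AdjacencyMatrix, conversion_distances
from .data_model import make_known_pairs, make_reaction_graph
from .scoring import ScoreParams, confidence_scores, default_params

EXAMPLE_SLC = "SLC35B1"
EXAMPLE_METABOLITE = "glutamate"

#: Transformed-rho decile knots of the reference pairs per panel.
PANEL_KNOTS = {
    "NCI60": [0.0, 0.2, 0.4, 0.6, 0.8, 0.95, 1.0, 1.2, 1.4, 1.6, 1.8],
    "CCLE2019": [0.0, 0.2, 0.4, 0.6, 0.8, 0.95, 1.0, 1.2, 1.4, 1.6, 1.8],
    "CCL180": [1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9, 2.0],
}
#: -log10 adjusted-p knots of the reference pairs for the dependency source.
GENE_DEP_KNOTS = [0.8, 1.2, 1.6, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 6.0]

#: The example pair's transformed rho per panel and its dependency p.
EXAMPLE_RHO_T = {"NCI60": -0.97, "CCLE2019": 0.96, "CCL180": 0.019}
EXAMPLE_DEP_P_ADJ = 9.7e-5

#: Transformed rho of the example transporter against each glutamate
#: neighbour, per panel (None = not measured in that panel).
NEIGHBOR_RHO_T = {
    "NCI60": {"N01": 1.5, "N02": 1.5, "N03": 0.05, "N04": 0.05, "N05": 0.05,
              "N06": 0.05, "N07": 0.05, "N08": 0.05, "N09": 0.05, "N10": 0.05},
    "CCLE2019": {"N01": 0.05, "N02": 0.05, "N03": 1.5, "N04": 1.5, "N05": 0.05,
                 "N06": 0.05, "N07": 0.05, "N08": 0.05, "N09": 0.05, "N10": 0.05},
    "CCL180": {"N01": 0.05, "N02": 0.05, "N03": 0.05, "N04": 0.05,
               "N05": 0.5, "N06": 1.95},
}


@dataclass
class DemoInputs:
    correlations: pd.DataFrame
    dependency: pd.DataFrame
    adjacency: AdjacencyMatrix
    known_pairs: pd.DataFrame
    params: ScoreParams


def demo_inputs() -> DemoInputs:
    """Assemble the worked-example input tables."""
    ref_slcs = [f"REF_SLC{i:02d}" for i in range(11)]
    ref_mets = [f"REF_MET{i:02d}" for i in range(11)]
    known = make_known_pairs(list(zip(ref_slcs, ref_mets)))

    corr_rows = []
    for ds, knots in PANEL_KNOTS.items():
        for slc, met, value in zip(ref_slcs, ref_mets, knots):
            corr_rows.append(_corr_row(slc, met, ds, value))
        corr_rows.append(
            _corr_row(EXAMPLE_SLC, EXAMPLE_METABOLITE, ds, EXAMPLE_RHO_T[ds])
        )
        for nb, value in NEIGHBOR_RHO_T[ds].items():
            corr_rows.append(_corr_row(EXAMPLE_SLC, nb, ds, value))
    corr = pd.DataFrame(corr_rows)

    dep_rows = [
        {"slc_id": slc, "metabolite_id": met, "n_top": 20, "n_bottom": 20,
         "p": 10.0 ** (-logp) / 2, "p_adj": 10.0 ** (-logp), "direction": 1}
        for slc, met, logp in zip(ref_slcs, ref_mets, GENE_DEP_KNOTS)
    ]
    dep_rows.append({
        "slc_id": EXAMPLE_SLC, "metabolite_id": EXAMPLE_METABOLITE,
        "n_top": 20, "n_bottom": 20,
        "p": EXAMPLE_DEP_P_ADJ / 2, "p_adj": EXAMPLE_DEP_P_ADJ, "direction": 1,
    })
    dep = pd.DataFrame(dep_rows)

    graph = make_reaction_graph(
        [(EXAMPLE_METABOLITE, f"N{i:02d}") for i in range(1, 11)]
    )
    adj = conversion_distances(graph)
    return DemoInputs(corr, dep, adj, known, default_params())


def _corr_row(slc, met, ds, rho_t):
    # raw rho/p are illustrative; scoring consumes only rho_transformed
    return {
        "slc_id": slc, "metabolite_id": met, "dataset_id": ds,
        "n_samples": 60, "rho": math.tanh(rho_t / 4), "p": 0.01,
        "p_adj": 0.02, "rho_transformed": float(rho_t),
    }


@dataclass
class DemoScores:
    cell_panel_score: float
    with_gene_dep: float
    adjacency_score: float
    confidence: float
    row: pd.Series
    table: pd.DataFrame


def demo_scores() -> DemoScores:
    """Run the scoring module on the worked example and unpack the pair."""
    inputs = demo_inputs()
    table = confidence_scores(
        inputs.correlations, inputs.dependency, inputs.adjacency,
        inputs.known_pairs, inputs.params,
    )
    row = table[
        (table["slc_id"] == EXAMPLE_SLC)
        & (table["metabolite_id"] == EXAMPLE_METABOLITE)
    ].iloc[0]
    panel_sum = sum(row[f"sub_{ds}"] for ds in PANEL_KNOTS)
    cell_panel = inputs.params.weight_a * panel_sum
    with_dep = cell_panel + inputs.params.weight_b * row["gene_dep_subscore"]
    return DemoScores(
        cell_panel_score=float(cell_panel),
        with_gene_dep=float(with_dep),
        adjacency_score=float(row["adjacency_score"]),
        confidence=float(row["confidence"]),
        row=row,
        table=table,
    )
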