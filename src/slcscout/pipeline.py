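"""End-to-end orchestration: raw panels in, confidence table out.

Ties the stages together in the canonical order: median-ratio
normalisation of counts, per-panel Spearman correlation with BH
adjustment and the transformed-rho standardisation, tissue z-scoring
plus dependency contrasts on the CRISPR panel, conversion distances on
the reaction graph, and finally the confidence score.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .adjacency import AdjacencyMatrix, conversion_distances
from .correlation import bh_adjust, correlate_panel, transform_rho
from .data_model import OmicsMatrix
from .dependency import dependency_scan_all
from .preprocess import mrn_normalize, tissue_zscore
from .scoring import ScoreParams, confidence_scores, default_params
from .synthetic import SyntheticPanel

#: Metabolite panel used for the CRISPR dependency contrast (the panel
#: with tissue annotations in the default synthetic setup).
DEPENDENCY_DATASET = "CCLE2019"


@dataclass
class PipelineResult:
    pseudocounts: OmicsMatrix
    correlations: pd.DataFrame
    dependency: pd.DataFrame
    adjacency: AdjacencyMatrix
    confidence: pd.DataFrame
    params: ScoreParams


def correlate_datasets(
    expr: OmicsMatrix,
    metabolites: dict[str, OmicsMatrix],
    slc_ids=None,
    min_overlap: int = 10,
) -> pd.DataFrame:
    """Correlate one expression matrix against several metabolite panels,
    BH-adjust within transporter, and standardise onto the rho~ scale."""
    slc_ids = list(slc_ids) if slc_ids is not None else expr.feature_ids
    parts = [
        correlate_panel(expr, metab, slc_ids, dataset_id=ds, min_overlap=min_overlap)
        for ds, metab in metabolites.items()
    ]
    corr = pd.concat(parts, ignore_index=True)
    corr = bh_adjust(corr)
    corr, _ = transform_rho(corr)
    return corr


def run_scoring_pipeline(
    panel: SyntheticPanel,
    params: ScoreParams | None = None,
    min_overlap: int = 10,
) -> PipelineResult:
    """Score every (transporter, metabolite) pair of a synthetic panel."""
    params = params or default_params()
    pseudo, _ = mrn_normalize(panel.counts)
    corr = correlate_datasets(pseudo, panel.metabolites, min_overlap=min_overlap)

    dep_metab = panel.metabolites.get(DEPENDENCY_DATASET)
    dep = pd.DataFrame()
    if dep_metab is not None:
        metab_z = tissue_zscore(dep_metab, panel.tissue_map)
        dep = dependency_scan_all(panel.gene_effect, metab_z, pseudo.feature_ids)

    adj = conversion_distances(panel.reaction_graph)
    conf = confidence_scores(
        corr, dep if not dep.empty else None, adj, panel.known_pairs, params
    )
    return PipelineResult(pseudo, corr, dep, adj, conf, params)
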