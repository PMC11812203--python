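"""Domain containers shared by every pipeline stage.

The central object is :class:`OmicsMatrix`, a thin wrapper around a
feature-by-sample :class:`pandas.DataFrame` that records what kind of
measurement it holds (raw counts, normalised pseudocounts, metabolite
concentrations or z-scores, CRISPR gene-effect scores) and, optionally,
a tissue label per sample.  Auxiliary tables (known transporter-substrate
pairs, metabolite synonym maps, reaction-network edge lists, pathway
membership) are validated :class:`pandas.DataFrame` objects with fixed
column names, and the reaction network itself is a :mod:`networkx` graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed values for :attr:`OmicsMatrix.kind`.
MATRIX_KINDS = frozenset(
    {"counts", "pseudocounts", "metabolite_level", "metabolite_zscore", "gene_effect"}
)

KNOWN_PAIR_COLUMNS = ["slc_id", "target_id", "target_kind", "evidence"]
PATHWAY_COLUMNS = ["pathway_id", "metabolite_id"]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


class SchemaError(ValidationError):
    """A delimited file is missing a required column."""


class ParseError(ValueError):
    """A file could not be parsed in the declared dialect."""


@dataclass
class OmicsMatrix:
    """A feature-by-sample numeric matrix with typed semantics.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
        Missing measurements are NaN, never zero.
    kind
        One of :data:`MATRIX_KINDS`.
    sample_annotations
        Optional map from sample id to tissue label.
    """

    values: pd.DataFrame
    kind: str
    sample_annotations: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in MATRIX_KINDS:
            raise ValidationError(f"unknown matrix kind {self.kind!r}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        dup_feat = self.values.index[self.values.index.duplicated()].unique().tolist()
        if dup_feat:
            raise ValidationError(f"duplicate feature ids: {dup_feat}")
        dup_samp = self.values.columns[self.values.columns.duplicated()].unique().tolist()
        if dup_samp:
            raise ValidationError(f"duplicate sample ids: {dup_samp}")
        self.values = self.values.astype(float)
        if self.kind == "counts":
            vals = self.values.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("counts matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def tissue_of(self, sample_id: str) -> str | None:
        if self.sample_annotations is None:
            return None
        return self.sample_annotations.get(sample_id)

    def subset_samples(self, sample_ids) -> "OmicsMatrix":
        keep = [s for s in sample_ids if s in self.values.columns]
        ann = None
        if self.sample_annotations is not None:
            ann = {s: self.sample_annotations[s] for s in keep if s in self.sample_annotations}
        return OmicsMatrix(self.values[keep].copy(), self.kind, ann)


def make_known_pairs(rows, target_kind: str = "metabolite") -> pd.DataFrame:
    """Build a validated known-pair table from (slc_id, target_id) rows.

    ``rows`` may be an iterable of 2-tuples or a DataFrame already holding
    the ``slc_id``/``target_id`` columns.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows), columns=["slc_id", "target_id"])
    if "target_kind" not in df.columns:
        df["target_kind"] = target_kind
    if "evidence" not in df.columns:
        df["evidence"] = ""
    return validate_known_pairs(df)


def validate_known_pairs(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"slc_id", "target_id"} - set(df.columns)
    if missing:
        raise SchemaError(f"known-pair table missing columns {sorted(missing)}")
    if "target_kind" not in df.columns:
        df = df.assign(target_kind="metabolite")
    if "evidence" not in df.columns:
        df = df.assign(evidence="")
    df = df[KNOWN_PAIR_COLUMNS].astype({"slc_id": str, "target_id": str})
    if (df["slc_id"].str.len() == 0).any() or (df["target_id"].str.len() == 0).any():
        raise ValidationError("known-pair table contains empty ids")
    bad_kind = set(df["target_kind"]) - {"metabolite", "drug"}
    if bad_kind:
        raise ValidationError(f"unknown target_kind values {sorted(bad_kind)}")
    dups = df.duplicated(subset=["slc_id", "target_id"])
    if dups.any():
        raise ValidationError(
            "duplicate (slc_id, target_id) rows: "
            f"{df.loc[dups, ['slc_id', 'target_id']].values.tolist()}"
        )
    return df.reset_index(drop=True)


def make_reaction_graph(edges, nodes=None) -> nx.Graph:
    """Build an undirected metabolite conversion graph from an edge list.

    Each edge is one conversion step between two distinct metabolites.
    Self-loops are rejected; isolated nodes may be supplied via ``nodes``.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(str(n) for n in nodes)
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            raise ValidationError(f"self-loop edge on node {a!r}")
        g.add_edge(a, b)
    return g


def validate_pathways(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(PATHWAY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"pathway table missing columns {sorted(missing)}")
    df = df[PATHWAY_COLUMNS].astype(str)
    dups = df.duplicated()
    if dups.any():
        raise ValidationError("duplicate (pathway_id, metabolite_id) rows")
    return df.reset_index(drop=True)


def make_synonym_table(rows) -> pd.DataFrame:
    """Validated synonym table with columns raw_name, canonical_id."""
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows), columns=["raw_name", "canonical_id"])
    missing = {"raw_name", "canonical_id"} - set(df.columns)
    if missing:
        raise SchemaError(f"synonym table missing columns {sorted(missing)}")
    df = df[["raw_name", "canonical_id"]].astype(str)
    if df["raw_name"].duplicated().any():
        raise ValidationError("duplicate raw_name entries in synonym table")
    if (df["canonical_id"].str.len() == 0).any():
        raise ValidationError("empty canonical_id in synonym table")
    return df.reset_index(drop=True)


@dataclass
class HarmonizationReport:
    """Outcome of metabolite-name harmonization."""

    mapped: dict[str, str] = field(default_factory=dict)
    unmapped: list[str] = field(default_factory=list)


def harmonize_names(
    names, table: pd.DataFrame
) -> tuple[list[str], HarmonizationReport]:
    """Map raw metabolite names to canonical ids.

    Matching is case-insensitive after trimming surrounding whitespace.
    Names absent from the table pass through unchanged and are listed in
    the report.  Two *distinct* input names collapsing onto one canonical
    id would silently merge matrix rows, so that raises.
    """
    table = make_synonym_table(table)
    lookup = {
        raw.strip().lower(): canon
        for raw, canon in zip(table["raw_name"], table["canonical_id"])
    }
    out: list[str] = []
    report = HarmonizationReport()
    seen_canonical: dict[str, str] = {}
    for name in names:
        key = str(name).strip().lower()
        canon = lookup.get(key)
        if canon is None:
            out.append(name)
            report.unmapped.append(name)
        else:
            prev = seen_canonical.get(canon)
            if prev is not None and prev.strip().lower() != key:
                raise ValidationError(
                    f"names {prev!r} and {name!r} both map to {canon!r}: ambiguous merge"
                )
            seen_canonical[canon] = str(name)
            out.append(canon)
            report.mapped[str(name)] = canon
    if report.unmapped:
        logger.info("harmonize_names: %d names unmapped", len(report.unmapped))
    return out, report
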