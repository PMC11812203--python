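"""Readers and writers for the delimited / GCT formats the pipeline consumes.

Two matrix dialects are supported: GCT 1.2 (``#1.2`` version line, a
dimensions line, then ``Name``/``Description`` columns before the sample
columns) and plain delimited text (header row of sample ids, first column
feature ids).  The delimiter of delimited files is auto-detected from the
header line (tab vs comma).  Missing cells are the tokens ``""``, ``NA``
or ``NaN`` and load as NaN — never as zero.

Lines starting with ``#`` (other than the GCT version line) are treated
as provenance comments and skipped.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import networkx as nx
import pandas as pd

from .data_model import (
    OmicsMatrix,
    ParseError,
    SchemaError,
    ValidationError,
    make_reaction_graph,
    validate_known_pairs,
    validate_pathways,
)

NA_TOKENS = ["", "NA", "NaN", "nan"]


def _strip_comments(path) -> tuple[str, list[str]]:
    """Return file text without '#'-comment lines, plus those lines."""
    text = Path(path).read_text(encoding="utf-8")
    kept, comments = [], []
    for line in text.splitlines():
        if line.startswith("#"):
            comments.append(line)
        else:
            kept.append(line)
    return "\n".join(kept) + "\n", comments


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def _read_table(path) -> pd.DataFrame:
    body, _ = _strip_comments(path)
    header = body.splitlines()[0] if body.strip() else ""
    if not header:
        raise ParseError(f"{path}: empty file")
    sep = _sniff_delimiter(header)
    return pd.read_csv(
        _io.StringIO(body), sep=sep, na_values=NA_TOKENS, keep_default_na=False
    )


def load_matrix(path, kind: str, dialect: str = "auto") -> OmicsMatrix:
    """Load a feature-by-sample matrix.

    ``dialect`` is ``"gct"``, ``"delimited"`` or ``"auto"`` (GCT when the
    first line is the ``#1.2`` version tag).
    """
    path = Path(path)
    first = ""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
    if dialect == "auto":
        dialect = "gct" if first.startswith("#1.") else "delimited"
    if dialect == "gct":
        df = _load_gct(path)
    elif dialect == "delimited":
        df = _load_delimited(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    dups = df.index[df.index.duplicated()].unique().tolist()
    if dups:
        raise ValidationError(f"{path}: duplicate feature ids {dups}")
    return OmicsMatrix(df, kind)


def _load_gct(path) -> pd.DataFrame:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#1."):
        raise ParseError(f"{path}: line 1: expected GCT version tag '#1.2'")
    try:
        n_rows, n_cols = (int(x) for x in lines[1].split("\t")[:2])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: line 2: expected '<rows>\\t<cols>' dimensions") from exc
    body = "\n".join(lines[2:])
    df = pd.read_csv(_io.StringIO(body), sep="\t", na_values=NA_TOKENS, keep_default_na=False)
    if df.columns[0] != "Name" or df.columns[1] != "Description":
        raise ParseError(f"{path}: line 3: expected 'Name\\tDescription' header")
    if len(df) != n_rows or df.shape[1] - 2 != n_cols:
        raise ParseError(
            f"{path}: dimensions line says {n_rows}x{n_cols}, "
            f"found {len(df)}x{df.shape[1] - 2}"
        )
    out = df.drop(columns=["Description"]).set_index("Name")
    out.index = out.index.astype(str)
    out.index.name = None
    return out.astype(float)


def _load_delimited(path) -> pd.DataFrame:
    df = _read_table(path)
    out = df.set_index(df.columns[0])
    out.index = out.index.astype(str)
    out.index.name = None
    try:
        return out.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell in matrix body: {exc}") from exc


def write_matrix(path, matrix: OmicsMatrix, dialect: str = "delimited",
                 sep: str = "\t", comments: list[str] | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if dialect == "gct":
            fh.write("#1.2\n")
            fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
            df = matrix.values.copy()
            df.insert(0, "Description", df.index)
            df.insert(0, "Name", df.index)
            df.to_csv(fh, sep="\t", index=False, na_rep="NA")
        elif dialect == "delimited":
            for line in comments or []:
                fh.write(f"# {line}\n")
            df = matrix.values.copy()
            df.index.name = "feature_id"
            df.to_csv(fh, sep=sep, na_rep="NA")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def load_known_pairs(path) -> pd.DataFrame:
    df = _read_table(path)
    if "metabolite_id" in df.columns and "target_id" not in df.columns:
        df = df.rename(columns={"metabolite_id": "target_id"})
    missing = {"slc_id", "target_id"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return validate_known_pairs(df)


def write_known_pairs(path, pairs: pd.DataFrame) -> None:
    validate_known_pairs(pairs).to_csv(path, sep="\t", index=False)


def load_reaction_graph(path) -> nx.Graph:
    df = _read_table(path)
    missing = {"met_a", "met_b"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return make_reaction_graph(zip(df["met_a"].astype(str), df["met_b"].astype(str)))


def write_reaction_graph(path, graph: nx.Graph) -> None:
    rows = [{"met_a": a, "met_b": b} for a, b in sorted(graph.edges())]
    pd.DataFrame(rows, columns=["met_a", "met_b"]).to_csv(path, sep="\t", index=False)


def load_pathways(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = {"pathway_id", "metabolite_id"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return validate_pathways(df)


def write_pathways(path, pathways: pd.DataFrame) -> None:
    validate_pathways(pathways).to_csv(path, sep="\t", index=False)


def load_tissue_map(path) -> dict[str, str]:
    df = _read_table(path)
    missing = {"sample_id", "tissue"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return dict(zip(df["sample_id"].astype(str), df["tissue"].astype(str)))


def write_tissue_map(path, tissue_map: dict[str, str]) -> None:
    pd.DataFrame(
        {"sample_id": list(tissue_map), "tissue": list(tissue_map.values())}
    ).to_csv(path, sep="\t", index=False)


def write_table(path, df: pd.DataFrame, comments: list[str] | None = None) -> None:
    """Write a tidy result table as TSV with optional provenance comments."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def load_table(path) -> pd.DataFrame:
    return _read_table(path)


def read_provenance(path) -> list[str]:
    _, comments = _strip_comments(path)
    return [c.lstrip("# ") for c in comments if not c.startswith("#1.")]
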