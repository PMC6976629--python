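"""Readers and writers for the pipeline's plain-text formats.

Counts TSV (genes x samples), design CSV, GMT gene sets, BioGRID-like
weighted edge lists, wide protein-intensity TSVs with empty cells as
missing, long-format isotopologue CSVs, and JSON truth records.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from .design import SampleDesign
from .errors import EmptyInputError
from .syndata import SimTruth


# -- counts ---------------------------------------------------------------

def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise EmptyInputError(f"empty count matrix: {path}")
    return df.astype("int64")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


# -- design ---------------------------------------------------------------

def read_design_csv(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path))


def write_design_csv(design: SampleDesign, path) -> None:
    design.table.to_csv(path, index=False)


# -- GMT gene sets --------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """GMT: one set per line, tab-separated name, description, members."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise EmptyInputError(f"malformed GMT line: {line[:80]!r}")
        name, _desc, *members = fields
        if name in sets:
            raise EmptyInputError(f"duplicate GMT set name {name!r}")
        sets[name] = [m for m in members if m]
    if not sets:
        raise EmptyInputError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- interaction network --------------------------------------------------

def read_edgelist_tsv(path) -> nx.Graph:
    """Weighted undirected edge list: node_a <TAB> node_b <TAB> weight.
    A header line is detected (non-numeric third column) and skipped."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 3:
        raise EmptyInputError("edge list needs 3 columns: node_a, node_b, weight")
    first_weight = df.iloc[0, 2]
    try:
        float(first_weight)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    g = nx.Graph()
    for _, (a, b, w) in df.iloc[:, :3].iterrows():
        g.add_edge(str(a), str(b), weight=float(w))
    if g.number_of_edges() == 0:
        raise EmptyInputError(f"no edges in {path}")
    return g


def write_edgelist_tsv(graph: nx.Graph, path, header: bool = True) -> None:
    rows = [
        (u, v, f"{data.get('weight', 1.0):.6g}")
        for u, v, data in graph.edges(data=True)
    ]
    with open(path, "w") as fh:
        if header:
            fh.write("node_a\tnode_b\tweight\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w}\n")


# -- proteomics -----------------------------------------------------------

def read_protein_tsv(path) -> pd.DataFrame:
    """Wide protein x sample log2-intensity table; empty cells are
    missing (NaN)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise EmptyInputError(f"empty protein matrix: {path}")
    return df.astype(float)


def write_protein_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


# -- isotopologues --------------------------------------------------------

def read_isotopologues_csv(path) -> pd.DataFrame:
    from .tracing import validate_table

    return validate_table(pd.read_csv(path))


def write_isotopologues_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# -- truth / results ------------------------------------------------------

def write_truth_json(truth: SimTruth, path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2, sort_keys=True))


def read_truth_json(path) -> SimTruth:
    return SimTruth(**json.loads(Path(path).read_text()))


def write_de_tsv(de_table: pd.DataFrame, path) -> None:
    de_table.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
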