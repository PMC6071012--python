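"""Plain-text readers and writers for edge lists, MeSH tables and scores.

All formats are tab-separated UTF-8 text.  Lines starting with ``#`` are
comments.  A single optional header line is recognized when its first two
fields equal the expected column labels (case-insensitive); anything else
on the first line is data.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np

from .network import (
    DiseaseOntology,
    EdgeSet,
    ParseError,
    ScoreMatrix,
    TREE_NUMBER_RE,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _data_lines(path: PathLike):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_edge_list(path: PathLike, left_kind: str, right_kind: str) -> EdgeSet:
    """Read a two-column edge list into a deduplicated :class:`EdgeSet`.

    Node names are whitespace-trimmed with case preserved.  Duplicate lines
    collapse silently (the count is logged).  Columns beyond the second are
    ignored.
    """
    expected_header = [left_kind.lower(), right_kind.lower()]
    pairs = []
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if first:
            first = False
            if [f.strip().lower() for f in fields[:2]] == expected_header:
                continue
        if len(fields) < 2:
            raise ParseError(
                f"{path}:{lineno}: expected at least 2 tab-separated fields"
            )
        left, right = fields[0].strip(), fields[1].strip()
        if not left or not right:
            raise ParseError(f"{path}:{lineno}: empty node name")
        pairs.append((left, right))
    edges = frozenset(pairs)
    n_dup = len(pairs) - len(edges)
    if n_dup:
        logger.info("%s: collapsed %d duplicate edge(s)", path, n_dup)
    return EdgeSet(left_kind, right_kind, edges)


def write_edge_list(edge_set: EdgeSet, path: PathLike) -> None:
    """Write an edge set as sorted two-column TSV with a kind header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{edge_set.left_kind}\t{edge_set.right_kind}\n")
        for left, right in sorted(edge_set.edges):
            fh.write(f"{left}\t{right}\n")


def read_mesh_table(path: PathLike) -> DiseaseOntology:
    """Read a disease -> MeSH-tree-number table.

    One line per (disease, tree number); multiple lines per disease collect
    into a set.  Tree numbers must be dotted codes with non-empty segments.
    """
    mapping: dict[str, set[str]] = {}
    first = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if first:
            first = False
            if [f.strip().lower() for f in fields[:2]] == ["disease", "tree_number"]:
                continue
        if len(fields) < 2:
            raise ParseError(
                f"{path}:{lineno}: expected at least 2 tab-separated fields"
            )
        disease, code = fields[0].strip(), fields[1].strip()
        if not disease or not code:
            raise ParseError(f"{path}:{lineno}: empty field")
        if not TREE_NUMBER_RE.match(code):
            raise ParseError(f"{path}:{lineno}: malformed tree number {code!r}")
        mapping.setdefault(disease, set()).add(code)
    return DiseaseOntology({d: frozenset(c) for d, c in mapping.items()})


def write_mesh_table(ontology: DiseaseOntology, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\ttree_number\n")
        for disease in sorted(ontology.tree_numbers):
            for code in sorted(ontology.tree_numbers[disease]):
                fh.write(f"{disease}\t{code}\n")


def write_scores(scores: ScoreMatrix, path: PathLike) -> None:
    """Write a score matrix as a ranked 4-column TSV.

    Rows are sorted by score descending; ties break by (lncRNA, disease)
    name order so output is deterministic.  Rank is the 1-based position
    after sorting.
    """
    vals = scores.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("score matrix contains non-finite values")
    rows = [
        (lnc, dis, float(vals[i, j]))
        for i, lnc in enumerate(scores.lncrnas)
        for j, dis in enumerate(scores.diseases)
    ]
    rows.sort(key=lambda row: (-row[2], row[0], row[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lncRNA\tdisease\tscore\trank\n")
        for rank, (lnc, dis, score) in enumerate(rows, 1):
            fh.write(f"{lnc}\t{dis}\t{score:.10g}\t{rank}\n")
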