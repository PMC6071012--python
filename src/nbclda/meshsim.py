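"""MeSH-based disease semantic similarity and score re-weighting.

Each disease maps to one or more MeSH tree numbers (dotted position
codes).  The dotted prefixes of a tree number are the disease's ancestors,
and together they form a small DAG rooted at the disease's own positions.
Following the Wang et al. measure, an ancestor at hop distance k
contributes delta**k to the disease's semantics (delta in (0, 1], default
0.5); the semantic value DV of a disease is the sum of its ancestors'
contributions, and the similarity of two diseases is the contribution mass
they share:

    SD(di, dj) = sum_{t in Ti ∩ Tj} (D_i(t) + D_j(t)) / (DV(di) + DV(dj))

Nodes are identified by their tree-number strings, so the same MeSH
heading at two tree positions counts twice; a plain tree-number table
carries no heading-merge information.  Diseases without tree numbers fall
back to identity similarity rows, so re-weighting degrades gracefully to
the base score for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .network import (
    ConfigurationError,
    DiseaseOntology,
    MissingMeshError,
    ScoreMatrix,
)

DEFAULT_DELTA = 0.5


@dataclass(frozen=True)
class DiseaseDAG:
    """The ancestor DAG of one disease.

    ``terminals`` are the disease's own tree numbers (contribution 1);
    ``parents`` maps each node to its parent positions (dotted prefixes one
    segment shorter).
    """

    disease: str
    nodes: frozenset[str]
    parents: Mapping[str, frozenset[str]]
    terminals: frozenset[str]


@dataclass(eq=False)
class SimilarityMatrix:
    """Symmetric disease x disease semantic similarity with unit diagonal."""

    diseases: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.diseases)
        if self.values.shape != (k, k):
            raise ConfigurationError("similarity matrix must be square over diseases")

    def get(self, di: str, dj: str) -> float:
        i = self.diseases.index(di)
        j = self.diseases.index(dj)
        return float(self.values[i, j])


def build_dag(ontology: DiseaseOntology, disease: str) -> DiseaseDAG:
    """Expand a disease's tree numbers into its ancestor DAG.

    Every dotted prefix of every tree number is one node; the parent of
    ``A.B.C`` is ``A.B``.  Raises :class:`MissingMeshError` when the
    disease has no tree numbers, leaving the fallback to the caller.
    """
    codes = ontology.get(disease)
    if not codes:
        raise MissingMeshError(disease)
    nodes: set[str] = set()
    parents: dict[str, set[str]] = {}
    for code in codes:
        segments = code.split(".")
        chain = [".".join(segments[: i + 1]) for i in range(len(segments))]
        nodes.update(chain)
        for child, parent in zip(chain[1:], chain[:-1]):
            parents.setdefault(child, set()).add(parent)
    return DiseaseDAG(
        disease=disease,
        nodes=frozenset(nodes),
        parents={k: frozenset(v) for k, v in parents.items()},
        terminals=codes,
    )


def _check_acyclic(dag: DiseaseDAG) -> None:
    # Kahn-style elimination over child -> parent links.
    indeg = {node: 0 for node in dag.nodes}
    for child, ps in dag.parents.items():
        for parent in ps:
            indeg[parent] += 1
    stack = [node for node, deg in indeg.items() if deg == 0]
    seen = 0
    while stack:
        node = stack.pop()
        seen += 1
        for parent in dag.parents.get(node, ()):
            indeg[parent] -= 1
            if indeg[parent] == 0:
                stack.append(parent)
    if seen != len(dag.nodes):
        raise ValueError(f"cycle detected in DAG of {dag.disease!r}")


def contribution(dag: DiseaseDAG, delta: float = DEFAULT_DELTA) -> dict[str, float]:
    """Semantic contribution of every DAG node to its disease.

    The disease's own positions contribute 1; every other node contributes
    the maximum of delta times its children's contributions, which equals
    delta**(minimum hop distance to the disease).
    """
    if not 0 < delta <= 1:
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    _check_acyclic(dag)
    depth = {t: 0 for t in dag.terminals if t in dag.nodes}
    frontier = sorted(depth)
    while frontier:
        nxt = []
        for node in frontier:
            for parent in dag.parents.get(node, ()):
                if parent not in depth:
                    depth[parent] = depth[node] + 1
                    nxt.append(parent)
        frontier = sorted(nxt)
    unreachable = dag.nodes - depth.keys()
    if unreachable:
        raise ValueError(
            f"nodes unreachable from disease {dag.disease!r}: {sorted(unreachable)}"
        )
    return {node: delta ** d for node, d in depth.items()}


def semantic_value(contribs: Mapping[str, float]) -> float:
    """Total semantic value DV: the sum of all node contributions."""
    return float(sum(contribs.values()))


def similarity_matrix(ontology: DiseaseOntology,
                      diseases: Sequence[str],
                      delta: float = DEFAULT_DELTA) -> SimilarityMatrix:
    """Pairwise semantic similarity over a disease registry.

    Diseases absent from the ontology get identity rows (1 on the
    diagonal, 0 elsewhere) so downstream re-weighting passes their scores
    through unchanged.
    """
    diseases = tuple(diseases)
    profiles: dict[str, Optional[tuple[dict[str, float], float]]] = {}
    for disease in diseases:
        try:
            dag = build_dag(ontology, disease)
        except MissingMeshError:
            profiles[disease] = None
            continue
        contribs = contribution(dag, delta)
        profiles[disease] = (contribs, semantic_value(contribs))
    values = np.eye(len(diseases))
    for i, di in enumerate(diseases):
        if profiles[di] is None:
            continue
        ci, dvi = profiles[di]
        for j in range(i + 1, len(diseases)):
            dj = diseases[j]
            if profiles[dj] is None:
                continue
            cj, dvj = profiles[dj]
            shared = ci.keys() & cj.keys()
            if not shared:
                continue
            sim = sum(ci[t] + cj[t] for t in shared) / (dvi + dvj)
            values[i, j] = values[j, i] = sim
    return SimilarityMatrix(diseases, values)


def combine(scores: ScoreMatrix, sim: SimilarityMatrix) -> ScoreMatrix:
    """Re-weight scores by disease similarity: S(l, d) = sum_d' S'(l, d') SD(d', d).

    A disease-space matrix product, i.e. score smoothing over semantically
    similar diseases.  With an identity similarity matrix the output equals
    the input exactly.
    """
    if tuple(scores.diseases) != tuple(sim.diseases):
        raise ConfigurationError(
            "score columns and similarity matrix cover different disease registries"
        )
    return ScoreMatrix(scores.lncrnas, scores.diseases,
                       scores.values @ sim.values, lam=scores.lam)


def write_similarity(sim: SimilarityMatrix, path) -> None:
    """Write the similarity matrix as TSV with a disease header row/column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease\t" + "\t".join(sim.diseases) + "\n")
        for i, disease in enumerate(sim.diseases):
            row = "\t".join(f"{v:.10g}" for v in sim.values[i])
            fh.write(f"{disease}\t{row}\n")
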