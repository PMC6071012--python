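"""Synthetic heterogeneous networks with planted lncRNA–disease signal.

Each bipartite evidence layer (miRNA–lncRNA, miRNA–disease, gene–lncRNA,
gene–disease, gene–miRNA) is drawn i.i.d. Bernoulli at a common density.
Known lncRNA–disease associations are then planted with probability
``logistic(a + b * k)`` where ``k`` is the pair's common-neighbour count
(miRNAs plus genes), so association probability rises with shared
evidence — the statistical structure the common-neighbour scorer assumes —
without encoding the scoring formula itself.  A two-level tree-number
ontology makes diseases that share a random root prefix "similar".

Everything is driven by one integer seed; the same parameters and seed
reproduce the network, ontology and written files byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import write_edge_list, write_mesh_table
from .network import (
    DISEASE,
    DiseaseOntology,
    EdgeSet,
    GENE,
    HeteroNetwork,
    LNCRNA,
    MIRNA,
)


@dataclass(frozen=True)
class GeneratorParams:
    """Node counts, layer density and logistic planting coefficients."""

    n_l: int = 40
    n_d: int = 30
    n_m: int = 25
    n_g: int = 15
    layer_density: float = 0.1
    plant_intercept: float = -3.0
    plant_slope: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_l, self.n_d, self.n_m, self.n_g) < 1:
            raise ValueError("node counts must be at least 1")
        if not 0 <= self.layer_density <= 1:
            raise ValueError("layer_density must be in [0, 1]")


def _names(prefix: str, count: int) -> tuple[str, ...]:
    width = max(3, len(str(count)))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(count))


def _edges_from_matrix(matrix: np.ndarray, left_names, right_names,
                       left_kind: str, right_kind: str) -> EdgeSet:
    pairs = frozenset(
        (left_names[i], right_names[j]) for i, j in np.argwhere(matrix)
    )
    return EdgeSet(left_kind, right_kind, pairs)


def generate(params: GeneratorParams) -> tuple[HeteroNetwork, DiseaseOntology, frozenset]:
    """Draw one synthetic quadruple network, ontology and planted truth set.

    Returns a GN2-mode network whose registries include every generated
    node (isolated ones too, keeping the n x r candidate grid fixed), the
    disease ontology, and the planted lncRNA–disease edges as the truth
    set (identical to the network's LDN).
    """
    rng = np.random.default_rng(params.seed)
    lncrnas = _names("l", params.n_l)
    diseases = _names("d", params.n_d)
    mirnas = _names("m", params.n_m)
    genes = _names("g", params.n_g)

    density = params.layer_density
    lm = rng.random((params.n_l, params.n_m)) < density  # lncRNA x miRNA
    md = rng.random((params.n_m, params.n_d)) < density  # miRNA x disease
    gl = rng.random((params.n_g, params.n_l)) < density  # gene x lncRNA
    gd = rng.random((params.n_g, params.n_d)) < density  # gene x disease
    gm = rng.random((params.n_g, params.n_m)) < density  # gene x miRNA

    k = (lm.astype(int) @ md.astype(int)
         + gl.T.astype(int) @ gd.astype(int))  # common neighbours per (l, d)
    logit = params.plant_intercept + params.plant_slope * k
    prob = 1.0 / (1.0 + np.exp(-logit))
    ld = rng.random((params.n_l, params.n_d)) < prob

    network = HeteroNetwork(
        lncrnas=lncrnas, diseases=diseases, mirnas=mirnas, genes=genes,
        mdn=_edges_from_matrix(md, mirnas, diseases, MIRNA, DISEASE),
        mln=_edges_from_matrix(lm.T, mirnas, lncrnas, MIRNA, LNCRNA),
        ldn=_edges_from_matrix(ld, lncrnas, diseases, LNCRNA, DISEASE),
        gdn=_edges_from_matrix(gd, genes, diseases, GENE, DISEASE),
        gln=_edges_from_matrix(gl, genes, lncrnas, GENE, LNCRNA),
        gmn=_edges_from_matrix(gm, genes, mirnas, GENE, MIRNA),
        mode="GN2",
    )

    # Two-level ontology: diseases drawing the same root prefix share one
    # ancestor, everyone else is disjoint.
    n_roots = max(2, params.n_d // 6)
    roots = rng.integers(0, n_roots, size=params.n_d)
    tree_numbers = {
        disease: frozenset({f"C{roots[j] + 1:02d}.{j + 1:03d}"})
        for j, disease in enumerate(diseases)
    }
    ontology = DiseaseOntology(tree_numbers)
    truth = frozenset(network.ldn.edges)
    return network, ontology, truth


#: file names used by :func:`write_dataset` for each layer
DATASET_FILES = {
    "mdn": "mdn.tsv", "mln": "mln.tsv", "ldn": "ldn.tsv",
    "gdn": "gdn.tsv", "gln": "gln.tsv", "gmn": "gmn.tsv",
}


def write_dataset(outdir, network: HeteroNetwork, ontology: DiseaseOntology,
                  truth: frozenset = None) -> dict[str, str]:
    """Write the six edge lists, the MeSH table and the truth set as TSV.

    Returns the mapping of layer name to written path.  The files use the
    same formats the readers consume, so a generated dataset feeds
    straight back into the scoring pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, filename in DATASET_FILES.items():
        edge_set = getattr(network, name)
        if edge_set is None:
            continue
        path = outdir / filename
        write_edge_list(edge_set, path)
        written[name] = str(path)
    mesh_path = outdir / "mesh.tsv"
    write_mesh_table(ontology, mesh_path)
    written["mesh"] = str(mesh_path)
    if truth is not None:
        truth_path = outdir / "truth.tsv"
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write("lncRNA\tdisease\n")
            for lnc, dis in sorted(truth):
                fh.write(f"{lnc}\t{dis}\n")
        written["truth"] = str(truth_path)
    return written
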