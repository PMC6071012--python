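"""Shared fixtures: hand-built toy networks and a random-network factory."""

from __future__ import annotations

import numpy as np
import pytest

from nbclda.network import (
    DISEASE,
    EdgeSet,
    GENE,
    HeteroNetwork,
    LNCRNA,
    MIRNA,
    assemble_gn1,
    assemble_gn2,
)


def edge_set(left_kind, right_kind, pairs):
    return EdgeSet(left_kind, right_kind, frozenset(pairs))


@pytest.fixture
def toy_t1():
    """Tripartite toy: one miRNA hub, one known association.

    n=2 lncRNAs, r=2 diseases, t=1 miRNA, |known|=1, so the prior odds are
    (1/4)/(3/4) = 1/3 and the single feature m1 has counts
    (N+, N-, Nl, Nd) = (1, 3, 2, 2).
    """
    return assemble_gn1(
        edge_set(MIRNA, DISEASE, {("m1", "d1"), ("m1", "d2")}),
        edge_set(MIRNA, LNCRNA, {("m1", "l1"), ("m1", "l2")}),
        edge_set(LNCRNA, DISEASE, {("l1", "d1")}),
    )


@pytest.fixture
def toy_t2(toy_t1):
    """Quadruple toy: T1 plus one gene that pairs with the miRNA at (l2, d2)."""
    return assemble_gn2(
        toy_t1,
        edge_set(GENE, DISEASE, {("g1", "d2")}),
        edge_set(GENE, LNCRNA, {("g1", "l2")}),
        edge_set(GENE, MIRNA, {("g1", "m1")}),
    )


@pytest.fixture
def interacting_pair_subnetwork():
    """Two common miRNAs and two common genes at (l2, d3), m3-g4 interacting.

    The feature partition of (l2, d3) must be {pair(m3, g4), m1, g1}.
    """
    gn1 = assemble_gn1(
        edge_set(MIRNA, DISEASE, {("m1", "d3"), ("m3", "d3")}),
        edge_set(MIRNA, LNCRNA, {("m1", "l2"), ("m3", "l2")}),
        edge_set(LNCRNA, DISEASE, {("l2", "d3")}),
    )
    return assemble_gn2(
        gn1,
        edge_set(GENE, DISEASE, {("g1", "d3"), ("g4", "d3")}),
        edge_set(GENE, LNCRNA, {("g1", "l2"), ("g4", "l2")}),
        edge_set(GENE, MIRNA, {("g4", "m3")}),
    )


def random_network(rng: np.random.Generator,
                   max_l=6, max_d=6, max_m=5, max_g=4,
                   mode="GN2") -> HeteroNetwork:
    """A random small network with full registries (isolated nodes kept)."""
    n_l = int(rng.integers(1, max_l + 1))
    n_d = int(rng.integers(1, max_d + 1))
    n_m = int(rng.integers(1, max_m + 1))
    n_g = int(rng.integers(1, max_g + 1)) if mode == "GN2" else 0
    lncrnas = tuple(f"l{i}" for i in range(n_l))
    diseases = tuple(f"d{i}" for i in range(n_d))
    mirnas = tuple(f"m{i}" for i in range(n_m))
    genes = tuple(f"g{i}" for i in range(n_g))
    density = float(rng.uniform(0.1, 0.6))

    def bern(rows, cols):
        return rng.random((len(rows), len(cols))) < density

    def edges(matrix, rows, cols, lk, rk):
        pairs = frozenset((rows[i], cols[j]) for i, j in np.argwhere(matrix))
        return EdgeSet(lk, rk, pairs)

    kwargs = dict(
        lncrnas=lncrnas, diseases=diseases, mirnas=mirnas, genes=genes,
        mdn=edges(bern(mirnas, diseases), mirnas, diseases, MIRNA, DISEASE),
        mln=edges(bern(mirnas, lncrnas), mirnas, lncrnas, MIRNA, LNCRNA),
        ldn=edges(bern(lncrnas, diseases), lncrnas, diseases, LNCRNA, DISEASE),
        mode=mode,
    )
    if mode == "GN2":
        kwargs.update(
            gdn=edges(bern(genes, diseases), genes, diseases, GENE, DISEASE),
            gln=edges(bern(genes, lncrnas), genes, lncrnas, GENE, LNCRNA),
            gmn=edges(bern(genes, mirnas), genes, mirnas, GENE, MIRNA),
        )
    return HeteroNetwork(**kwargs)


def random_ontology(rng: np.random.Generator, n_diseases=8,
                    max_depth=4) -> dict[str, frozenset[str]]:
    """Random dotted tree numbers over a tiny alphabet (shared prefixes likely)."""
    mapping = {}
    for i in range(n_diseases):
        n_codes = int(rng.integers(1, 3))
        codes = set()
        for _ in range(n_codes):
            depth = int(rng.integers(1, max_depth + 1))
            segments = [str(rng.integers(0, 3)) for _ in range(depth)]
            codes.add("C" + ".".join(segments))
        mapping[f"d{i}"] = frozenset(codes)
    return mapping
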