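"""Containers for the heterogeneous lncRNA–miRNA–gene–disease network.

The global network comes in two flavours: the tripartite network (mode
``"GN1"``) integrates three bipartite layers — miRNA–disease (MDN),
miRNA–lncRNA (MLN) and lncRNA–disease (LDN) — while the quadruple network
(mode ``"GN2"``) adds three gene layers: gene–disease (GDN), gene–lncRNA
(GLN) and gene–miRNA (GMN).  Node identity is the exact name string after
trimming leading/trailing whitespace; case is significant.  Registries are
kept sorted lexicographically so matrix layouts and rank tie-breaks are
reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Mapping, Optional

import numpy as np

LNCRNA = "lncRNA"
DISEASE = "disease"
MIRNA = "miRNA"
GENE = "gene"

#: Dotted MeSH position code: non-empty segments separated by single dots.
TREE_NUMBER_RE = re.compile(r"^[^.\s]+(\.[^.\s]+)*$")


class ParseError(ValueError):
    """An input table could not be parsed."""


class ConfigurationError(ValueError):
    """Inputs were wired together inconsistently (kind or registry mismatch)."""


class MissingMeshError(KeyError):
    """A disease has no MeSH tree numbers; callers decide the fallback."""


@dataclass(frozen=True)
class EdgeSet:
    """One bipartite relation: undirected cross-edges between two node kinds.

    Edges are stored as ``(left_name, right_name)`` pairs with set
    semantics — duplicates collapse, order within the pair is fixed by the
    kind labels.  A reversed pair in an input file is a kind violation, not
    an edge to auto-flip.
    """

    left_kind: str
    right_kind: str
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        cleaned = set()
        for pair in self.edges:
            left, right = pair
            left, right = left.strip(), right.strip()
            if not left or not right:
                raise ParseError(f"empty node name in edge pair {pair!r}")
            cleaned.add((left, right))
        object.__setattr__(self, "edges", frozenset(cleaned))

    def __len__(self) -> int:
        return len(self.edges)

    def lefts(self) -> frozenset[str]:
        return frozenset(left for left, _ in self.edges)

    def rights(self) -> frozenset[str]:
        return frozenset(right for _, right in self.edges)


def _empty_edges(left_kind: str, right_kind: str) -> EdgeSet:
    return EdgeSet(left_kind, right_kind, frozenset())


def _check_kinds(es: EdgeSet, left: str, right: str, name: str) -> None:
    if (es.left_kind, es.right_kind) != (left, right):
        raise ConfigurationError(
            f"{name} must have kinds ({left}, {right}), "
            f"got ({es.left_kind}, {es.right_kind})"
        )


def _adjacency(edges: Iterable[tuple[str, str]],
               row_index: Mapping[str, int],
               col_index: Mapping[str, int],
               row_is_left: bool) -> np.ndarray:
    mat = np.zeros((len(row_index), len(col_index)), dtype=bool)
    for left, right in edges:
        if row_is_left:
            mat[row_index[left], col_index[right]] = True
        else:
            mat[row_index[right], col_index[left]] = True
    return mat


def _neighbor_map(pairs: Iterable[tuple[str, str]], key_first: bool) -> dict[str, frozenset[str]]:
    acc: dict[str, set[str]] = {}
    for a, b in pairs:
        key, val = (a, b) if key_first else (b, a)
        acc.setdefault(key, set()).add(val)
    return {k: frozenset(v) for k, v in acc.items()}


@dataclass(eq=False)
class HeteroNetwork:
    """The global network GN1 or GN2: node registries plus the edge layers.

    Registries are ordered name tuples; every edge endpoint must appear in
    the registry of its kind (registries may be supersets, which is how a
    training-reduced LDN keeps the original candidate space).  ``n``, ``r``,
    ``t`` and ``p`` are the registry sizes for lncRNAs, diseases, miRNAs
    and genes.
    """

    lncrnas: tuple[str, ...]
    diseases: tuple[str, ...]
    mirnas: tuple[str, ...]
    genes: tuple[str, ...]
    mdn: EdgeSet
    mln: EdgeSet
    ldn: EdgeSet
    gdn: Optional[EdgeSet] = None
    gln: Optional[EdgeSet] = None
    gmn: Optional[EdgeSet] = None
    mode: str = "GN1"

    def __post_init__(self) -> None:
        if self.mode not in ("GN1", "GN2"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        _check_kinds(self.mdn, MIRNA, DISEASE, "mdn")
        _check_kinds(self.mln, MIRNA, LNCRNA, "mln")
        _check_kinds(self.ldn, LNCRNA, DISEASE, "ldn")
        if self.mode == "GN1":
            if self.gdn is not None or self.gln is not None or self.gmn is not None:
                raise ConfigurationError("GN1 networks carry no gene edge sets")
            if self.genes:
                raise ConfigurationError("GN1 networks have an empty gene registry")
        else:
            if self.gdn is None or self.gln is None or self.gmn is None:
                raise ConfigurationError("GN2 networks need gdn, gln and gmn")
            _check_kinds(self.gdn, GENE, DISEASE, "gdn")
            _check_kinds(self.gln, GENE, LNCRNA, "gln")
            _check_kinds(self.gmn, GENE, MIRNA, "gmn")
        self._validate_registries()

    def _validate_registries(self) -> None:
        reg = {
            LNCRNA: set(self.lncrnas),
            DISEASE: set(self.diseases),
            MIRNA: set(self.mirnas),
            GENE: set(self.genes),
        }
        for name, es in self._edge_sets().items():
            for left, right in es.edges:
                if left not in reg[es.left_kind] or right not in reg[es.right_kind]:
                    raise ConfigurationError(
                        f"edge ({left}, {right}) in {name} has an endpoint "
                        f"missing from its registry"
                    )

    def _edge_sets(self) -> dict[str, EdgeSet]:
        sets = {"mdn": self.mdn, "mln": self.mln, "ldn": self.ldn}
        if self.mode == "GN2":
            sets.update({"gdn": self.gdn, "gln": self.gln, "gmn": self.gmn})
        return sets

    # -- registry sizes ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.lncrnas)

    @property
    def r(self) -> int:
        return len(self.diseases)

    @property
    def t(self) -> int:
        return len(self.mirnas)

    @property
    def p(self) -> int:
        return len(self.genes)

    # -- index maps and adjacency ------------------------------------------
    @cached_property
    def lnc_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.lncrnas)}

    @cached_property
    def dis_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.diseases)}

    @cached_property
    def mir_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.mirnas)}

    @cached_property
    def gene_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.genes)}

    @cached_property
    def adj_lm(self) -> np.ndarray:
        """lncRNA x miRNA adjacency from MLN."""
        return _adjacency(self.mln.edges, self.lnc_index, self.mir_index, row_is_left=False)

    @cached_property
    def adj_md(self) -> np.ndarray:
        """miRNA x disease adjacency from MDN."""
        return _adjacency(self.mdn.edges, self.mir_index, self.dis_index, row_is_left=True)

    @cached_property
    def adj_ld(self) -> np.ndarray:
        """lncRNA x disease adjacency of known associations (LDN)."""
        return _adjacency(self.ldn.edges, self.lnc_index, self.dis_index, row_is_left=True)

    @cached_property
    def adj_gl(self) -> np.ndarray:
        """gene x lncRNA adjacency from GLN (all-zero in GN1 mode)."""
        if self.gln is None:
            return np.zeros((self.p, self.n), dtype=bool)
        return _adjacency(self.gln.edges, self.gene_index, self.lnc_index, row_is_left=True)

    @cached_property
    def adj_gd(self) -> np.ndarray:
        if self.gdn is None:
            return np.zeros((self.p, self.r), dtype=bool)
        return _adjacency(self.gdn.edges, self.gene_index, self.dis_index, row_is_left=True)

    @cached_property
    def adj_gm(self) -> np.ndarray:
        if self.gmn is None:
            return np.zeros((self.p, self.t), dtype=bool)
        return _adjacency(self.gmn.edges, self.gene_index, self.mir_index, row_is_left=True)

    # -- neighbour maps (per-name set views, used by per-pair operations) ---
    @cached_property
    def mirnas_of_lncrna(self) -> dict[str, frozenset[str]]:
        return _neighbor_map(self.mln.edges, key_first=False)

    @cached_property
    def mirnas_of_disease(self) -> dict[str, frozenset[str]]:
        return _neighbor_map(self.mdn.edges, key_first=False)

    @cached_property
    def lncrnas_of_mirna(self) -> dict[str, frozenset[str]]:
        return _neighbor_map(self.mln.edges, key_first=True)

    @cached_property
    def diseases_of_mirna(self) -> dict[str, frozenset[str]]:
        return _neighbor_map(self.mdn.edges, key_first=True)

    @cached_property
    def genes_of_lncrna(self) -> dict[str, frozenset[str]]:
        if self.gln is None:
            return {}
        return _neighbor_map(self.gln.edges, key_first=False)

    @cached_property
    def genes_of_disease(self) -> dict[str, frozenset[str]]:
        if self.gdn is None:
            return {}
        return _neighbor_map(self.gdn.edges, key_first=False)

    @cached_property
    def lncrnas_of_gene(self) -> dict[str, frozenset[str]]:
        if self.gln is None:
            return {}
        return _neighbor_map(self.gln.edges, key_first=True)

    @cached_property
    def diseases_of_gene(self) -> dict[str, frozenset[str]]:
        if self.gdn is None:
            return {}
        return _neighbor_map(self.gdn.edges, key_first=True)

    # -- derived views ------------------------------------------------------
    def with_ldn(self, edges: Iterable[tuple[str, str]]) -> "HeteroNetwork":
        """Same network with a replacement LDN (registries unchanged).

        Used for training-reduced scoring: candidate pairs still span the
        full lncRNA and disease registries.
        """
        new_ldn = EdgeSet(LNCRNA, DISEASE, frozenset(edges))
        return replace(self, ldn=new_ldn)

    def to_gn1(self) -> "HeteroNetwork":
        """Drop the gene layers, keeping all other registries and edges."""
        if self.mode == "GN1":
            return self
        return HeteroNetwork(
            lncrnas=self.lncrnas, diseases=self.diseases, mirnas=self.mirnas,
            genes=(), mdn=self.mdn, mln=self.mln, ldn=self.ldn, mode="GN1",
        )


def assemble_gn1(mdn: EdgeSet, mln: EdgeSet, ldn: EdgeSet) -> HeteroNetwork:
    """Build the global tripartite network from its three bipartite layers.

    Registries are the sorted unions of the endpoint names of each kind, so
    an lncRNA appearing only in the LDN still enters the lncRNA registry.
    """
    _check_kinds(mdn, MIRNA, DISEASE, "mdn")
    _check_kinds(mln, MIRNA, LNCRNA, "mln")
    _check_kinds(ldn, LNCRNA, DISEASE, "ldn")
    lncrnas = tuple(sorted(mln.rights() | ldn.lefts()))
    diseases = tuple(sorted(mdn.rights() | ldn.rights()))
    mirnas = tuple(sorted(mdn.lefts() | mln.lefts()))
    return HeteroNetwork(lncrnas, diseases, mirnas, (), mdn, mln, ldn, mode="GN1")


def assemble_gn2(gn1: HeteroNetwork, gdn: EdgeSet, gln: EdgeSet, gmn: EdgeSet) -> HeteroNetwork:
    """Append the three gene layers to a tripartite network.

    All GN1 content is preserved; registries grow by any new endpoint names
    brought in by the gene layers.
    """
    if gn1.mode != "GN1":
        raise ConfigurationError("assemble_gn2 expects a GN1 network")
    _check_kinds(gdn, GENE, DISEASE, "gdn")
    _check_kinds(gln, GENE, LNCRNA, "gln")
    _check_kinds(gmn, GENE, MIRNA, "gmn")
    lncrnas = tuple(sorted(set(gn1.lncrnas) | gln.rights()))
    diseases = tuple(sorted(set(gn1.diseases) | gdn.rights()))
    mirnas = tuple(sorted(set(gn1.mirnas) | gmn.rights()))
    genes = tuple(sorted(gdn.lefts() | gln.lefts() | gmn.lefts()))
    return HeteroNetwork(lncrnas, diseases, mirnas, genes,
                         gn1.mdn, gn1.mln, gn1.ldn, gdn, gln, gmn, mode="GN2")


@dataclass(frozen=True)
class DiseaseOntology:
    """MeSH tree numbers per disease (dot-separated position codes)."""

    tree_numbers: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        validated = {}
        for disease, codes in self.tree_numbers.items():
            disease = disease.strip()
            if not disease:
                raise ParseError("empty disease name in ontology")
            codes = frozenset(str(c).strip() for c in codes)
            for code in codes:
                if not TREE_NUMBER_RE.match(code):
                    raise ParseError(f"malformed MeSH tree number {code!r} for {disease!r}")
            validated[disease] = codes
        object.__setattr__(self, "tree_numbers", validated)

    def get(self, disease: str) -> frozenset[str]:
        return self.tree_numbers.get(disease, frozenset())

    def missing(self, diseases: Iterable[str]) -> tuple[str, ...]:
        """Diseases with no tree number (these fall back to identity rows)."""
        return tuple(d for d in diseases if not self.get(d))


@dataclass(eq=False)
class ScoreMatrix:
    """lncRNA x disease association scores aligned to a network's registries.

    ``lam`` records the normalization constant when the values are
    log-normalized scores; it is ``None`` for raw posterior odds.
    """

    lncrnas: tuple[str, ...]
    diseases: tuple[str, ...]
    values: np.ndarray
    lam: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.lncrnas), len(self.diseases)):
            raise ConfigurationError(
                f"score matrix shape {self.values.shape} does not match "
                f"registries ({len(self.lncrnas)}, {len(self.diseases)})"
            )

    def get(self, lncrna: str, disease: str) -> float:
        i = self.lncrnas.index(lncrna)
        j = self.diseases.index(disease)
        return float(self.values[i, j])
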