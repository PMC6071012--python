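"""Naive-Bayes posterior-odds scoring of lncRNA–disease pairs.

The score of a candidate pair (l, d) is the posterior odds of association
under a naive Bayesian classifier whose evidence variables are the common
neighbours of l and d in the global network.  Writing phi for the prior
odds |known associations| / (n*r - |known|), the closed form is

    S(l, d) = phi * prod_f [ phi^-1 * (N_f+ + 1) / (N_f- + 1) ]

where the product runs over the features f of the pair, N_f+ counts the
known lncRNA–disease associations whose endpoints are both adjacent to f,
and N_f- = Nl_f * Nd_f - N_f+ counts the unknown ones (Nl_f and Nd_f are
the numbers of lncRNAs and diseases adjacent to f).  The +1 terms are
Laplace calibration so a feature never zeroes the product.

On the tripartite network the features are the common miRNA neighbours.
On the quadruple network, common genes join in, and a common miRNA m and a
common gene g that interact (edge in GMN) merge into one miRNA–gene *pair
feature* whose adjacency means "adjacent to both m and g"; nodes covered
by at least one pair never also count as singleton features.  Every
connected (m, g) combination among the common neighbours becomes a pair,
which keeps the construction order-independent.  Each feature — singleton
or pair — contributes exactly one phi^-1 factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import ConfigurationError, HeteroNetwork, ScoreMatrix

Edge = tuple[str, str]


@dataclass(frozen=True)
class PriorOdds:
    """Prior probability and odds of a random lncRNA–disease pair being linked."""

    p1: float
    p0: float
    phi: float
    n_known: int
    n_pairs: int


@dataclass(frozen=True)
class Feature:
    """A unit of common-neighbour evidence for one lncRNA–disease pair.

    ``kind`` is ``"miRNA"`` or ``"gene"`` for singletons (``members`` holds
    one name) or ``"pair"`` for a merged miRNA–gene feature (``members`` is
    the ordered (miRNA, gene) name pair).
    """

    kind: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("miRNA", "gene", "pair"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        expected = 2 if self.kind == "pair" else 1
        if len(self.members) != expected:
            raise ValueError(f"{self.kind} feature needs {expected} member(s)")


@dataclass(frozen=True)
class FeatureSet:
    """The features of one (lncRNA, disease) pair, pairs first then singletons."""

    lncrna: str
    disease: str
    features: tuple[Feature, ...]

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class FeatureCounts:
    """Association counts for one feature.

    ``n_plus``/``n_minus`` are the known/unknown lncRNA–disease pair counts
    among the Nl x Nd pairs adjacent to the feature; their sum always
    equals ``n_l * n_d``.
    """

    n_plus: int
    n_minus: int
    n_l: int
    n_d: int

    def __post_init__(self) -> None:
        if min(self.n_plus, self.n_minus, self.n_l, self.n_d) < 0:
            raise ValueError("feature counts must be non-negative")
        if self.n_plus + self.n_minus != self.n_l * self.n_d:
            raise ValueError(
                f"count conservation violated: {self.n_plus} + {self.n_minus} "
                f"!= {self.n_l} * {self.n_d}"
            )


def prior_odds(network: HeteroNetwork,
               excluded_edge: Optional[Edge] = None,
               restrict_to_ldn: bool = False) -> PriorOdds:
    """Prior odds of association from the known-association density.

    ``n_pairs`` is n*r over the full registries by default;
    ``restrict_to_ldn`` instead counts only lncRNAs and diseases that carry
    at least one known association.  ``excluded_edge`` (held out during
    cross-validation) is removed from the known set before counting.
    """
    known = set(network.ldn.edges)
    known.discard(excluded_edge)
    if restrict_to_ldn:
        n = len({l for l, _ in known})
        r = len({d for _, d in known})
    else:
        n, r = network.n, network.r
    n_pairs = n * r
    if n_pairs == 0:
        raise ValueError("prior odds undefined on an empty lncRNA/disease registry")
    p1 = len(known) / n_pairs
    p0 = 1.0 - p1
    phi = p1 / p0 if p0 > 0 else math.inf
    return PriorOdds(p1=p1, p0=p0, phi=phi, n_known=len(known), n_pairs=n_pairs)


def common_neighbors(network: HeteroNetwork, lncrna: str, disease: str) -> FeatureSet:
    """Partition the common neighbours of (lncrna, disease) into features.

    Tripartite mode yields singleton miRNA features only.  Quadruple mode
    adds singleton genes and merges interacting (miRNA, gene) common
    neighbours into pair features, removing covered nodes from the
    singletons.
    """
    if lncrna not in network.lnc_index:
        raise KeyError(f"unknown lncRNA {lncrna!r}")
    if disease not in network.dis_index:
        raise KeyError(f"unknown disease {disease!r}")
    empty: frozenset[str] = frozenset()
    cm = (network.mirnas_of_lncrna.get(lncrna, empty)
          & network.mirnas_of_disease.get(disease, empty))
    features: list[Feature] = []
    if network.mode == "GN2":
        cg = (network.genes_of_lncrna.get(lncrna, empty)
              & network.genes_of_disease.get(disease, empty))
        gmn_edges = network.gmn.edges  # (gene, miRNA) pairs
        pairs = sorted((m, g) for m in cm for g in cg if (g, m) in gmn_edges)
        covered_m = {m for m, _ in pairs}
        covered_g = {g for _, g in pairs}
        features.extend(Feature("pair", pair) for pair in pairs)
        features.extend(Feature("miRNA", (m,)) for m in sorted(cm - covered_m))
        features.extend(Feature("gene", (g,)) for g in sorted(cg - covered_g))
    else:
        features.extend(Feature("miRNA", (m,)) for m in sorted(cm))
    return FeatureSet(lncrna, disease, tuple(features))


def feature_counts(network: HeteroNetwork, feature: Feature,
                   excluded_edge: Optional[Edge] = None) -> FeatureCounts:
    """Count known/unknown associations among the pairs adjacent to a feature."""
    empty: frozenset[str] = frozenset()
    if feature.kind == "miRNA":
        (m,) = feature.members
        lncs = network.lncrnas_of_mirna.get(m, empty)
        diss = network.diseases_of_mirna.get(m, empty)
    elif feature.kind == "gene":
        (g,) = feature.members
        lncs = network.lncrnas_of_gene.get(g, empty)
        diss = network.diseases_of_gene.get(g, empty)
    else:
        m, g = feature.members
        lncs = (network.lncrnas_of_mirna.get(m, empty)
                & network.lncrnas_of_gene.get(g, empty))
        diss = (network.diseases_of_mirna.get(m, empty)
                & network.diseases_of_gene.get(g, empty))
    known = set(network.ldn.edges)
    known.discard(excluded_edge)
    n_plus = sum(1 for l, d in known if l in lncs and d in diss)
    n_l, n_d = len(lncs), len(diss)
    return FeatureCounts(n_plus=n_plus, n_minus=n_l * n_d - n_plus, n_l=n_l, n_d=n_d)


def score_pair(network: HeteroNetwork, lncrna: str, disease: str,
               prior: Optional[PriorOdds] = None,
               excluded_edge: Optional[Edge] = None) -> float:
    """Raw posterior-odds score of one candidate pair.

    With no common neighbours the score is the bare prior odds phi; with no
    known associations at all, phi = 0 and so is the score.  In the
    degenerate saturated case (every pair already known) the odds are
    infinite and so is the score.
    """
    if prior is None:
        prior = prior_odds(network, excluded_edge=excluded_edge)
    if prior.phi == 0:
        return 0.0
    if prior.p0 == 0:
        return math.inf
    score = prior.phi
    for feature in common_neighbors(network, lncrna, disease).features:
        counts = feature_counts(network, feature, excluded_edge=excluded_edge)
        score *= (counts.n_plus + 1) / (counts.n_minus + 1) / prior.phi
    return score


def _singleton_weights(adj_left: np.ndarray, adj_right: np.ndarray,
                       known: np.ndarray, log_phi: float) -> np.ndarray:
    """Per-feature log factor log((N+ + 1)/(N- + 1)) - log(phi).

    ``adj_left`` maps features to lncRNAs (features x n), ``adj_right``
    maps features to diseases (features x r).
    """
    n_l = adj_left.sum(axis=1)
    n_d = adj_right.sum(axis=1)
    n_plus = ((adj_left.astype(float) @ known) * adj_right).sum(axis=1)
    n_minus = n_l * n_d - n_plus
    if np.any(n_minus < 0):  # conservation guard; cannot trip by construction
        raise AssertionError("count conservation violated in vectorized scorer")
    return np.log((n_plus + 1.0) / (n_minus + 1.0)) - log_phi


def score_all(network: HeteroNetwork,
              excluded_edge: Optional[Edge] = None,
              prior: Optional[PriorOdds] = None) -> ScoreMatrix:
    """Raw posterior-odds scores for every lncRNA x disease pair.

    Vectorized equivalent of :func:`score_pair` over the full registry
    grid, computed in log space.  ``excluded_edge`` removes one known
    association from every count (prior, N+, N-) before scoring.
    """
    if prior is None:
        prior = prior_odds(network, excluded_edge=excluded_edge)
    n, r = network.n, network.r
    if prior.phi == 0:
        return ScoreMatrix(network.lncrnas, network.diseases, np.zeros((n, r)))
    if prior.p0 == 0:
        return ScoreMatrix(network.lncrnas, network.diseases,
                           np.full((n, r), np.inf))

    known = network.adj_ld.astype(float)
    if excluded_edge is not None and excluded_edge in network.ldn.edges:
        li = network.lnc_index[excluded_edge[0]]
        dj = network.dis_index[excluded_edge[1]]
        known[li, dj] = 0.0

    log_phi = math.log(prior.phi)
    lm = network.adj_lm  # lncRNA x miRNA
    md = network.adj_md  # miRNA x disease

    w_m = _singleton_weights(lm.T, md, known, log_phi)
    log_s = log_phi + np.einsum("lm,m,md->ld", lm.astype(float), w_m,
                                md.astype(float))

    if network.mode == "GN2" and network.p:
        gl = network.adj_gl  # gene x lncRNA
        gd = network.adj_gd  # gene x disease
        w_g = _singleton_weights(gl, gd, known, log_phi)
        log_s += np.einsum("gl,g,gd->ld", gl.astype(float), w_g, gd.astype(float))

        # Pair features: for each interacting (gene, miRNA), the pair is
        # active at (l, d) exactly where both members are common
        # neighbours; covered members lose their singleton contribution.
        cov_m: dict[int, np.ndarray] = {}
        cov_g: dict[int, np.ndarray] = {}
        for gi, mi in np.argwhere(network.adj_gm):
            l_adj = lm[:, mi] & gl[gi, :]
            d_adj = md[mi, :] & gd[gi, :]
            n_l, n_d = int(l_adj.sum()), int(d_adj.sum())
            n_plus = float(known[np.ix_(l_adj, d_adj)].sum())
            w_pair = math.log((n_plus + 1.0) / (n_l * n_d - n_plus + 1.0)) - log_phi
            active = np.outer(l_adj, d_adj)
            log_s += w_pair * active
            prev_m = cov_m.setdefault(mi, np.zeros((n, r), dtype=bool))
            prev_m |= active
            prev_g = cov_g.setdefault(gi, np.zeros((n, r), dtype=bool))
            prev_g |= active
        for mi, covered in cov_m.items():
            log_s -= w_m[mi] * covered
        for gi, covered in cov_g.items():
            log_s -= w_g[gi] * covered

    return ScoreMatrix(network.lncrnas, network.diseases, np.exp(log_s))


def normalize_scores(raw: ScoreMatrix, lambda_mode="auto") -> ScoreMatrix:
    """Log-normalize raw odds: S' = ln(S) / lambda.

    ``lambda_mode="auto"`` sets lambda to the largest |ln S| over positive
    entries (1 when that maximum is 0), which maps all normalized scores
    into [-1, 1]; a positive float fixes lambda instead.  Zero raw scores
    (possible only when there are no known associations) are assigned a
    sentinel one unit below the smallest finite normalized score so they
    rank strictly last.  Any positive lambda is a monotone rescaling, so
    rankings never depend on it.
    """
    values = raw.values
    if np.any(values < 0):
        raise ValueError("raw scores must be non-negative")
    positive = values > 0
    logs = np.log(values[positive])
    if lambda_mode == "auto":
        lam = float(np.max(np.abs(logs))) if logs.size else 1.0
        if lam == 0.0:
            lam = 1.0
    else:
        lam = float(lambda_mode)
        if lam <= 0:
            raise ValueError(f"lambda must be positive, got {lam}")
    out = np.empty_like(values)
    out[positive] = logs / lam
    sentinel = (float(out[positive].min()) if logs.size else 0.0) - 1.0
    out[~positive] = sentinel
    return ScoreMatrix(raw.lncrnas, raw.diseases, out, lam=lam)
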