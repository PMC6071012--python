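"""Leave-one-out cross-validation and top-k precision/recall evaluation.

LOOCV holds out each known lncRNA–disease association in turn, recomputes
every count (prior odds, per-feature N+/N-) on the remaining training
associations, and ranks the held-out pair among all candidate pairs not in
the training set.  The pooled AUC is the mean over rounds of the
Mann–Whitney round statistic (#negatives below the positive + half the
ties, over #negatives); 0.5 is the random-guess baseline.

The top-k protocol samples a seeded fraction of the known associations as
the training set, scores everything else, and reports precision, recall
and F1 of the top-k ranked candidates against the held-out associations.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .bayes import normalize_scores, score_all
from .meshsim import DEFAULT_DELTA, combine, similarity_matrix
from .network import ConfigurationError, DiseaseOntology, HeteroNetwork, ScoreMatrix

Edge = tuple[str, str]
Scorer = Callable[[HeteroNetwork, Optional[Edge]], ScoreMatrix]


def auc_from_ranks(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """Mann–Whitney AUC of positive over negative scores.

    Equals the exhaustive pair count (#(pos > neg) + 0.5 * #(pos == neg))
    divided by |pos| * |neg|, i.e. the area under the threshold-swept ROC
    with half credit for ties.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2
    return float(u / (pos.size * neg.size))


@dataclass(frozen=True)
class RoundRecord:
    """Outcome of one LOOCV round for a held-out association."""

    lncrna: str
    disease: str
    rank: float  # 1-based mid-rank among candidates
    n_negatives: int
    n_ties: int
    auc: float


@dataclass(eq=False)
class CVReport:
    """Summary of an LOOCV run: per-round records, pooled ROC and AUC."""

    rounds: list[RoundRecord]
    auc: float
    roc: np.ndarray  # (k, 2) array of (FPR, TPR) points
    mode: str
    use_sd: bool
    per_disease: bool
    lambda_mode: str

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "n_rounds": self.n_rounds,
            "mode": self.mode,
            "use_sd": self.use_sd,
            "per_disease": self.per_disease,
            "lambda_mode": self.lambda_mode,
        }

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        with open(outdir / "rounds.tsv", "w", encoding="utf-8") as fh:
            fh.write("lncRNA\tdisease\trank\tn_negatives\tn_ties\tauc\n")
            for rec in self.rounds:
                fh.write(f"{rec.lncrna}\t{rec.disease}\t{rec.rank:.10g}\t"
                         f"{rec.n_negatives}\t{rec.n_ties}\t{rec.auc:.10g}\n")
        with open(outdir / "roc.tsv", "w", encoding="utf-8") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in self.roc:
                fh.write(f"{fpr:.10g}\t{tpr:.10g}\n")


@dataclass(frozen=True)
class TopKReport:
    """Precision/recall/F1 of the top-k predictions under seeded training."""

    k: int
    precision: float
    recall: float
    f1: float
    seed: int
    train_fraction: float
    n_train: int
    n_held_out: int
    true_positives: int

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def topk_metrics(true_positives: int, k: int, n_held_out: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from top-k retrieval counts."""
    precision = true_positives / k
    recall = true_positives / n_held_out if n_held_out else 0.0
    denom = precision + recall
    f1 = 2 * precision * recall / denom if denom > 0 else 0.0
    return precision, recall, f1


def _network_view(network: HeteroNetwork, mode: str) -> HeteroNetwork:
    if mode == "GN1":
        return network.to_gn1()
    if mode == "GN2":
        if network.mode != "GN2":
            raise ConfigurationError("GN2 evaluation requires a GN2 network")
        return network
    raise ConfigurationError(f"unknown mode {mode!r}")


def _pipeline_scores(network: HeteroNetwork, excluded_edge: Optional[Edge],
                     scorer: Scorer, lambda_mode,
                     sim) -> np.ndarray:
    raw = scorer(network, excluded_edge)
    mat = normalize_scores(raw, lambda_mode)
    if sim is not None:
        mat = combine(mat, sim)
    return mat.values


def loocv(network: HeteroNetwork,
          mode: str = "GN1",
          use_sd: bool = False,
          ontology: Optional[DiseaseOntology] = None,
          delta: float = DEFAULT_DELTA,
          lambda_mode="auto",
          per_disease: bool = False,
          scorer: Scorer = score_all) -> CVReport:
    """Leave-one-out cross-validation of the posterior-odds scorer.

    Each known association is removed in turn; counts and prior are
    recomputed without it, scores are normalized (and re-weighted by
    disease semantic similarity when ``use_sd``), and the held-out pair is
    ranked against the candidate pairs outside the training positives —
    globally by default, or within the held-out disease's column when
    ``per_disease``.  ``scorer`` is injectable for testing.
    """
    net = _network_view(network, mode)
    known = sorted(net.ldn.edges)
    if len(known) < 2:
        raise ValueError("LOOCV needs at least 2 known associations")
    sim = None
    if use_sd:
        if ontology is None:
            raise ConfigurationError("use_sd requires a disease ontology")
        sim = similarity_matrix(ontology, net.diseases, delta)

    known_mask = net.adj_ld
    rounds = []
    for edge in known:
        values = _pipeline_scores(net, edge, scorer, lambda_mode, sim)
        i = net.lnc_index[edge[0]]
        j = net.dis_index[edge[1]]
        candidate = ~known_mask
        candidate = candidate.copy()
        candidate[i, j] = False  # held-out positive is not its own negative
        if per_disease:
            mask = np.zeros_like(candidate)
            mask[:, j] = candidate[:, j]
            candidate = mask
        negatives = values[candidate]
        positive = values[i, j]
        n_neg = negatives.size
        if n_neg == 0:
            raise ValueError("no candidate negatives in LOOCV round")
        n_above = int((negatives > positive).sum())
        n_ties = int((negatives == positive).sum())
        auc_round = ((n_neg - n_above - n_ties) + 0.5 * n_ties) / n_neg
        rounds.append(RoundRecord(
            lncrna=edge[0], disease=edge[1],
            rank=1 + n_above + 0.5 * n_ties,
            n_negatives=n_neg, n_ties=n_ties, auc=auc_round,
        ))

    auc = float(np.mean([rec.auc for rec in rounds]))
    fprs = np.sort([1.0 - rec.auc for rec in rounds])
    n = len(fprs)
    roc = np.vstack([
        [0.0, 0.0],
        np.column_stack([fprs, np.arange(1, n + 1) / n]),
        [1.0, 1.0],
    ])
    return CVReport(rounds=rounds, auc=auc, roc=roc, mode=mode, use_sd=use_sd,
                    per_disease=per_disease, lambda_mode=str(lambda_mode))


def f1_at_k(network: HeteroNetwork,
            k: int,
            mode: str = "GN1",
            train_fraction: float = 0.2,
            seed: int = 0,
            use_sd: bool = False,
            ontology: Optional[DiseaseOntology] = None,
            delta: float = DEFAULT_DELTA,
            lambda_mode="auto",
            scorer: Scorer = score_all) -> TopKReport:
    """Top-k F1 with a seeded random training subset of the known associations.

    ``ceil(train_fraction * |known|)`` associations become the training
    set; the network is scored with only those as known, and the top-k
    candidates (score descending, ties broken by lncRNA then disease name)
    are compared against the held-out associations.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not 0 < train_fraction <= 1:
        raise ValueError(f"train_fraction must be in (0, 1], got {train_fraction}")
    net = _network_view(network, mode)
    known = sorted(net.ldn.edges)
    if not known:
        raise ValueError("no known associations to sample from")
    rng = np.random.default_rng(seed)
    n_train = max(1, math.ceil(train_fraction * len(known)))
    train_idx = rng.choice(len(known), size=n_train, replace=False)
    train = {known[i] for i in train_idx}
    held_out = set(known) - train
    tnet = net.with_ldn(train)
    sim = None
    if use_sd:
        if ontology is None:
            raise ConfigurationError("use_sd requires a disease ontology")
        sim = similarity_matrix(ontology, net.diseases, delta)
    values = _pipeline_scores(tnet, None, scorer, lambda_mode, sim)
    candidates = [
        (lnc, dis, values[i, j])
        for i, lnc in enumerate(net.lncrnas)
        for j, dis in enumerate(net.diseases)
        if (lnc, dis) not in train
    ]
    candidates.sort(key=lambda row: (-row[2], row[0], row[1]))
    top = candidates[:k]
    tp = sum(1 for lnc, dis, _ in top if (lnc, dis) in held_out)
    precision, recall, f1 = topk_metrics(tp, k, len(held_out))
    return TopKReport(k=k, precision=precision, recall=recall, f1=f1,
                      seed=seed, train_fraction=train_fraction,
                      n_train=n_train, n_held_out=len(held_out),
                      true_positives=tp)
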