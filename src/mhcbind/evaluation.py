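"""Evaluation protocols: AUC, best-F1, per-allele reports, bootstrap
stability, leave-one-allele-out generalization and peptidome scoring.

AUC is the Mann–Whitney statistic P(score_pos > score_neg) + half credit for
ties. Per-allele reporting applies the eligibility rule used throughout:
an allele is evaluated only with >= 30 records of which >= 5 are positive
and >= 5 negative. Best F1 scans every distinct observed score as a
threshold (predict positive when score >= threshold), breaking value ties
toward the higher threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

MIN_RECORDS = 30
MIN_POSITIVES = 5
MIN_NEGATIVES = 5


@dataclass
class ScoredSet:
    scores: np.ndarray
    labels: np.ndarray
    alleles: list[str] | None = None
    peptides: list[str] | None = None
    folds: np.ndarray | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must be parallel")
        if self.scores.size == 0:
            raise ValueError("scored set is empty")


def auc(s: ScoredSet | None = None, *, scores=None, labels=None) -> float:
    if s is not None:
        scores, labels = s.scores, s.labels
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def best_f1(s: ScoredSet | None = None, *, scores=None, labels=None
            ) -> tuple[float, float]:
    """(best F1, threshold). Vectorized scan over distinct scores, descending:
    at threshold t, predictions are score >= t."""
    if s is not None:
        scores, labels = s.scores, s.labels
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if len(np.unique(labels)) < 2:
        raise ValueError("best F1 undefined: only one class present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    # index of the last occurrence of each distinct score
    last = np.nonzero(np.diff(sorted_scores, append=-np.inf))[0]
    tp = np.cumsum(sorted_labels)[last]
    npred = last + 1.0
    p_total = labels.sum()
    f1 = 2.0 * tp / (npred + p_total)
    best = int(np.argmax(f1))  # argmax takes the first max = highest threshold
    return float(f1[best]), float(sorted_scores[last[best]])


@dataclass
class EvaluationReport:
    overall_auc: float
    overall_f1: float
    f1_threshold: float
    per_allele: pd.DataFrame = field(default_factory=pd.DataFrame)
    bootstrap_cv: float | None = None

    @property
    def n_eligible(self) -> int:
        return int(self.per_allele["eligible"].sum()) if len(self.per_allele) else 0


def per_allele_report(s: ScoredSet) -> EvaluationReport:
    """Group by allele, apply the 30/5/5 eligibility rule, and report AUC for
    the eligible alleles. With fold identifiers present, each eligible
    allele's AUC is the mean over folds where both classes occur; otherwise
    the pooled AUC is reported and flagged in the `pooled` column."""
    if s.alleles is None:
        raise ValueError("per-allele report requires allele names")
    df = pd.DataFrame({"allele": s.alleles, "score": s.scores,
                       "label": s.labels})
    if s.folds is not None:
        df["fold"] = s.folds
    rows = []
    for allele, g in df.groupby("allele", sort=True):
        n, n_pos = len(g), int(g["label"].sum())
        n_neg = n - n_pos
        eligible = (n >= MIN_RECORDS and n_pos >= MIN_POSITIVES
                    and n_neg >= MIN_NEGATIVES)
        allele_auc = np.nan
        pooled = True
        if eligible:
            if "fold" in g:
                fold_aucs = [auc(scores=fg["score"], labels=fg["label"])
                             for _, fg in g.groupby("fold")
                             if fg["label"].nunique() == 2]
                if fold_aucs:
                    allele_auc = float(np.mean(fold_aucs))
                    pooled = False
            if np.isnan(allele_auc):
                allele_auc = auc(scores=g["score"], labels=g["label"])
        rows.append({"allele": allele, "n": n, "n_pos": n_pos, "n_neg": n_neg,
                     "eligible": eligible, "auc": allele_auc, "pooled": pooled})
    overall_auc = auc(scores=s.scores, labels=s.labels)
    f1, thr = best_f1(scores=s.scores, labels=s.labels)
    return EvaluationReport(overall_auc, f1, thr, pd.DataFrame(rows))


def bootstrap_auc_cv(s: ScoredSet, n_boot: int = 100, frac: float = 0.8,
                     seed: int | None = None) -> float:
    """Coefficient of variation (sd/mean) of AUC over bootstrap resamples of
    ceil(frac*N) records drawn with replacement. Resamples missing a class
    are redrawn so exactly n_boot AUCs enter the statistic."""
    rng = np.random.default_rng(seed)
    n = len(s.scores)
    m = int(np.ceil(frac * n))
    aucs = []
    while len(aucs) < n_boot:
        idx = rng.integers(0, n, size=m)
        lab = s.labels[idx]
        if lab.min() == lab.max():
            continue
        aucs.append(auc(scores=s.scores[idx], labels=lab))
    aucs = np.asarray(aucs)
    return float(aucs.std(ddof=1) / aucs.mean())


def peptidome_score(ensemble, sample, training_peptides: set[str] = frozenset()
                    ) -> ScoredSet:
    """Max-over-alleles scoring of an individual's peptidome.

    Each peptide's score is the maximum ensemble binding probability over the
    individual's typed alleles. Peptides overlapping the training data are
    removed before scoring to keep the evaluation independent.
    """
    positives = [p for p in sample.positives if p not in training_peptides]
    negatives = [p for p in sample.negatives if p not in training_peptides]
    if not positives or not negatives:
        raise ValueError("peptidome sample has no usable records after "
                         "training-overlap removal")
    peptides = positives + negatives
    labels = np.array([1] * len(positives) + [0] * len(negatives))
    scores = np.zeros(len(peptides))
    for allele in sample.alleles:
        allele_scores = ensemble.predict_proba_pairs(peptides,
                                                     [allele] * len(peptides))
        scores = np.maximum(scores, allele_scores)
    return ScoredSet(scores, labels, alleles=None, peptides=peptides)


def leave_one_allele_out(ds, allele: str, *, estimator_params: dict,
                         n_restarts: int = 5, seed: int = 0,
                         true_labels: dict | None = None) -> float:
    """Mean held-out-allele AUC over `n_restarts` random initializations.

    Trains on every record of the other alleles and scores all records of
    the omitted allele. `true_labels` optionally supplies noise-free labels
    keyed by (peptide, allele) for scoring (training always uses the
    dataset's own labels).
    """
    from .model import BindingClassifier

    df = ds.to_frame()
    held = df[df["allele"] == allele]
    train = df[df["allele"] != allele]
    if held.empty:
        raise ValueError(f"allele {allele!r} not present in dataset")
    eval_labels = held["label"].to_numpy()
    if true_labels is not None:
        eval_labels = np.array([true_labels[(p, allele)]
                                for p in held["peptide"]])
    if eval_labels.min() == eval_labels.max():
        raise ValueError(f"AUC undefined: held-out allele {allele!r} has a "
                         "single class")
    X_train = train[["peptide", "allele"]].to_numpy()
    y_train = train["label"].to_numpy()
    X_held = held[["peptide", "allele"]].to_numpy()
    params = dict(estimator_params)
    if params.get("mhc_repr") == "one_hot_allele":
        # baseline: the held-out allele is registered but untrained, so its
        # identity embedding carries no information
        params["known_alleles"] = [allele]
    aucs = []
    for restart in range(n_restarts):
        clf = BindingClassifier(**{**params,
                                   "random_state": seed + 1000 * restart})
        clf.fit(X_train, y_train)
        scores = clf.predict_proba(X_held)[:, 1]
        aucs.append(auc(scores=scores, labels=eval_labels))
    return float(np.mean(aucs))


def write_report(report: EvaluationReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"overall_auc\t{report.overall_auc:.6f}\n")
        fh.write(f"overall_best_f1\t{report.overall_f1:.6f}\n")
        fh.write(f"f1_threshold\t{report.f1_threshold:.6f}\n")
        if report.bootstrap_cv is not None:
            fh.write(f"bootstrap_auc_cv\t{report.bootstrap_cv:.6f}\n")
        fh.write(f"eligible_alleles\t{report.n_eligible}\n")
    if len(report.per_allele):
        report.per_allele.to_csv(str(path) + ".per_allele.tsv", sep="\t",
                                 index=False)
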