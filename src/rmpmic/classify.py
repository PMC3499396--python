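"""End-to-end siRNA classification, evaluation metrics and the resampling
protocol.

Pipeline: profile all sequences (labelled training + unlabelled queries)
under the three Markov chains fitted to the effective training sequences,
build mini-clusters on one feature (Q4 by default), label clusters from the
known training labels, merge uncertain clusters into their nearest
determined cluster, and read each query's label off its cluster.

Two "specificity" flavours are reported: the conventional true-negative
rate TN/(TN+FP), and the precision-style fraction TP/(TP+FP) of predicted
effectives that really are effective — the latter is the headline metric in
this problem domain (a design tool's shortlist should be mostly real hits),
reported alongside the predicted-effective total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cluster import build_mini_clusters, label_clusters, merge_uncertain
from .markov import (PositionalMarkovChain, VALID_ORDERS, fit_markov,
                     profile_sequences)
from .records import EFFECTIVE, INEFFECTIVE, SequenceRecord, as_sequences

FEATURES = ("q1", "q2", "q3", "q4")


def _feature_values(models: Mapping[int, PositionalMarkovChain],
                    seqs: Sequence[str], feature: str) -> list[float]:
    feature = feature.lower()
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}, got {feature!r}")
    profiles = profile_sequences(models, seqs)
    return [p[feature] for p in profiles]


def classify(models: Mapping[int, PositionalMarkovChain],
             training: Sequence[SequenceRecord | str],
             training_labels: Mapping[int, str],
             queries: Sequence[SequenceRecord | str],
             feature: str = "q4") -> dict[int, str]:
    """Predict effective/ineffective for every query sequence.

    ``training_labels`` maps indices into ``training`` to known labels;
    the returned mapping is keyed by index into ``queries``.
    """
    if not queries:
        return {}
    train_seqs = as_sequences(training)
    query_seqs = as_sequences(queries)
    all_seqs = train_seqs + query_seqs
    values = _feature_values(models, all_seqs, feature)
    clustering = build_mini_clusters(values)
    clustering = label_clusters(clustering, dict(training_labels))
    clustering = merge_uncertain(clustering, values)
    labels = clustering.labels()
    n0 = len(train_seqs)
    return {i: labels[n0 + i] for i in range(len(query_seqs))}


@dataclass
class EvaluationResult:
    """Confusion counts and derived rates for an effective/ineffective call.

    ``paper_specificity`` is precision, TP / (TP + FP) = TP / Total, where
    Total is the number of sequences predicted effective;
    ``specificity_true`` is the conventional TN / (TN + FP).
    """

    n_effective: int
    n_ineffective: int
    true_positives: int
    false_positives: int
    false_negatives: int
    true_negatives: int

    @property
    def total_predicted_effective(self) -> int:
        return self.true_positives + self.false_positives

    @property
    def sensitivity(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 0.0

    @property
    def specificity_true(self) -> float:
        d = self.true_negatives + self.false_positives
        return self.true_negatives / d if d else 0.0

    @property
    def paper_specificity(self) -> float:
        d = self.total_predicted_effective
        return self.true_positives / d if d else 0.0

    def as_dict(self) -> dict:
        return {"n_effective": self.n_effective,
                "n_ineffective": self.n_ineffective,
                "total_predicted_effective": self.total_predicted_effective,
                "true_positives": self.true_positives,
                "false_positives": self.false_positives,
                "false_negatives": self.false_negatives,
                "true_negatives": self.true_negatives,
                "sensitivity": self.sensitivity,
                "specificity_true": self.specificity_true,
                "paper_specificity": self.paper_specificity}


def round_percent(fraction: float, decimals: int = 2) -> float:
    """Fraction -> percentage rounded half-up (matching report formatting)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def evaluate(predictions: Mapping[int, str],
             truth: Mapping[int, str]) -> EvaluationResult:
    """Confusion counts of predicted vs true effective/ineffective labels.

    Every predicted index must be covered by ``truth``; order-independent.
    """
    tp = fp = fn = tn = 0
    for i, pred in predictions.items():
        if i not in truth:
            raise KeyError(f"prediction index {i} missing from truth")
        t = truth[i]
        if t == EFFECTIVE:
            tp += pred == EFFECTIVE
            fn += pred != EFFECTIVE
        elif t == INEFFECTIVE:
            fp += pred == EFFECTIVE
            tn += pred != EFFECTIVE
        else:
            raise ValueError(f"truth label for {i} must be "
                             f"effective/ineffective, got {t!r}")
    return EvaluationResult(n_effective=tp + fn, n_ineffective=fp + tn,
                            true_positives=tp, false_positives=fp,
                            false_negatives=fn, true_negatives=tn)


class MiniClusterClassifier(BaseEstimator, ClassifierMixin):
    """Transductive effective/ineffective classifier for siRNA sequences.

    ``fit`` stores the labelled training sequences and estimates the three
    Markov chains (orders 1-3) from the *effective* ones only.  ``predict``
    profiles training + query sequences together, mini-clusters the chosen
    feature, labels clusters from the training labels and merges uncertain
    clusters — so predictions depend on the whole query batch, as in any
    transductive method.

    Parameters
    ----------
    feature : {"q1", "q2", "q3", "q4"}, default "q4"
        Clustering feature; Q4 is the relative mean probability.
    pseudocount : float, default 0.0
        Additive smoothing for the Markov chains.
    position_specific : bool, default True
        Per-position (inhomogeneous) conditionals vs pooled.
    use_ineffective_labels : bool, default True
        Whether ineffective training sequences contribute known labels to
        the clusters (switch them off to label from effectives alone).

    Attributes
    ----------
    classes_ : ndarray — ["effective", "ineffective"]
    models_ : dict[int, PositionalMarkovChain]
    train_seqs_, train_labels_ : training data retained for transduction

    Examples
    --------
    >>> clf = MiniClusterClassifier().fit(
    ...     ["UAAUC", "UACCG", "CGAUC", "GGGGG"],
    ...     ["effective", "effective", "effective", "ineffective"])
    >>> clf.predict(["UAACG"])[0] in ("effective", "ineffective")
    True
    """

    def __init__(self, feature: str = "q4", pseudocount: float = 0.0,
                 position_specific: bool = True,
                 use_ineffective_labels: bool = True):
        self.feature = feature
        self.pseudocount = pseudocount
        self.position_specific = position_specific
        self.use_ineffective_labels = use_ineffective_labels

    @staticmethod
    def _canon_labels(y) -> list[str]:
        out = []
        for lab in y:
            if isinstance(lab, str):
                lab = lab.lower()
                if lab not in (EFFECTIVE, INEFFECTIVE):
                    raise ValueError(f"unrecognised label {lab!r}")
                out.append(lab)
            else:
                out.append(EFFECTIVE if lab else INEFFECTIVE)
        return out

    def fit(self, X: Sequence[SequenceRecord | str], y) -> "MiniClusterClassifier":
        seqs = as_sequences(X)
        labels = self._canon_labels(y)
        if len(seqs) != len(labels):
            raise ValueError("X and y length mismatch")
        effective = [s for s, lab in zip(seqs, labels) if lab == EFFECTIVE]
        if not effective:
            raise ValueError("training set contains no effective sequences; "
                             "the Markov chains are estimated from effectives")
        self.models_ = {h: fit_markov(effective, h, self.pseudocount,
                                      self.position_specific)
                        for h in VALID_ORDERS}
        self.train_seqs_ = seqs
        self.train_labels_ = labels
        self.classes_ = np.array([EFFECTIVE, INEFFECTIVE])
        return self

    def _known(self) -> dict[int, str]:
        return {i: lab for i, lab in enumerate(self.train_labels_)
                if lab == EFFECTIVE or self.use_ineffective_labels}

    def predict(self, X: Sequence[SequenceRecord | str]) -> np.ndarray:
        check_is_fitted(self, "models_")
        preds = classify(self.models_, self.train_seqs_, self._known(),
                         X, self.feature)
        return np.array([preds[i] for i in range(len(list(X)))], dtype=object)

    def transform_values(self, X: Sequence[SequenceRecord | str]) -> list[float]:
        """The clustering feature value per sequence (diagnostic helper)."""
        check_is_fitted(self, "models_")
        return _feature_values(self.models_, as_sequences(X), self.feature)


@dataclass
class ResampleSummary:
    """Mean miscall counts across resampled training sets.

    ``mean_missed_effective`` — held-out effective sequences called
    ineffective (false negatives), averaged over repeats;
    ``mean_misidentified_ineffective`` — ineffective sequences landing in
    effective clusters (false positives), averaged over repeats.
    """

    repeats: int
    n_train_effective: int
    n_heldout_effective: int
    n_ineffective: int
    mean_missed_effective: float
    mean_misidentified_ineffective: float
    per_repeat_missed: list[int] = field(default_factory=list)
    per_repeat_misidentified: list[int] = field(default_factory=list)

    @property
    def heldout_error_rate(self) -> float:
        return self.mean_missed_effective / self.n_heldout_effective


def resample_protocol(effective: Sequence[SequenceRecord | str],
                      ineffective: Sequence[SequenceRecord | str],
                      fraction: float = 0.8,
                      repeats: int = 1000,
                      seed: int | None = None,
                      feature: str = "q4",
                      pseudocount: float = 0.0,
                      use_ineffective_labels: bool = True) -> ResampleSummary:
    """Repeated holdout validation of the mini-cluster pipeline.

    Each repeat draws ``floor(fraction * n_effective)`` effective sequences
    without replacement; these train the Markov chains and provide the known
    effective labels (all ineffective sequences keep known labels unless
    ``use_ineffective_labels`` is off).  The held-out effective sequences
    are classified and miscalls counted; means are taken across repeats.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    eff = as_sequences(effective)
    ineff = as_sequences(ineffective)
    n_train = int(np.floor(fraction * len(eff)))
    if n_train == 0 or n_train == len(eff):
        raise ValueError(
            f"fraction {fraction} leaves an empty train or test split "
            f"({n_train} of {len(eff)} effective sequences in training)")

    rng = np.random.default_rng(seed)
    missed, misid = [], []
    for _ in range(repeats):
        idx = rng.permutation(len(eff))
        train_eff = [eff[i] for i in idx[:n_train]]
        heldout = [eff[i] for i in idx[n_train:]]
        models = {h: fit_markov(train_eff, h, pseudocount)
                  for h in VALID_ORDERS}
        # one clustering over every sequence in play
        all_seqs = train_eff + ineff + heldout
        known = {i: EFFECTIVE for i in range(len(train_eff))}
        if use_ineffective_labels:
            known.update({len(train_eff) + i: INEFFECTIVE
                          for i in range(len(ineff))})
        values = _feature_values(models, all_seqs, feature)
        clustering = merge_uncertain(
            label_clusters(build_mini_clusters(values), known), values)
        labels = clustering.labels()
        n0 = len(train_eff) + len(ineff)
        missed.append(sum(1 for i in range(n0, len(all_seqs))
                          if labels[i] != EFFECTIVE))
        misid.append(sum(1 for i in range(len(train_eff), n0)
                         if labels[i] == EFFECTIVE))
    return ResampleSummary(
        repeats=repeats, n_train_effective=n_train,
        n_heldout_effective=len(eff) - n_train, n_ineffective=len(ineff),
        mean_missed_effective=float(np.mean(missed)),
        mean_misidentified_ineffective=float(np.mean(misid)),
        per_repeat_missed=missed, per_repeat_misidentified=misid)
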