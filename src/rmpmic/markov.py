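"""Position-specific (inhomogeneous) Markov chain models of siRNA sequences.

The scoring model is a fixed-order Markov chain estimated from *effective*
siRNAs only.  For order ``h`` the probability of a length-``L`` sequence
``x = x_1 ... x_L`` is

    Q_h(x) = Pr(x_1 ... x_h) * prod_{j=h+1..L} Pr(x_j | x_{j-h} ... x_{j-1})

where the initial term is the relative frequency of the leading h-mer in the
training set and every conditional is estimated *per position* (position 2
may behave differently from position 19 — effective siRNAs carry positional
nucleotide preferences, which is exactly what the model is meant to capture).
A pooled (homogeneous) variant is available for comparison.

Three such models, of orders 1, 2 and 3, are combined into the *relative
mean probability*

    Q_4 = (Q_1 + Q_2 + Q_3) / (1[Q_1>0] + 1[Q_2>0] + 1[Q_3>0]),

the arithmetic mean of the chain probabilities that are non-zero (zero by
convention when all three vanish).  Zero probabilities are informative —
they flag sequences whose leading h-mer or some positional transition never
occurs among effective siRNAs — so no smoothing is applied by default; an
optional pseudocount is provided for robustness studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .records import RNA_ALPHABET, SequenceRecord, as_sequences

VALID_ORDERS = (1, 2, 3)


class EmptyTrainingError(ValueError):
    """Raised when a model is fit on an empty training set."""


class HeterogeneousLengthError(ValueError):
    """Raised when training sequences do not share a single length."""


class OrderError(ValueError):
    """Raised for a Markov order outside {1, 2, 3}."""


class LengthMismatchError(ValueError):
    """Raised when a scored sequence does not match the model length."""


@dataclass
class ProbabilityProfile:
    """Per-sequence chain probabilities Q1-Q3 and their relative mean Q4."""

    q1: float
    q2: float
    q3: float
    q4: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.q1, self.q2, self.q3, self.q4)

    def __getitem__(self, feature: str) -> float:
        return getattr(self, feature.lower())


class PositionalMarkovChain:
    """An order-h Markov chain with per-position conditional distributions.

    Parameters
    ----------
    order : int
        Chain order h, one of {1, 2, 3}.
    length : int
        Sequence length L the model was trained for (L > h).
    initial : mapping
        ``{h-mer: probability}`` for the leading positions 1..h.  Only
        h-mers observed in training (or smoothed) appear; anything absent
        has probability ``unseen_initial``.
    transitions : mapping
        ``{position: {context: {base: probability}}}`` for 1-based positions
        h+1..L (a single shared table under key ``0`` when the model is
        pooled across positions).  Contexts never observed at a position
        have conditional probability 0 for every base when the pseudocount
        is 0, and 1/4 for every base otherwise.
    pseudocount : float
        Additive smoothing mass per (context, base) cell; 0 disables
        smoothing.
    position_specific : bool
        Whether conditionals are estimated per position (default) or pooled.
    n_train : int
        Number of training sequences (needed to score unseen leading h-mers
        under smoothing).
    """

    def __init__(self, order: int, length: int,
                 initial: Mapping[str, float],
                 transitions: Mapping[int, Mapping[str, Mapping[str, float]]],
                 pseudocount: float = 0.0,
                 position_specific: bool = True,
                 n_train: int = 0) -> None:
        if order not in VALID_ORDERS:
            raise OrderError(f"order must be one of {VALID_ORDERS}, got {order}")
        self.order = order
        self.length = length
        self.initial = dict(initial)
        self.transitions = {int(p): {c: dict(b) for c, b in t.items()}
                            for p, t in transitions.items()}
        self.pseudocount = float(pseudocount)
        self.position_specific = bool(position_specific)
        self.n_train = int(n_train)

    # -- probabilities for events unseen in training ----------------------
    @property
    def unseen_initial(self) -> float:
        if self.pseudocount <= 0.0:
            return 0.0
        k = 4 ** self.order
        return self.pseudocount / (self.n_train + self.pseudocount * k)

    @property
    def unseen_conditional(self) -> float:
        return 0.25 if self.pseudocount > 0.0 else 0.0

    def _table(self, position: int) -> Mapping[str, Mapping[str, float]]:
        return self.transitions[position if self.position_specific else 0]

    def conditional(self, position: int, context: str, base: str) -> float:
        """Pr(base | context) at a 1-based position in h+1..L."""
        table = self._table(position)
        if context not in table:
            return self.unseen_conditional
        return table[context].get(base, 0.0)

    def sequence_probability(self, seq: str | SequenceRecord) -> float:
        """Chain probability of one sequence; 0 if any factor is 0."""
        s = seq.seq if isinstance(seq, SequenceRecord) else seq
        if len(s) != self.length:
            raise LengthMismatchError(
                f"sequence length {len(s)} != model length {self.length}")
        h = self.order
        p = self.initial.get(s[:h], self.unseen_initial)
        for j in range(h + 1, self.length + 1):  # 1-based positions
            if p == 0.0:
                return 0.0
            p *= self.conditional(j, s[j - 1 - h:j - 1], s[j - 1])
        return p

    # -- JSON serialization -----------------------------------------------
    def to_dict(self) -> dict:
        rows = []
        for pos in sorted(self.transitions):
            for context in sorted(self.transitions[pos]):
                for base in sorted(self.transitions[pos][context]):
                    rows.append({"position": pos, "context": context,
                                 "base": base,
                                 "prob": self.transitions[pos][context][base]})
        return {"order": self.order, "length": self.length,
                "pseudocount": self.pseudocount,
                "position_specific": self.position_specific,
                "n_train": self.n_train,
                "initial": dict(sorted(self.initial.items())),
                "transitions": rows}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PositionalMarkovChain":
        transitions: dict[int, dict[str, dict[str, float]]] = {}
        for row in d["transitions"]:
            pos = transitions.setdefault(int(row["position"]), {})
            pos.setdefault(row["context"], {})[row["base"]] = float(row["prob"])
        return cls(order=int(d["order"]), length=int(d["length"]),
                   initial=d["initial"], transitions=transitions,
                   pseudocount=float(d.get("pseudocount", 0.0)),
                   position_specific=bool(d.get("position_specific", True)),
                   n_train=int(d.get("n_train", 0)))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PositionalMarkovChain":
        return cls.from_dict(json.loads(text))


def fit_markov(training: Sequence[SequenceRecord | str], order: int,
               pseudocount: float = 0.0,
               position_specific: bool = True) -> PositionalMarkovChain:
    """Estimate an order-h chain from training sequences by relative frequency.

    The initial distribution is the relative frequency of the leading h-mer;
    the conditional at position j is the relative frequency of the base given
    the h preceding bases at that position.  With pseudocount p > 0 every
    (context, base) cell — including contexts never observed — receives p
    extra counts, so no valid sequence scores exactly zero.

    Raises
    ------
    OrderError, EmptyTrainingError, HeterogeneousLengthError
    """
    if order not in VALID_ORDERS:
        raise OrderError(f"order must be one of {VALID_ORDERS}, got {order}")
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be non-negative, got {pseudocount}")
    seqs = as_sequences(training)
    if not seqs:
        raise EmptyTrainingError("cannot fit a Markov model on an empty training set")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise HeterogeneousLengthError(
            f"training sequences have mixed lengths {sorted(lengths)}")
    length = lengths.pop()
    if length <= order:
        raise HeterogeneousLengthError(
            f"sequence length {length} must exceed the order {order}")

    h, n, p = order, len(seqs), float(pseudocount)

    init_counts: dict[str, float] = {}
    for s in seqs:
        init_counts[s[:h]] = init_counts.get(s[:h], 0.0) + 1.0
    if p > 0:  # smooth over the full 4^h h-mer space
        from itertools import product
        for hmer in product(RNA_ALPHABET, repeat=h):
            init_counts[''.join(hmer)] = init_counts.get(''.join(hmer), 0.0) + p
    denom = n + (p * 4 ** h if p > 0 else 0.0)
    initial = {k: v / denom for k, v in init_counts.items()}

    positions = range(h + 1, length + 1) if position_specific else (0,)
    counts: dict[int, dict[str, dict[str, float]]] = {pos: {} for pos in positions}
    for s in seqs:
        for j in range(h + 1, length + 1):
            key = j if position_specific else 0
            ctx, base = s[j - 1 - h:j - 1], s[j - 1]
            cell = counts[key].setdefault(ctx, {})
            cell[base] = cell.get(base, 0.0) + 1.0
    if p > 0:  # smooth observed AND unobserved contexts at every position
        from itertools import product
        all_ctx = [''.join(c) for c in product(RNA_ALPHABET, repeat=h)]
        for key in counts:
            for ctx in all_ctx:
                cell = counts[key].setdefault(ctx, {})
                for b in RNA_ALPHABET:
                    cell[b] = cell.get(b, 0.0) + p
    transitions: dict[int, dict[str, dict[str, float]]] = {}
    for key, table in counts.items():
        transitions[key] = {}
        for ctx, cell in table.items():
            tot = sum(cell.values())
            transitions[key][ctx] = {b: c / tot for b, c in cell.items()}

    return PositionalMarkovChain(order=order, length=length, initial=initial,
                                 transitions=transitions, pseudocount=p,
                                 position_specific=position_specific, n_train=n)


def sequence_probability(model: PositionalMarkovChain,
                         record: SequenceRecord | str) -> float:
    """Chain probability of ``record`` under ``model`` (see the class method)."""
    return model.sequence_probability(record)


def relative_mean_probability(q1: float, q2: float, q3: float) -> float:
    """Mean of the strictly positive chain probabilities; 0 if all are 0.

    The denominator counts how many of Q1..Q3 are non-zero, so a sequence
    that is impossible under, say, the order-3 model is not dragged to zero
    by it — only sequences impossible under *all* three models score 0.
    """
    qs = (float(q1), float(q2), float(q3))
    for q in qs:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"probabilities must lie in [0, 1], got {q}")
    k = sum(1 for q in qs if q > 0.0)
    return sum(qs) / k if k else 0.0


def profile_sequences(models: Mapping[int, PositionalMarkovChain],
                      records: Iterable[SequenceRecord | str],
                      ) -> list[ProbabilityProfile]:
    """Q1, Q2, Q3 and Q4 for every record, in input order.

    ``models`` maps each order in {1, 2, 3} to its fitted chain.
    """
    for order in VALID_ORDERS:
        if order not in models:
            raise OrderError(f"missing model of order {order}")
    out = []
    for seq in as_sequences(records):
        q1, q2, q3 = (models[h].sequence_probability(seq) for h in VALID_ORDERS)
        out.append(ProbabilityProfile(q1, q2, q3,
                                      relative_mean_probability(q1, q2, q3)))
    return out


def entropy_score(q4: float) -> float:
    """|ln Q4| — the sequence's entropy-style rarity score.

    Monotone decreasing in Q4; undefined at 0 (raise, callers may treat the
    limit as +infinity).
    """
    if not 0.0 < q4 <= 1.0:
        raise ValueError(f"entropy score requires q4 in (0, 1], got {q4}")
    return abs(math.log(q4))


class MarkovProfiler(BaseEstimator, TransformerMixin):
    """Transformer: sequences -> (Q1, Q2, Q3, Q4) feature matrix.

    Fits one Markov chain per order in ``orders`` on the training sequences
    (which should be the *effective* siRNAs) and transforms any sequence set
    of the same length into chain probabilities plus their relative mean.

    Parameters
    ----------
    pseudocount : float, default 0.0
        Additive smoothing; 0 keeps the informative zero probabilities.
    position_specific : bool, default True
        Per-position conditionals (inhomogeneous chain) vs pooled.

    Attributes
    ----------
    models_ : dict[int, PositionalMarkovChain]
        Fitted chains keyed by order.
    length_ : int
        Training sequence length.

    Examples
    --------
    >>> prof = MarkovProfiler().fit(["UAAUC", "UACCG", "CGAUC", "CGCCG"])
    >>> prof.transform(["UAAUC"]).shape
    (1, 4)
    """

    def __init__(self, pseudocount: float = 0.0, position_specific: bool = True):
        self.pseudocount = pseudocount
        self.position_specific = position_specific

    def fit(self, X: Sequence[SequenceRecord | str], y=None) -> "MarkovProfiler":
        seqs = as_sequences(X)
        self.models_ = {h: fit_markov(seqs, h, self.pseudocount,
                                      self.position_specific)
                        for h in VALID_ORDERS}
        self.length_ = self.models_[1].length
        return self

    def transform(self, X: Sequence[SequenceRecord | str]) -> np.ndarray:
        check_is_fitted(self, "models_")
        profiles = profile_sequences(self.models_, X)
        return np.array([p.as_tuple() for p in profiles], dtype=float).reshape(-1, 4)

    def get_feature_names_out(self, input_features=None):
        return np.array(["q1", "q2", "q3", "q4"])
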