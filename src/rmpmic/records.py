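"""Sequence records and input normalization.

An siRNA guide strand is modelled as a short RNA word, 19 nt by default
(the paired region of a canonical siRNA duplex).  Records carry an optional
measured knockdown efficiency (percent reduction of target expression) and
an efficacy label derived from it via a threshold, 80% by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

RNA_ALPHABET = ("A", "C", "G", "U")

EFFECTIVE = "effective"
INEFFECTIVE = "ineffective"
UNKNOWN = "unknown"
UNCERTAIN = "uncertain"

#: default knockdown-efficiency threshold (percent) above which an siRNA
#: is called effective
DEFAULT_THRESHOLD = 80.0

_TRANSLATE = str.maketrans("acgutT", "ACGUUU")


class SequenceAlphabetError(ValueError):
    """Sequence contains characters outside {A,C,G,U} (after T->U mapping)."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map DNA thymine to uracil, and reject anything else.

    Raises
    ------
    SequenceAlphabetError
        If any character is not one of A/C/G/U/T in either case.
    """
    out = seq.strip().translate(_TRANSLATE)
    bad = set(out) - set(RNA_ALPHABET)
    if bad:
        raise SequenceAlphabetError(
            f"illegal characters {sorted(bad)} in sequence {seq!r}"
        )
    return out


def label_from_efficiency(efficiency: float, threshold: float = DEFAULT_THRESHOLD,
                          inclusive: bool = True) -> str:
    """Efficacy label from a knockdown percentage.

    ``inclusive`` applies the threshold as ``>=`` (the siRNA convention);
    ``inclusive=False`` uses strict ``>`` (the shRNA score convention).
    """
    if inclusive:
        return EFFECTIVE if efficiency >= threshold else INEFFECTIVE
    return EFFECTIVE if efficiency > threshold else INEFFECTIVE


@dataclass
class SequenceRecord:
    """One siRNA/shRNA: identifier, normalized RNA sequence, optional efficacy.

    Parameters
    ----------
    id : str
        Unique identifier.
    seq : str
        Sequence over {A,C,G,U}; DNA input (T) and lowercase are normalized
        on construction.
    efficiency : float, optional
        Measured knockdown efficiency in percent, in [0, 100].
    label : str, optional
        One of "effective" / "ineffective" / "unknown".  If an efficiency is
        given and no label, the label is derived from ``threshold``.
    """

    id: str
    seq: str
    efficiency: float | None = None
    label: str = UNKNOWN
    threshold: float = field(default=DEFAULT_THRESHOLD, repr=False)

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq)
        if self.efficiency is not None:
            if not 0.0 <= float(self.efficiency) <= 100.0:
                raise ValueError(
                    f"efficiency {self.efficiency!r} outside [0, 100] for {self.id!r}"
                )
            self.efficiency = float(self.efficiency)
            if self.label == UNKNOWN:
                self.label = label_from_efficiency(self.efficiency, self.threshold)
        if self.label not in (EFFECTIVE, INEFFECTIVE, UNKNOWN):
            raise ValueError(f"unknown label {self.label!r} for {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


def as_sequences(records: Iterable[SequenceRecord | str]) -> list[str]:
    """Extract plain sequence strings from records or pass strings through."""
    out = []
    for r in records:
        out.append(normalize_sequence(r) if isinstance(r, str) else r.seq)
    return out


def common_length(seqs: Sequence[str]) -> int:
    """Shared length of a non-empty set of sequences.

    Raises ``ValueError`` on an empty set or heterogeneous lengths.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"heterogeneous sequence lengths {sorted(lengths)}")
    return lengths.pop()
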