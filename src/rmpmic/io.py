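"""Reading and writing sequence sets, models and reports.

Two input formats: FASTA (ids + sequences only) and a tab-separated
efficacy table with header columns ``id``, ``sequence`` and optionally
``efficiency`` (percent) and ``label``.  Sequences are normalized on read
(T -> U, uppercased); labels absent from a TSV are derived from the
efficiency and the threshold.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .classify import EvaluationResult, round_percent
from .cluster import Clustering
from .markov import PositionalMarkovChain
from .records import (DEFAULT_THRESHOLD, SequenceRecord, UNKNOWN,
                      SequenceAlphabetError)

TSV_COLUMNS = ("id", "sequence", "efficiency", "label")


class InputFormatError(ValueError):
    """Malformed input file (message carries the offending line/record)."""


class DuplicateIdError(InputFormatError):
    """Two records share an identifier."""


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: dict[str, int] = {}
    for k, r in enumerate(records, start=1):
        if r.id in seen:
            raise DuplicateIdError(
                f"duplicate id {r.id!r} (records {seen[r.id]} and {k})")
        seen[r.id] = k


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = []
    for k, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq)))
        except SequenceAlphabetError as e:
            raise InputFormatError(f"record {k} ({rec.id!r}): {e}") from e
    if not records:
        raise InputFormatError(f"no FASTA records found in {path}")
    _check_unique_ids(records)
    return records


def read_tsv(path: str | Path,
             threshold: float = DEFAULT_THRESHOLD) -> list[SequenceRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as e:
        raise InputFormatError(f"empty input file {path}") from e
    missing = {"id", "sequence"} - set(df.columns)
    if missing:
        raise InputFormatError(
            f"{path}: missing required TSV columns {sorted(missing)}")
    records = []
    for k, row in enumerate(df.itertuples(index=False), start=2):  # header=line 1
        eff = getattr(row, "efficiency", None)
        lab = getattr(row, "label", None)
        try:
            records.append(SequenceRecord(
                id=str(row.id), seq=str(row.sequence),
                efficiency=None if pd.isna(eff) or eff is None else float(eff),
                label=UNKNOWN if pd.isna(lab) or lab is None else str(lab),
                threshold=threshold))
        except (ValueError, SequenceAlphabetError) as e:
            raise InputFormatError(f"{path} line {k}: {e}") from e
    if not records:
        raise InputFormatError(f"no data rows in {path}")
    _check_unique_ids(records)
    return records


def read_sequences(path: str | Path, format: str | None = None,
                   threshold: float = DEFAULT_THRESHOLD) -> list[SequenceRecord]:
    """Read a sequence set, inferring the format from the extension if
    ``format`` (``"fasta"`` or ``"tsv"``) is not given."""
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".fna") \
            else "tsv"
    if format.lower() == "fasta":
        return read_fasta(path)
    if format.lower() == "tsv":
        return read_tsv(path, threshold=threshold)
    raise ValueError(f"unknown format {format!r} (expected fasta or tsv)")


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write([BioSeqRecord(Seq(r.seq), id=r.id, description="")
                 for r in records], str(path), "fasta")


def write_tsv(records: Iterable[SequenceRecord], path: str | Path) -> None:
    df = pd.DataFrame([{"id": r.id, "sequence": r.seq,
                        "efficiency": r.efficiency,
                        "label": r.label} for r in records],
                      columns=list(TSV_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def write_sequences(records: Sequence[SequenceRecord], path: str | Path,
                    format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".fna") \
            else "tsv"
    (write_fasta if format.lower() == "fasta" else write_tsv)(records, path)


# -- model bundles ---------------------------------------------------------

def save_models(models: Mapping[int, PositionalMarkovChain],
                path: str | Path) -> None:
    """Serialize the order-1..3 model bundle to one JSON document."""
    doc = {str(h): m.to_dict() for h, m in models.items()}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_models(path: str | Path) -> dict[int, PositionalMarkovChain]:
    doc = json.loads(Path(path).read_text())
    return {int(h): PositionalMarkovChain.from_dict(d) for h, d in doc.items()}


# -- reports ---------------------------------------------------------------

def assignments_frame(ids: Sequence[str], values: Sequence[float],
                      clustering: Clustering) -> pd.DataFrame:
    """Cluster assignment table: id, value, cluster_id (1-based), label."""
    return pd.DataFrame({
        "id": list(ids),
        "value": list(values),
        "cluster_id": [c + 1 for c in clustering.assignments()],
        "cluster_label": clustering.labels(),
    })


def metrics_row(algorithm: str, feature: str,
                result: EvaluationResult) -> dict:
    """One row of the standard report table."""
    return {"Algorithm": algorithm, "Feature": feature.upper(),
            "Total": result.total_predicted_effective,
            "Sensitivity(%)": round_percent(result.sensitivity),
            "Specificity(%)": round_percent(result.paper_specificity)}


def write_metrics(rows: Sequence[dict], tsv_path: str | Path | None = None,
                  json_path: str | Path | None = None) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if tsv_path is not None:
        df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(rows, indent=1))
    return df
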