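"""File formats: FASTA sequences, labeled pair lists, feature matrices and
prediction tables.

Pair lists are 3-column delimited text (tab or comma):
``id_a<SEP>id_b<SEP>label`` with label in {0, 1}; for prediction inputs the
label column may be omitted.  Predictions are written as TSV with columns
id_a, id_b, predicted_label, score and the per-class residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataValidationError

#: Default minimum protein length; shorter proteins are removed.
MIN_PROTEIN_LENGTH = 50


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier plus amino-acid sequence."""

    id: str
    sequence: str


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    Multi-line sequences are joined and whitespace stripped; duplicate ids
    and empty files raise :class:`DataValidationError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise DataValidationError(f"{path}: FASTA record with empty id")
        if rec.id in seen:
            raise DataValidationError(f"{path}: duplicate FASTA id {rec.id!r}")
        seq = str(rec.seq).replace(" ", "").strip()
        if not seq:
            raise DataValidationError(f"{path}: record {rec.id!r} has empty sequence")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise DataValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(Path(path)), "fasta")


def sequences_by_id(records: Iterable[ProteinRecord]) -> dict[str, str]:
    """Map protein id -> sequence."""
    return {r.id: r.sequence for r in records}


def read_pairs(
    path: str | Path,
    known_ids: set[str] | None = None,
    require_label: bool = True,
) -> list[tuple[str, str, int | None]]:
    """Parse a pair list file into (id_a, id_b, label) tuples.

    Tab- or comma-separated; a header line starting with ``id_a`` is
    skipped.  Errors (wrong column count, non-binary label, unknown id
    against ``known_ids``) report the 1-based line number.
    """
    path = Path(path)
    pairs: list[tuple[str, str, int | None]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            sep = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(sep)]
            if lineno == 1 and fields[0].lower() in ("id_a", "ida", "protein_a"):
                continue
            if len(fields) == 2 and not require_label:
                id_a, id_b, label = fields[0], fields[1], None
            elif len(fields) == 3:
                id_a, id_b, raw_label = fields
                if raw_label not in ("0", "1"):
                    raise DataValidationError(
                        f"{path}:{lineno}: label must be 0 or 1, got {raw_label!r}"
                    )
                label = int(raw_label)
            else:
                raise DataValidationError(
                    f"{path}:{lineno}: expected "
                    f"{'3' if require_label else '2 or 3'} columns, "
                    f"got {len(fields)}"
                )
            if known_ids is not None:
                for pid in (id_a, id_b):
                    if pid not in known_ids:
                        raise DataValidationError(
                            f"{path}:{lineno}: id {pid!r} not found in FASTA set"
                        )
            pairs.append((id_a, id_b, label))
    if not pairs:
        raise DataValidationError(f"{path}: no pairs found")
    return pairs


def write_pairs(
    pairs: Iterable[tuple[str, str, int | None]], path: str | Path
) -> None:
    """Write pairs as ``id_a<TAB>id_b<TAB>label`` lines."""
    with open(path, "w") as fh:
        for id_a, id_b, label in pairs:
            if label is None:
                fh.write(f"{id_a}\t{id_b}\n")
            else:
                fh.write(f"{id_a}\t{id_b}\t{int(label)}\n")


def filter_short(
    records: Sequence[ProteinRecord], min_len: int = MIN_PROTEIN_LENGTH
) -> tuple[list[ProteinRecord], list[str]]:
    """Remove proteins shorter than ``min_len`` residues.

    A protein of exactly ``min_len`` residues is kept ("less than" is
    removed).  Returns the kept records and the removal log of dropped ids.
    """
    if min_len < 1:
        raise DataValidationError(f"min_len must be >= 1, got {min_len}")
    kept = [r for r in records if len(r.sequence) >= min_len]
    removed = [r.id for r in records if len(r.sequence) < min_len]
    return kept, removed


def drop_pairs_of(
    pairs: Sequence[tuple[str, str, int | None]], removed_ids: Iterable[str]
) -> tuple[list[tuple[str, str, int | None]], int]:
    """Drop pairs touching any removed protein; returns (kept, n_dropped)."""
    removed = set(removed_ids)
    kept = [p for p in pairs if p[0] not in removed and p[1] not in removed]
    return kept, len(pairs) - len(kept)


def write_feature_frame(df: pd.DataFrame, path: str | Path) -> None:
    """Write a feature matrix (id_a, id_b, label, cells...) as TSV."""
    df.to_csv(path, sep="\t", index=False)


def read_feature_frame(path: str | Path) -> pd.DataFrame:
    """Read a feature matrix TSV written by :func:`write_feature_frame`."""
    df = pd.read_csv(path, sep="\t")
    required = {"id_a", "id_b", "label"}
    if not required.issubset(df.columns):
        raise DataValidationError(
            f"{path}: feature matrix must have columns {sorted(required)}"
        )
    return df


def write_predictions(
    path: str | Path,
    rows: Iterable[dict],
) -> None:
    """Write prediction rows (id_a, id_b, predicted_label, score, residuals)."""
    df = pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
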