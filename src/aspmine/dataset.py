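"""Labeled, categorized protein sequence datasets.

A dataset D is an ordered collection of proteins, each carrying an
amino-acid sequence z_i, a biological category name, and a binary
allergenicity label y_i in {+1, -1}.  D splits into the allergenic
partition D+ (size n+) and the nonallergenic partition D- (size n-).

Biological categories come in three types:

* ``paired``         -- contains both allergens and nonallergens,
* ``positive_only``  -- contains only allergens,
* ``negative_only``  -- contains only nonallergens.

The distinction matters downstream: a motif confined to a single
positive-only category cannot be told apart from a category-specific
(rather than allergen-specific) sequence feature.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ProteinRecord",
    "ProteinDataset",
    "CategoryInfo",
    "CategoryProfile",
    "DatasetParseError",
    "LABEL_ALIASES",
    "read_dataset",
    "write_dataset",
    "classify_categories",
    "dataset_summary",
]

#: Accepted spellings for the two labels in input files (case-insensitive).
LABEL_ALIASES: Mapping[str, int] = {
    "1": 1,
    "+1": 1,
    "-1": -1,
    "allergen": 1,
    "nonallergen": -1,
    "non-allergen": -1,
    "pos": 1,
    "neg": -1,
}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class DatasetParseError(ValueError):
    """Raised when an input file violates the dataset contract."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    category: str
    label: int

    def __post_init__(self) -> None:
        if not self.sequence or not self.sequence.isalpha() or not self.sequence.isupper():
            raise ValueError(
                f"record {self.id!r}: sequence must be a nonempty uppercase "
                f"alphabetic string"
            )
        if self.label not in (1, -1):
            raise ValueError(f"record {self.id!r}: label must be +1 or -1, got {self.label!r}")


class ProteinDataset:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    def __init__(self, records: Iterable[ProteinRecord]):
        self.records: list[ProteinRecord] = list(records)
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate protein id {r.id!r}")
            seen.add(r.id)

    # -- basic container protocol -------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, ProteinDataset) and self.records == other.records

    # -- derived counts ------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == -1)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int8)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def subset(self, indices: Sequence[int]) -> "ProteinDataset":
        return ProteinDataset(self.records[i] for i in indices)

    def relabeled(self, labels: Sequence[int]) -> "ProteinDataset":
        """Same proteins with a replacement label vector (used by permutation tests)."""
        if len(labels) != len(self.records):
            raise ValueError("label vector length mismatch")
        return ProteinDataset(
            ProteinRecord(r.id, r.sequence, r.category, int(y))
            for r, y in zip(self.records, labels)
        )


@dataclass(frozen=True)
class CategoryInfo:
    name: str
    type: str  # paired | positive_only | negative_only
    count_pos: int
    count_neg: int


@dataclass
class CategoryProfile:
    """Per-category class counts and the paired/positive-only/negative-only type."""

    categories: dict[str, CategoryInfo] = field(default_factory=dict)

    def type_of(self, name: str) -> str:
        return self.categories[name].type

    @property
    def paired(self) -> list[str]:
        return [c.name for c in self.categories.values() if c.type == "paired"]

    @property
    def positive_only(self) -> list[str]:
        return [c.name for c in self.categories.values() if c.type == "positive_only"]

    @property
    def negative_only(self) -> list[str]:
        return [c.name for c in self.categories.values() if c.type == "negative_only"]


def classify_categories(dataset: ProteinDataset) -> CategoryProfile:
    """Assign each biological category its paired/positive-only/negative-only type."""
    counts: dict[str, list[int]] = {}
    for r in dataset:
        c = counts.setdefault(r.category, [0, 0])
        if r.label == 1:
            c[0] += 1
        else:
            c[1] += 1
    profile = CategoryProfile()
    for name, (cp, cn) in counts.items():
        if cp > 0 and cn > 0:
            t = "paired"
        elif cp > 0:
            t = "positive_only"
        else:
            t = "negative_only"
        profile.categories[name] = CategoryInfo(name, t, cp, cn)
    return profile


def _parse_label(raw: str, line_no: int) -> int:
    key = raw.strip().lower()
    if key not in LABEL_ALIASES:
        raise DatasetParseError(
            f"line {line_no}: unrecognized label {raw!r} "
            f"(accepted: {sorted(LABEL_ALIASES)})"
        )
    return LABEL_ALIASES[key]


_REQUIRED_COLUMNS = ("id", "sequence", "category", "label")


def _records_from_rows(rows, start_line: int, strict: bool) -> list[ProteinRecord]:
    records = []
    for offset, row in enumerate(rows):
        line_no = start_line + offset
        seq = (row.get("sequence") or "").strip().upper()
        rid = (row.get("id") or "").strip()
        cat = (row.get("category") or "").strip()
        if not rid:
            raise DatasetParseError(f"line {line_no}: empty id")
        if not seq:
            raise DatasetParseError(f"line {line_no}: empty sequence")
        if not (seq.isalpha() and seq.isascii()):
            raise DatasetParseError(f"line {line_no}: non-alphabetic sequence {seq[:20]!r}")
        if strict and not set(seq) <= _STANDARD_AA:
            bad = sorted(set(seq) - _STANDARD_AA)
            raise DatasetParseError(
                f"line {line_no}: nonstandard residues {bad} (strict mode)"
            )
        label = _parse_label(row.get("label", ""), line_no)
        try:
            records.append(ProteinRecord(rid, seq, cat, label))
        except ValueError as e:  # pragma: no cover - guarded above
            raise DatasetParseError(f"line {line_no}: {e}") from e
    return records


def read_dataset(path, format: str = "auto", *, meta_path=None, strict: bool = False) -> ProteinDataset:
    """Read a labeled protein dataset.

    Parameters
    ----------
    path
        TSV/CSV with header columns ``id, sequence, category, label``, or a
        FASTA file (``format="fasta"``) accompanied by ``meta_path``, a TSV
        with columns ``id, category, label`` keyed by FASTA record id.
    format
        ``tsv``, ``csv``, ``fasta`` or ``auto`` (by file extension).
    strict
        Reject nonstandard residue codes (B, J, O, U, X, Z).
    """
    path = Path(path)
    if format == "auto":
        ext = path.suffix.lower()
        format = {".tsv": "tsv", ".csv": "csv", ".fa": "fasta", ".fasta": "fasta"}.get(ext, "tsv")

    if format == "fasta":
        if meta_path is None:
            raise DatasetParseError("FASTA input requires a metadata table (meta_path)")
        from Bio import SeqIO

        meta: dict[str, dict] = {}
        with open(meta_path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = {"id", "category", "label"} - set(reader.fieldnames or ())
            if missing:
                raise DatasetParseError(f"metadata table missing columns: {sorted(missing)}")
            for line_no, row in enumerate(reader, start=2):
                meta[row["id"].strip()] = (row, line_no)
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id not in meta:
                raise DatasetParseError(f"FASTA record {rec.id!r} missing from metadata table")
            row, _ = meta[rec.id]
            rows.append(
                {"id": rec.id, "sequence": str(rec.seq), "category": row["category"], "label": row["label"]}
            )
        records = _records_from_rows(rows, start_line=2, strict=strict)
        ds = ProteinDataset(records)
        return ds

    delimiter = {"tsv": "\t", "csv": ","}[format]
    with open(path, newline="") as fh:
        # tolerate leading "# ..." provenance/comment lines
        lines = (l for l in fh if not l.startswith("#"))
        reader = csv.DictReader(lines, delimiter=delimiter)
        fields = set(reader.fieldnames or ())
        missing = set(_REQUIRED_COLUMNS) - fields
        if missing:
            raise DatasetParseError(f"{path}: missing required columns {sorted(missing)}")
        records = _records_from_rows(reader, start_line=2, strict=strict)
    try:
        return ProteinDataset(records)
    except ValueError as e:
        raise DatasetParseError(str(e)) from e


def write_dataset(dataset: ProteinDataset, path, format: str = "tsv") -> None:
    delimiter = {"tsv": "\t", "csv": ","}[format]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(_REQUIRED_COLUMNS)
        for r in dataset:
            writer.writerow([r.id, r.sequence, r.category, r.label])


def dataset_summary(dataset: ProteinDataset) -> dict:
    """Headline statistics: sizes, sequence-length range, category type counts."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    lengths = [len(r.sequence) for r in dataset]
    profile = classify_categories(dataset)
    type_counts = {"paired": 0, "positive_only": 0, "negative_only": 0}
    for info in profile.categories.values():
        type_counts[info.type] += 1
    return {
        "n": dataset.n,
        "n_pos": dataset.n_pos,
        "n_neg": dataset.n_neg,
        "mean_length": float(np.mean(lengths)),
        "min_length": int(min(lengths)),
        "max_length": int(max(lengths)),
        "n_categories": len(profile.categories),
        "category_types": type_counts,
    }


def summary_json(dataset: ProteinDataset) -> str:
    return json.dumps(dataset_summary(dataset), indent=2, sort_keys=True)
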