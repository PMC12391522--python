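"""Cohort variable metadata: domain types, file I/O and inventory summaries.

A *variable* is one column of a cohort study's codebook — a short name plus a
free-text description such as ``"diabetes with fasting glucose cutpoint<126"``.
Harmonization maps such variables onto a shared inventory of medical
*concepts*, each belonging to a coarse *concept group* (sociodemographics,
vitals, comorbidities, ...). This module defines the in-memory containers for
that metadata and reads/writes the delimited-text formats cohort codebooks are
typically distributed in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

METADATA_COLUMNS = ("cohort", "variable", "description", "concept")
CONCEPT_COLUMNS = ("id", "name", "group")


@dataclass(frozen=True)
class VariableRecord:
    """One cohort variable: where it comes from, what it is called, what it says.

    ``concept_id`` is the harmonized label when known (training/reference data)
    and ``None`` for variables still awaiting harmonization.
    """

    cohort_id: str
    variable_name: str
    description: str
    concept_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.description or not self.description.strip():
            raise ValidationError(
                f"empty description for variable {self.cohort_id}/{self.variable_name}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.cohort_id, self.variable_name)

    @property
    def is_labeled(self) -> bool:
        return self.concept_id is not None


@dataclass(frozen=True)
class ConceptEntry:
    concept_id: str
    name: str
    group: str


class ConceptDictionary:
    """The harmonized concept inventory, each concept in exactly one group."""

    def __init__(self, entries: Iterable[ConceptEntry]):
        self.entries: list[ConceptEntry] = list(entries)
        self._by_id: dict[str, ConceptEntry] = {}
        for e in self.entries:
            if e.concept_id in self._by_id:
                raise ValidationError(f"duplicate concept id {e.concept_id!r}")
            self._by_id[e.concept_id] = e

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._by_id

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, ConceptDictionary) and self.entries == other.entries

    def __getitem__(self, concept_id: str) -> ConceptEntry:
        return self._by_id[concept_id]

    def group_of(self, concept_id: str) -> str:
        return self._by_id[concept_id].group

    @property
    def ids(self) -> list[str]:
        return [e.concept_id for e in self.entries]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.group, None)
        return list(seen)


@dataclass
class Corpus:
    """A set of variable records plus the concept dictionary they refer to."""

    records: list[VariableRecord]
    concepts: ConceptDictionary

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        bad_rows: list[str] = []
        for i, r in enumerate(self.records):
            if r.key in seen:
                raise ValidationError(
                    f"duplicate (cohort, variable) pair {r.key} at row {i}"
                )
            seen.add(r.key)
            if r.concept_id is not None and r.concept_id not in self.concepts:
                bad_rows.append(f"row {i} ({r.cohort_id}/{r.variable_name}): {r.concept_id!r}")
        if bad_rows:
            raise ValidationError(
                "concept labels absent from dictionary: " + "; ".join(bad_rows)
            )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Corpus)
            and self.records == other.records
            and self.concepts == other.concepts
        )

    @property
    def labeled(self) -> list[VariableRecord]:
        return [r for r in self.records if r.is_labeled]

    @property
    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.cohort_id, None)
        return list(seen)

    def labeled_concept_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.labeled:
            seen.setdefault(r.concept_id, None)  # type: ignore[arg-type]
        return list(seen)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_concepts(path: str | Path) -> ConceptDictionary:
    """Read a concept dictionary from JSON (list of {id,name,group}) or CSV/TSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(raw, list):
            raise FormatError(f"{path}: concept JSON must be a list of objects")
        entries = []
        for i, item in enumerate(raw):
            missing = [k for k in CONCEPT_COLUMNS if k not in item]
            if missing:
                raise FormatError(f"{path}: entry {i} missing key(s) {missing}")
            entries.append(ConceptEntry(str(item["id"]), str(item["name"]), str(item["group"])))
        return ConceptDictionary(entries)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in CONCEPT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return ConceptDictionary(
        ConceptEntry(row["id"], row["name"], row["group"]) for _, row in df.iterrows()
    )


def write_concepts(concepts: ConceptDictionary, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {"id": e.concept_id, "name": e.name, "group": e.group} for e in concepts
        ]
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    else:
        pd.DataFrame(
            [(e.concept_id, e.name, e.group) for e in concepts],
            columns=list(CONCEPT_COLUMNS),
        ).to_csv(path, sep=_sep_for(path), index=False)


def read_corpus(metadata_path: str | Path, concepts_path: str | Path) -> Corpus:
    """Read and validate a variable-metadata table against a concept dictionary.

    The metadata file is CSV or TSV (by extension) with header columns
    ``cohort,variable,description,concept``; a blank concept cell means the
    variable is unlabeled. Rows are preserved in file order.
    """
    metadata_path = Path(metadata_path)
    concepts = read_concepts(concepts_path)
    df = pd.read_csv(
        metadata_path, sep=_sep_for(metadata_path), dtype=str, keep_default_na=False
    )
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{metadata_path}: missing required column(s) {missing}")

    records: list[VariableRecord] = []
    empty_rows: list[int] = []
    for i, row in enumerate(df.itertuples(index=False)):
        desc = str(getattr(row, "description")).strip()
        if not desc:
            empty_rows.append(i)
            continue
        concept = str(getattr(row, "concept")).strip()
        records.append(
            VariableRecord(
                cohort_id=str(getattr(row, "cohort")).strip(),
                variable_name=str(getattr(row, "variable")).strip(),
                description=desc,
                concept_id=concept or None,
            )
        )
    if empty_rows:
        raise ValidationError(
            f"{metadata_path}: empty description at data row(s) {empty_rows}"
        )
    return Corpus(records=records, concepts=concepts)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the metadata table; ``read_corpus`` on the result round-trips."""
    path = Path(path)
    rows = [
        (r.cohort_id, r.variable_name, r.description, r.concept_id or "")
        for r in corpus.records
    ]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(
        path, sep=_sep_for(path), index=False
    )


def summarize_corpus(corpus: Corpus) -> pd.DataFrame:
    """Per-cohort breakdown of labeled variables by concept group.

    Returns a long-form table with columns ``cohort, concept_group, n, pct``
    where ``pct`` is the share of the cohort's labeled variables in that group,
    as a percentage rounded to one decimal. A ``concept_group == "total"`` row
    per cohort carries the cohort total (pct 100.0). Groups with no variables
    in a cohort appear with n=0 so the table shape matches the dictionary.
    """
    labeled = corpus.labeled
    if not labeled:
        raise ValidationError("summarize_corpus requires a labeled corpus")
    groups = corpus.concepts.groups
    cohorts = corpus.cohorts
    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {c: 0 for c in cohorts}
    for r in labeled:
        g = corpus.concepts.group_of(r.concept_id)  # type: ignore[arg-type]
        counts[(r.cohort_id, g)] = counts.get((r.cohort_id, g), 0) + 1
        totals[r.cohort_id] += 1
    rows = []
    for cohort in cohorts:
        total = totals[cohort]
        for g in groups:
            n = counts.get((cohort, g), 0)
            pct = round(n / total * 100, 1) if total else float("nan")
            rows.append((cohort, g, n, pct))
        rows.append((cohort, "total", total, 100.0 if total else float("nan")))
    return pd.DataFrame(rows, columns=["cohort", "concept_group", "n", "pct"])
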