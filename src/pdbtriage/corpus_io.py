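"""Shared domain records and tab-separated file I/O.

The triage pipeline consumes four flat, UTF-8, LF-terminated, tab-separated
files that emulate the metadata exports a structural-bioinformatics survey
would assemble:

``structure_entries.tsv``
    One row per PDB coordinate entry.  Columns (with header):
    ``pdb_id  molecule_name  classification_header  deposition_date  species
    accessions`` — ``accessions`` is a comma-joined list of sequence-database
    accessions (may be empty).

``annotations.tsv``
    One row per sequence-database (UniProtKB-like) record.  Columns (with
    header): ``accession  protein_name  reviewed  function_text
    catalytic_activity  ec_numbers  go_terms  integration_date``.
    ``go_terms`` is a semicolon-joined list of ``GO:NNNNNNN|DOMAIN|term name``
    (optionally ``|evidence_code``) sub-fields; ``ec_numbers`` is comma-joined.

``sequence_hits.tsv``
    Header-less 12-column BLAST tabular layout (``outfmt 6``): qseqid, sseqid,
    pident, length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
    bitscore.  Subject metadata is joined from the annotations mapping at read
    time, never carried in extra columns.

``structure_hits.tsv``
    One row per structural-alignment hit (Dali-results-like).  Columns (with
    header): ``query_id  subject_pdb_id  z_score  rmsd_angstrom
    subject_classification  subject_name  subject_deposition_date``.

All dates are ISO 8601 (``YYYY-MM-DD``).  Readers report every malformed line
with its line number; writers emit a canonical form so that ``write(read(x))``
is byte-identical for files produced by this package.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("pdbtriage")

__all__ = [
    "TriageError",
    "ValidationError",
    "ConsistencyError",
    "GoDomain",
    "GoAnnotation",
    "StructureEntry",
    "ProteinAnnotation",
    "SequenceHit",
    "StructureHit",
    "entry_id_of",
    "round_percent",
    "read_structure_entries",
    "read_annotations",
    "read_sequence_hits",
    "read_structure_hits",
    "write_structure_entries",
    "write_annotations",
    "write_sequence_hits",
    "write_structure_hits",
    "format_go_terms",
    "parse_go_terms",
    "ENTRY_COLUMNS",
    "ANNOTATION_COLUMNS",
    "BLAST_COLUMNS",
    "STRUCTURE_HIT_COLUMNS",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class TriageError(Exception):
    """Base class for every error raised by this package."""


class ValidationError(TriageError):
    """An input file or record violates the format contract.

    ``problems`` lists every individual violation (one string each, with a
    line number where the violation comes from a file).
    """

    def __init__(self, problems: str | Sequence[str]):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class ConsistencyError(TriageError):
    """A derived count violates a conservation identity."""


# ---------------------------------------------------------------------------
# Enumerations and patterns
# ---------------------------------------------------------------------------

class GoDomain(str, Enum):
    """The three Gene Ontology domains."""

    BIOLOGICAL_PROCESS = "BIOLOGICAL_PROCESS"
    MOLECULAR_FUNCTION = "MOLECULAR_FUNCTION"
    CELLULAR_COMPONENT = "CELLULAR_COMPONENT"


# 4-character PDB entry identifier: leading digit, then alphanumerics.
PDB_ID_PATTERN = re.compile(r"^[0-9][A-Za-z0-9]{3}$")
GO_ID_PATTERN = re.compile(r"^GO:[0-9]{7}$")
# EC number: four dot-separated fields, each a number or a "-" wildcard.
EC_PATTERN = re.compile(r"^([0-9]+|-)\.([0-9]+|-)\.([0-9]+|-)\.([0-9]+|-)$")


def entry_id_of(query_id: str) -> str:
    """Strip an optional chain suffix (``1htw_A`` -> ``1htw``).

    The unit of accounting is the 4-character PDB entry, so all grouping is
    done on the stripped identifier.
    """
    return query_id.split("_", 1)[0]


def round_percent(numerator: int, denominator: int) -> float:
    """100*numerator/denominator rounded half-away-from-zero to 2 decimals.

    Exact integer arithmetic; no binary-float rounding surprises at ties.
    """
    if denominator <= 0:
        raise ValidationError("percentage denominator must be positive")
    if numerator < 0:
        raise ValidationError("percentage numerator must be non-negative")
    q, r = divmod(10000 * numerator, denominator)
    if 2 * r >= denominator:
        q += 1
    return q / 100.0


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

def _check_pdb_id(pdb_id: str, what: str = "pdb_id") -> None:
    if not PDB_ID_PATTERN.match(pdb_id):
        raise ValidationError(
            f"{what} {pdb_id!r} is not a 4-character identifier with a leading digit"
        )


@dataclass(frozen=True)
class GoAnnotation:
    """A single GO term assignment on a sequence record."""

    go_id: str
    domain: GoDomain
    term_name: str
    evidence_code: str | None = None

    def __post_init__(self) -> None:
        if not GO_ID_PATTERN.match(self.go_id):
            raise ValidationError(f"malformed GO accession {self.go_id!r}")
        if not isinstance(self.domain, GoDomain):
            raise ValidationError(f"unknown GO domain {self.domain!r}")


@dataclass(frozen=True)
class StructureEntry:
    """Metadata of one PDB coordinate entry — the unit of triage."""

    pdb_id: str
    molecule_name: str
    classification_header: str
    deposition_date: date
    species: str
    accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        _check_pdb_id(self.pdb_id)
        if len(set(self.accessions)) != len(self.accessions):
            raise ValidationError(
                f"entry {self.pdb_id}: duplicate accessions {list(self.accessions)}"
            )


@dataclass(frozen=True)
class ProteinAnnotation:
    """One sequence-database record: the annotation evidence for stage 1.

    ``reviewed`` distinguishes the manually curated (Swiss-Prot-like) section
    from the automatic one; ``integration_date`` is when the record entered
    the sequence database.
    """

    accession: str
    protein_name: str
    reviewed: bool
    function_text: str = ""
    catalytic_activity: str = ""
    ec_numbers: tuple[str, ...] = ()
    go_terms: tuple[GoAnnotation, ...] = ()
    integration_date: date = date(2000, 1, 1)

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("annotation record with empty accession")
        for ec in self.ec_numbers:
            if not EC_PATTERN.match(ec):
                raise ValidationError(
                    f"record {self.accession}: malformed EC number {ec!r}"
                )


@dataclass(frozen=True)
class SequenceHit:
    """One BLAST tabular row, enriched with subject metadata.

    ``query_id`` keeps the raw qseqid (chain suffix included); use
    :func:`entry_id_of` or :attr:`entry_id` for the 4-character entry.
    The twelve standard tabular columns are all retained so files written
    back out are byte-identical.
    """

    query_id: str
    subject_accession: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float
    subject_name: str = ""
    subject_reviewed: bool = False
    subject_go_terms: tuple[GoAnnotation, ...] = ()
    subject_integration_date: date | None = None

    def __post_init__(self) -> None:
        _check_pdb_id(entry_id_of(self.query_id), "query_id entry part")
        if not self.subject_accession:
            raise ValidationError(f"hit for {self.query_id}: empty subject accession")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_accession}: "
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length <= 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_accession}: "
                f"non-positive alignment length {self.alignment_length}"
            )
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_accession}: "
                f"negative e-value {self.e_value}"
            )

    @property
    def entry_id(self) -> str:
        return entry_id_of(self.query_id)


@dataclass(frozen=True)
class StructureHit:
    """One structural-alignment row (Dali-results-like)."""

    query_id: str
    subject_pdb_id: str
    z_score: float
    rmsd_angstrom: float
    subject_classification: str
    subject_name: str
    subject_deposition_date: date

    def __post_init__(self) -> None:
        _check_pdb_id(entry_id_of(self.query_id), "query_id entry part")
        _check_pdb_id(self.subject_pdb_id, "subject_pdb_id")
        if self.rmsd_angstrom < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_pdb_id}: "
                f"negative RMSD {self.rmsd_angstrom}"
            )


# ---------------------------------------------------------------------------
# Sub-field (de)serialization
# ---------------------------------------------------------------------------

def format_go_terms(terms: Iterable[GoAnnotation]) -> str:
    """Serialize GO terms to the ``GO:NNNNNNN|DOMAIN|name[|code];...`` field."""
    parts = []
    for t in terms:
        sub = [t.go_id, t.domain.value, t.term_name]
        if t.evidence_code:
            sub.append(t.evidence_code)
        parts.append("|".join(sub))
    return ";".join(parts)


def parse_go_terms(text: str, where: str = "") -> tuple[GoAnnotation, ...]:
    """Parse the serialized GO sub-field; unknown domain tokens are errors."""
    if not text:
        return ()
    terms = []
    for token in text.split(";"):
        sub = token.split("|")
        if len(sub) not in (3, 4):
            raise ValidationError(f"{where}malformed GO sub-field {token!r}")
        go_id, domain_token, term_name = sub[0], sub[1], sub[2]
        try:
            domain = GoDomain(domain_token)
        except ValueError:
            raise ValidationError(
                f"{where}unknown GO domain token {domain_token!r}"
            ) from None
        evidence = sub[3] if len(sub) == 4 else None
        terms.append(GoAnnotation(go_id, domain, term_name, evidence))
    return tuple(terms)


def _parse_date(text: str, where: str) -> date:
    try:
        return date.fromisoformat(text)
    except ValueError:
        raise ValidationError(f"{where}malformed ISO date {text!r}") from None


def _parse_float(text: str, where: str, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"{where}malformed {what} {text!r}") from None


def _parse_int(text: str, where: str, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValidationError(f"{where}malformed {what} {text!r}") from None


def _parse_bool(text: str, where: str) -> bool:
    if text == "true":
        return True
    if text == "false":
        return False
    raise ValidationError(f"{where}malformed boolean {text!r} (want true/false)")


# ---------------------------------------------------------------------------
# Line-level plumbing
# ---------------------------------------------------------------------------

ENTRY_COLUMNS = (
    "pdb_id",
    "molecule_name",
    "classification_header",
    "deposition_date",
    "species",
    "accessions",
)
ANNOTATION_COLUMNS = (
    "accession",
    "protein_name",
    "reviewed",
    "function_text",
    "catalytic_activity",
    "ec_numbers",
    "go_terms",
    "integration_date",
)
BLAST_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)
STRUCTURE_HIT_COLUMNS = (
    "query_id",
    "subject_pdb_id",
    "z_score",
    "rmsd_angstrom",
    "subject_classification",
    "subject_name",
    "subject_deposition_date",
)


def _read_rows(
    path: str | Path,
    expected_header: tuple[str, ...] | None,
    n_columns: int,
    problems: list[str],
):
    """Yield ``(line_number, fields)`` for each well-shaped data line."""
    path = Path(path)
    if not path.exists():
        raise TriageError(f"input file not found: {path}")
    with open(path, encoding="utf-8", newline="") as fh:
        first_data_line = 1
        if expected_header is not None:
            header = fh.readline().rstrip("\n").rstrip("\r")
            if tuple(header.split("\t")) != expected_header:
                raise ValidationError(
                    f"{path.name}: unexpected header {header!r}; "
                    f"expected {chr(9).join(expected_header)!r}"
                )
            first_data_line = 2
        for lineno, raw in enumerate(fh, start=first_data_line):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != n_columns:
                problems.append(
                    f"{path.name}:{lineno}: expected {n_columns} columns, "
                    f"got {len(fields)}"
                )
                continue
            yield lineno, fields


def _raise_if(problems: list[str]) -> None:
    if problems:
        raise ValidationError(problems)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_structure_entries(path: str | Path) -> list[StructureEntry]:
    """Read the structure-entry metadata table, in file order.

    Raises :class:`ValidationError` naming every malformed line and any
    duplicated ``pdb_id``.
    """
    problems: list[str] = []
    entries: list[StructureEntry] = []
    seen: dict[str, int] = {}
    name = Path(path).name
    for lineno, f in _read_rows(path, ENTRY_COLUMNS, len(ENTRY_COLUMNS), problems):
        where = f"{name}:{lineno}: "
        try:
            accessions = tuple(a for a in f[5].split(",") if a)
            entry = StructureEntry(
                pdb_id=f[0],
                molecule_name=f[1],
                classification_header=f[2],
                deposition_date=_parse_date(f[3], where),
                species=f[4],
                accessions=accessions,
            )
        except ValidationError as exc:
            problems.append(where + str(exc))
            continue
        if entry.pdb_id in seen:
            problems.append(
                f"{where}duplicate pdb_id {entry.pdb_id!r} "
                f"(first seen on line {seen[entry.pdb_id]})"
            )
            continue
        seen[entry.pdb_id] = lineno
        entries.append(entry)
    _raise_if(problems)
    return entries


def read_annotations(path: str | Path) -> dict[str, ProteinAnnotation]:
    """Read the sequence-annotation table into an accession-keyed mapping."""
    problems: list[str] = []
    records: dict[str, ProteinAnnotation] = {}
    name = Path(path).name
    for lineno, f in _read_rows(
        path, ANNOTATION_COLUMNS, len(ANNOTATION_COLUMNS), problems
    ):
        where = f"{name}:{lineno}: "
        try:
            record = ProteinAnnotation(
                accession=f[0],
                protein_name=f[1],
                reviewed=_parse_bool(f[2], where),
                function_text=f[3],
                catalytic_activity=f[4],
                ec_numbers=tuple(e for e in f[5].split(",") if e),
                go_terms=parse_go_terms(f[6], where),
                integration_date=_parse_date(f[7], where),
            )
        except ValidationError as exc:
            problems.append(where + str(exc))
            continue
        if record.accession in records:
            problems.append(f"{where}duplicate accession {record.accession!r}")
            continue
        records[record.accession] = record
    _raise_if(problems)
    return records


def read_sequence_hits(
    path: str | Path,
    annotations: Mapping[str, ProteinAnnotation],
    strict: bool = False,
) -> dict[str, list[SequenceHit]]:
    """Read the header-less BLAST tabular file, grouped by query entry.

    Each hit is enriched with the subject's name, review status, GO terms and
    integration date from ``annotations``.  A subject accession absent from
    the mapping is a validation error in ``strict`` mode; in the default
    lenient mode the hit is excluded (and counted in a warning), matching how
    ragged real corpora are handled.  Queries absent from the file simply map
    to an empty list via ``.get(query, [])``.
    """
    problems: list[str] = []
    grouped: dict[str, list[SequenceHit]] = {}
    dropped = 0
    name = Path(path).name
    for lineno, f in _read_rows(path, None, len(BLAST_COLUMNS), problems):
        where = f"{name}:{lineno}: "
        subject = f[1]
        meta = annotations.get(subject)
        if meta is None:
            if strict:
                problems.append(
                    f"{where}subject accession {subject!r} missing from annotations"
                )
            else:
                dropped += 1
            continue
        try:
            hit = SequenceHit(
                query_id=f[0],
                subject_accession=subject,
                percent_identity=_parse_float(f[2], where, "pident"),
                alignment_length=_parse_int(f[3], where, "length"),
                mismatches=_parse_int(f[4], where, "mismatch"),
                gap_opens=_parse_int(f[5], where, "gapopen"),
                query_start=_parse_int(f[6], where, "qstart"),
                query_end=_parse_int(f[7], where, "qend"),
                subject_start=_parse_int(f[8], where, "sstart"),
                subject_end=_parse_int(f[9], where, "send"),
                e_value=_parse_float(f[10], where, "evalue"),
                bit_score=_parse_float(f[11], where, "bitscore"),
                subject_name=meta.protein_name,
                subject_reviewed=meta.reviewed,
                subject_go_terms=meta.go_terms,
                subject_integration_date=meta.integration_date,
            )
        except ValidationError as exc:
            problems.append(where + str(exc))
            continue
        grouped.setdefault(hit.entry_id, []).append(hit)
    _raise_if(problems)
    if dropped:
        logger.warning(
            "%s: excluded %d hit(s) whose subject metadata is missing", name, dropped
        )
    return grouped


def read_structure_hits(path: str | Path) -> dict[str, list[StructureHit]]:
    """Read the structural-alignment table, grouped by query entry."""
    problems: list[str] = []
    grouped: dict[str, list[StructureHit]] = {}
    name = Path(path).name
    for lineno, f in _read_rows(
        path, STRUCTURE_HIT_COLUMNS, len(STRUCTURE_HIT_COLUMNS), problems
    ):
        where = f"{name}:{lineno}: "
        try:
            hit = StructureHit(
                query_id=f[0],
                subject_pdb_id=f[1],
                z_score=_parse_float(f[2], where, "z_score"),
                rmsd_angstrom=_parse_float(f[3], where, "rmsd"),
                subject_classification=f[4],
                subject_name=f[5],
                subject_deposition_date=_parse_date(f[6], where),
            )
        except ValidationError as exc:
            problems.append(where + str(exc))
            continue
        grouped.setdefault(entry_id_of(hit.query_id), []).append(hit)
    _raise_if(problems)
    return grouped


# ---------------------------------------------------------------------------
# Writers (canonical form; generator and round-trips share these)
# ---------------------------------------------------------------------------

def _fmt_float(v: float) -> str:
    return f"{v:.2f}"


def write_structure_entries(
    entries: Iterable[StructureEntry], path: str | Path
) -> None:
    lines = ["\t".join(ENTRY_COLUMNS)]
    for e in entries:
        lines.append(
            "\t".join(
                [
                    e.pdb_id,
                    e.molecule_name,
                    e.classification_header,
                    e.deposition_date.isoformat(),
                    e.species,
                    ",".join(e.accessions),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_annotations(
    records: Mapping[str, ProteinAnnotation] | Iterable[ProteinAnnotation],
    path: str | Path,
) -> None:
    if isinstance(records, Mapping):
        records = records.values()
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.accession,
                    r.protein_name,
                    "true" if r.reviewed else "false",
                    r.function_text,
                    r.catalytic_activity,
                    ",".join(r.ec_numbers),
                    format_go_terms(r.go_terms),
                    r.integration_date.isoformat(),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_sequence_hits(
    hits: Mapping[str, Sequence[SequenceHit]] | Iterable[SequenceHit],
    path: str | Path,
) -> None:
    """Write hits back to the 12-column tabular layout (no header).

    A mapping is flattened in key order; subject metadata is *not* written
    (it lives in the annotations file).
    """
    if isinstance(hits, Mapping):
        flat: Iterable[SequenceHit] = (h for hs in hits.values() for h in hs)
    else:
        flat = hits
    lines = []
    for h in flat:
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_accession,
                    _fmt_float(h.percent_identity),
                    str(h.alignment_length),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.query_start),
                    str(h.query_end),
                    str(h.subject_start),
                    str(h.subject_end),
                    f"{h.e_value:.2e}",
                    f"{h.bit_score:.1f}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_structure_hits(
    hits: Mapping[str, Sequence[StructureHit]] | Iterable[StructureHit],
    path: str | Path,
) -> None:
    if isinstance(hits, Mapping):
        flat: Iterable[StructureHit] = (h for hs in hits.values() for h in hs)
    else:
        flat = hits
    lines = ["\t".join(STRUCTURE_HIT_COLUMNS)]
    for h in flat:
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_pdb_id,
                    f"{h.z_score:.1f}",
                    f"{h.rmsd_angstrom:.1f}",
                    h.subject_classification,
                    h.subject_name,
                    h.subject_deposition_date.isoformat(),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
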