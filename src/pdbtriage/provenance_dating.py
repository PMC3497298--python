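"""Stage 4 — provenance dating and metadata-discrepancy flags.

Why do entries with detectable homologs still sit under "unknown function"?
Mostly staleness: the homolog entered its database *after* the query
structure was deposited, so the depositors could not have cited it.  This
stage compares each query's deposition date with the earliest date of its
supporting evidence (sequence-hit integration dates; the definite structural
best hit's deposition date), measures the lag in whole years, and flags the
two metadata discrepancies that point at re-annotation candidates:

* ``NAME_VS_CLASS`` — the classification header says "unknown function"
  although the molecule name names a function (e.g. an "...ase").
* ``CLASS_VS_NAME`` — the classification header names a function although
  the molecule name is an uncharacterized-style placeholder.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .annotation_triage import NameBlacklist, is_uninformative_name
from .corpus_io import StructureEntry, ValidationError, round_percent
from .sequence_evidence import SequenceEvidence
from .structure_evidence import StructureEvidence, StructureOutcome

__all__ = [
    "Discrepancy",
    "ProvenanceRecord",
    "DateAccounting",
    "DEFAULT_FUNCTION_VOCABULARY",
    "names_function",
    "lag_years",
    "build_provenance",
    "summarize_dates",
]


class Discrepancy(Enum):
    NAME_VS_CLASS = "NAME_VS_CLASS"
    CLASS_VS_NAME = "CLASS_VS_NAME"


#: Token patterns that mark a free-text name as naming a function.  The
#: dominant signal in enzyme nomenclature is the "-ase" suffix (kinase,
#: ligase, ATP-ase, ...); the rest catch common non-"-ase" activity words.
DEFAULT_FUNCTION_VOCABULARY: tuple[str, ...] = (
    r"[a-z0-9]*ase$",
    r"^enzyme$",
    r"^receptor$",
    r"^transporter$",
    r"^channel$",
    r"^inhibitor$",
    r"^regulator$",
    r"^factor$",
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def names_function(
    text: str,
    vocabulary: Sequence[str] = DEFAULT_FUNCTION_VOCABULARY,
    blacklist: NameBlacklist | None = None,
) -> bool:
    """True when ``text`` is informative *and* contains a function-word token."""
    if is_uninformative_name(text, blacklist):
        return False
    patterns = [re.compile(p) for p in vocabulary]
    return any(
        p.search(token) for token in _TOKEN_RE.findall(text.lower()) for p in patterns
    )


def lag_years(query_date: date, hit_date: date) -> int:
    """Whole-year lag between deposition and evidence availability.

    floor(elapsed days / 365.25); negative when the hit predates the query.
    """
    days = (hit_date - query_date).days
    return (days * 4) // 1461  # 1461 = 4 * 365.25, exact floor division


@dataclass(frozen=True)
class ProvenanceRecord:
    """Dating and discrepancy facts for one forwarded query."""

    query_id: str
    query_date: date
    earliest_hit_date: date | None = None
    hit_postdates_query: bool | None = None
    lag_years: int | None = None
    discrepancy_flags: frozenset[Discrepancy] = frozenset()

    def __post_init__(self) -> None:
        if (self.earliest_hit_date is None) != (self.lag_years is None):
            raise ValidationError(
                f"{self.query_id}: lag_years present iff earliest_hit_date present"
            )


@dataclass(frozen=True)
class DateAccounting:
    """Corpus-level date bookkeeping for the two evidence channels."""

    fraction_hits_postdate_blast: float
    fraction_hits_postdate_dali: float
    predating_query_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for v in (self.fraction_hits_postdate_blast, self.fraction_hits_postdate_dali):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"date fraction {v} outside [0, 100]")


def _evidence_dates(
    seq: SequenceEvidence | None, struct: StructureEvidence | None
) -> list[date]:
    dates: list[date] = []
    if seq is not None:
        dates.extend(
            h.subject_integration_date
            for h in seq.supporting_hits
            if h.subject_integration_date is not None
        )
    if (
        struct is not None
        and struct.value is StructureOutcome.DEFINITE
        and struct.best_hit is not None
    ):
        dates.append(struct.best_hit.subject_deposition_date)
    return dates


def build_provenance(
    entry: StructureEntry,
    seq: SequenceEvidence | None,
    struct: StructureEvidence | None,
    vocabulary: Sequence[str] = DEFAULT_FUNCTION_VOCABULARY,
    blacklist: NameBlacklist | None = None,
) -> ProvenanceRecord:
    """Assemble the provenance record for one forwarded entry.

    The earliest evidence date pools supporting sequence hits' integration
    dates with the definite structural best hit's deposition date; equal
    dates count as *not* postdating (evidence available on deposition day
    could have been cited).
    """
    dates = _evidence_dates(seq, struct)
    earliest = min(dates) if dates else None
    flags: set[Discrepancy] = set()
    header_is_unknown = (
        entry.classification_header.strip().lower() == "unknown function"
    )
    if header_is_unknown and names_function(entry.molecule_name, vocabulary, blacklist):
        flags.add(Discrepancy.NAME_VS_CLASS)
    if (
        not header_is_unknown
        and names_function(entry.classification_header, vocabulary, blacklist)
        and is_uninformative_name(entry.molecule_name, blacklist)
    ):
        flags.add(Discrepancy.CLASS_VS_NAME)
    return ProvenanceRecord(
        query_id=entry.pdb_id,
        query_date=entry.deposition_date,
        earliest_hit_date=earliest,
        hit_postdates_query=None if earliest is None else earliest > entry.deposition_date,
        lag_years=None if earliest is None else lag_years(entry.deposition_date, earliest),
        discrepancy_flags=frozenset(flags),
    )


def summarize_dates(
    records: Iterable[ProvenanceRecord],
    seq_outcomes: Mapping[str, SequenceEvidence],
    struct_outcomes: Mapping[str, StructureEvidence],
    denominator: str = "queries",
) -> DateAccounting:
    """Per-channel postdating fractions and the predating-query list.

    With ``denominator="queries"`` (default) each significant query counts
    once, by its earliest evidence date in that channel; with
    ``"alignments"`` every supporting alignment counts individually.  The
    predating list contains the queries whose pooled earliest evidence
    strictly predates their deposition — the set for which a citation
    cross-check would have been possible.
    """
    if denominator not in ("queries", "alignments"):
        raise ValidationError(f"unknown date denominator {denominator!r}")
    by_id = {r.query_id: r for r in records}

    def fraction(pairs: list[tuple[date, date]]) -> float:
        if not pairs:
            return 0.0
        later = sum(1 for qd, hd in pairs if hd > qd)
        return round_percent(later, len(pairs))

    blast_pairs: list[tuple[date, date]] = []
    for qid, ev in seq_outcomes.items():
        rec = by_id.get(qid)
        if rec is None or not ev.supporting_hits:
            continue
        hit_dates = [
            h.subject_integration_date
            for h in ev.supporting_hits
            if h.subject_integration_date is not None
        ]
        if not hit_dates:
            continue
        if denominator == "queries":
            blast_pairs.append((rec.query_date, min(hit_dates)))
        else:
            blast_pairs.extend((rec.query_date, d) for d in hit_dates)

    dali_pairs: list[tuple[date, date]] = []
    for qid, ev in struct_outcomes.items():
        rec = by_id.get(qid)
        if (
            rec is None
            or ev.value is not StructureOutcome.DEFINITE
            or ev.best_hit is None
        ):
            continue
        dali_pairs.append((rec.query_date, ev.best_hit.subject_deposition_date))

    predating = tuple(
        sorted(
            r.query_id
            for r in by_id.values()
            if r.earliest_hit_date is not None and r.earliest_hit_date < r.query_date
        )
    )
    return DateAccounting(
        fraction_hits_postdate_blast=fraction(blast_pairs),
        fraction_hits_postdate_dali=fraction(dali_pairs),
        predating_query_ids=predating,
    )
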