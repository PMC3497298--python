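"""Stage 1 — annotation sufficiency triage.

Each structure entry is checked against its mapped sequence-database record.
A record counts as *sufficient* functional characterization when it carries
an informative protein name together with at least one of: free-text function,
catalytic activity, an EC number, or a qualifying GO profile.  A GO profile
qualifies when it has at least ``min_terms`` terms that are not exclusively
cellular-component localizations and not exclusively "*-binding" terms —
neither of which, on its own, says what the protein actually does.

The stage partitions the corpus into four disjoint categories; SUFFICIENT
entries exit the pipeline, the other three proceed to the sequence screen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .corpus_io import (
    GoAnnotation,
    GoDomain,
    ProteinAnnotation,
    StructureEntry,
    ValidationError,
)

__all__ = [
    "AnnotationStatus",
    "NameBlacklist",
    "DEFAULT_BLACKLIST_KEYWORDS",
    "is_uninformative_name",
    "go_profile_sufficient",
    "classify_annotation_status",
    "partition_corpus",
]


class AnnotationStatus(Enum):
    """Stage-1 category of a structure entry."""

    SUFFICIENT = "SUFFICIENT"
    INSUFFICIENT = "INSUFFICIENT"
    UNCHARACTERIZED_EQUIVALENT = "UNCHARACTERIZED_EQUIVALENT"
    NO_MAPPING = "NO_MAPPING"


#: Words whose presence marks a protein name as carrying no functional signal.
DEFAULT_BLACKLIST_KEYWORDS = frozenset(
    {
        "uncharacterized",
        "putative",
        "unknown",
        "predicted",
        "unnamed",
        "probable",
        "hypothetical",
    }
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class NameBlacklist:
    """Lowercase keywords that mark a name as uninformative."""

    keywords: frozenset[str] = DEFAULT_BLACKLIST_KEYWORDS

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValidationError("name blacklist must be non-empty")
        if any(k != k.lower() for k in self.keywords):
            raise ValidationError("name blacklist keywords must be lowercase")

    @classmethod
    def default(cls) -> "NameBlacklist":
        return cls()

    @classmethod
    def from_keywords(cls, keywords: Iterable[str]) -> "NameBlacklist":
        return cls(frozenset(k.lower() for k in keywords))


def is_uninformative_name(name: str, blacklist: NameBlacklist | None = None) -> bool:
    """True when ``name`` carries no functional information.

    Matching is case-insensitive and whole-word on alphanumeric token
    boundaries, so "Probable kinase" matches but "probability" does not.
    An empty (or token-free) name is vacuous and therefore uninformative.
    """
    blacklist = blacklist or NameBlacklist.default()
    tokens = _TOKEN_RE.findall(name.lower())
    if not tokens:
        return True
    return any(t in blacklist.keywords for t in tokens)


def _ends_with_binding(term_name: str) -> bool:
    tokens = _TOKEN_RE.findall(term_name.lower())
    return bool(tokens) and tokens[-1] == "binding"


def go_profile_sufficient(
    terms: Sequence[GoAnnotation], min_terms: int = 3
) -> bool:
    """Whether a GO profile on its own constitutes sufficient characterization.

    Requires at least ``min_terms`` terms, and rejects profiles made entirely
    of cellular-component terms or entirely of "*-binding" terms (the
    exclusions generalize to any term count: a profile with no informative
    non-localization, non-binding signal never qualifies).
    """
    if len(terms) < min_terms:
        return False
    if all(t.domain is GoDomain.CELLULAR_COMPONENT for t in terms):
        return False
    if all(_ends_with_binding(t.term_name) for t in terms):
        return False
    return True


def _classify_record(
    record: ProteinAnnotation,
    blacklist: NameBlacklist,
    min_terms: int,
) -> AnnotationStatus:
    # The name check dominates: an uncharacterized-named equivalent stays in
    # the unknown pool no matter how many GO terms it carries.
    if is_uninformative_name(record.protein_name, blacklist):
        return AnnotationStatus.UNCHARACTERIZED_EQUIVALENT
    if (
        record.function_text.strip()
        or record.catalytic_activity.strip()
        or record.ec_numbers
        or go_profile_sufficient(record.go_terms, min_terms)
    ):
        return AnnotationStatus.SUFFICIENT
    return AnnotationStatus.INSUFFICIENT


def classify_annotation_status(
    entry: StructureEntry,
    annotations: Mapping[str, ProteinAnnotation],
    blacklist: NameBlacklist | None = None,
    min_terms: int = 3,
    accession_policy: str = "any-sufficient",
) -> AnnotationStatus:
    """Classify one entry from its resolvable sequence-database records.

    ``accession_policy``:

    * ``"first"`` — classify on the first accession whose record exists.
    * ``"any-sufficient"`` (default) — as above, but if any other resolvable
      record is sufficient the entry is SUFFICIENT (evidence is disjunctive).
    """
    if accession_policy not in ("first", "any-sufficient"):
        raise ValidationError(f"unknown accession policy {accession_policy!r}")
    blacklist = blacklist or NameBlacklist.default()
    records = [annotations[a] for a in entry.accessions if a in annotations]
    if not records:
        return AnnotationStatus.NO_MAPPING
    status = _classify_record(records[0], blacklist, min_terms)
    if (
        accession_policy == "any-sufficient"
        and status is not AnnotationStatus.SUFFICIENT
        and any(
            _classify_record(r, blacklist, min_terms) is AnnotationStatus.SUFFICIENT
            for r in records[1:]
        )
    ):
        return AnnotationStatus.SUFFICIENT
    return status


def partition_corpus(
    entries: Sequence[StructureEntry],
    annotations: Mapping[str, ProteinAnnotation],
    blacklist: NameBlacklist | None = None,
    min_terms: int = 3,
    accession_policy: str = "any-sufficient",
) -> dict[AnnotationStatus, list[str]]:
    """Partition the corpus into the four stage-1 buckets.

    Every entry lands in exactly one bucket; within-bucket order follows the
    input order.
    """
    buckets: dict[AnnotationStatus, list[str]] = {s: [] for s in AnnotationStatus}
    for entry in entries:
        status = classify_annotation_status(
            entry, annotations, blacklist, min_terms, accession_policy
        )
        buckets[status].append(entry.pdb_id)
    return buckets
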