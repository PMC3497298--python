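"""Stage 2 — sequence-homology evidence.

Queries that survived the annotation screen are checked against their BLAST
hit tables.  An alignment transfers annotation only when its percent identity
clears a GO-domain-specific cutoff — >40% for biological process, >50% for
molecular function, >60% for cellular component — reflecting the empirical
identity levels at which homologous pairs share most of their GO terms.
Two name-based discards apply: hits whose subject name is itself
uncharacterized-style are never evidence, and molecular-function terms that
are bare "*-binding" terms do not support the MF domain.

Each query gets one of five outcomes; the two SIGNIFICANT outcomes remove it
from the unknown pool, the rest forward it to the structural screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .annotation_triage import NameBlacklist, is_uninformative_name, _ends_with_binding
from .corpus_io import GoDomain, SequenceHit, ValidationError

__all__ = [
    "IdentityCutoffs",
    "SequenceOutcome",
    "SequenceEvidence",
    "hit_is_characterized",
    "hit_supported_domains",
    "classify_sequence_evidence",
    "summarize_sequence_stage",
]


@dataclass(frozen=True)
class IdentityCutoffs:
    """Per-GO-domain percent-identity thresholds (strict ``>``)."""

    biological_process: float = 40.0
    molecular_function: float = 50.0
    cellular_component: float = 60.0

    def __post_init__(self) -> None:
        for name, v in (
            ("biological_process", self.biological_process),
            ("molecular_function", self.molecular_function),
            ("cellular_component", self.cellular_component),
        ):
            if not 0.0 < v <= 100.0:
                raise ValidationError(f"identity cutoff {name}={v} outside (0, 100]")

    def for_domain(self, domain: GoDomain) -> float:
        return {
            GoDomain.BIOLOGICAL_PROCESS: self.biological_process,
            GoDomain.MOLECULAR_FUNCTION: self.molecular_function,
            GoDomain.CELLULAR_COMPONENT: self.cellular_component,
        }[domain]


class SequenceOutcome(Enum):
    """Per-query outcome of the sequence screen."""

    SIGNIFICANT_ALL_CHARACTERIZED = "SIGNIFICANT_ALL_CHARACTERIZED"
    SIGNIFICANT_MIXED = "SIGNIFICANT_MIXED"
    DISCARDED_ONLY = "DISCARDED_ONLY"
    SUB_THRESHOLD = "SUB_THRESHOLD"
    NO_HITS = "NO_HITS"

    @property
    def is_significant(self) -> bool:
        return self in (
            SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED,
            SequenceOutcome.SIGNIFICANT_MIXED,
        )


@dataclass(frozen=True)
class SequenceEvidence:
    """Outcome plus the hits that actually support annotation transfer."""

    value: SequenceOutcome
    supporting_hits: tuple[SequenceHit, ...] = ()

    def __post_init__(self) -> None:
        if self.value.is_significant and not self.supporting_hits:
            raise ValidationError(
                f"{self.value.value} evidence requires at least one supporting hit"
            )
        if self.value is SequenceOutcome.NO_HITS and self.supporting_hits:
            raise ValidationError("NO_HITS evidence cannot carry supporting hits")

    @property
    def is_significant(self) -> bool:
        return self.value.is_significant


def hit_is_characterized(
    hit: SequenceHit, blacklist: NameBlacklist | None = None
) -> bool:
    """A hit can only be evidence if its subject's own name is informative."""
    return not is_uninformative_name(hit.subject_name, blacklist)


def hit_supported_domains(
    hit: SequenceHit, cutoffs: IdentityCutoffs | None = None
) -> set[GoDomain]:
    """GO domains for which this alignment clears the identity cutoff.

    A domain is supported when the subject carries at least one GO term in it
    and the percent identity *strictly* exceeds that domain's cutoff.  For
    molecular function, bare "*-binding" terms are discarded first: at least
    one non-binding MF term must remain.
    """
    cutoffs = cutoffs or IdentityCutoffs()
    supported: set[GoDomain] = set()
    for domain in GoDomain:
        terms = [t for t in hit.subject_go_terms if t.domain is domain]
        if not terms:
            continue
        if hit.percent_identity <= cutoffs.for_domain(domain):
            continue
        if domain is GoDomain.MOLECULAR_FUNCTION and all(
            _ends_with_binding(t.term_name) for t in terms
        ):
            continue
        supported.add(domain)
    return supported


def classify_sequence_evidence(
    hits: Sequence[SequenceHit],
    cutoffs: IdentityCutoffs | None = None,
    blacklist: NameBlacklist | None = None,
) -> SequenceEvidence:
    """Classify one query's hit list into a sequence-evidence outcome.

    Hits split three ways: *supporting* (characterized subject, at least one
    supported domain), *name-discarded* (uncharacterized-style subject name),
    and *sub-threshold* (characterized subject, no supported domain).  The
    outcome follows from which of these sets are populated.
    """
    if not hits:
        return SequenceEvidence(SequenceOutcome.NO_HITS)
    cutoffs = cutoffs or IdentityCutoffs()
    blacklist = blacklist or NameBlacklist.default()
    supporting: list[SequenceHit] = []
    discarded = 0
    sub_threshold = 0
    for hit in hits:
        if not hit_is_characterized(hit, blacklist):
            discarded += 1
        elif hit_supported_domains(hit, cutoffs):
            supporting.append(hit)
        else:
            sub_threshold += 1
    if supporting:
        value = (
            SequenceOutcome.SIGNIFICANT_MIXED
            if discarded
            else SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED
        )
    elif discarded and not sub_threshold:
        value = SequenceOutcome.DISCARDED_ONLY
    else:
        value = SequenceOutcome.SUB_THRESHOLD
    return SequenceEvidence(value, tuple(supporting))


def summarize_sequence_stage(
    outcomes: Mapping[str, SequenceEvidence],
) -> dict[str, int]:
    """Per-class counts over the sequence-stage queries.

    The five outcome classes partition the query set; ``SIGNIFICANT`` is a
    derived row (sum of the two significant classes), not part of the
    partition.
    """
    counts = {o.value: 0 for o in SequenceOutcome}
    for ev in outcomes.values():
        counts[ev.value.value] += 1
    counts["SIGNIFICANT"] = (
        counts[SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED.value]
        + counts[SequenceOutcome.SIGNIFICANT_MIXED.value]
    )
    return counts
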