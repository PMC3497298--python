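"""Stage 3 — structural-homology evidence.

Queries with no significant sequence homolog are checked against their
structural-alignment hit tables.  The Z-score of a structural superposition
is banded into homology classes: above 20 the pair are definite homologs,
between 8 and 20 (inclusive) probable homologs, below 8 probably unrelated.

Before banding, hits are filtered for admissibility: a subject that is
itself of unknown function, ambiguously described, or a member of the
query corpus cannot donate an annotation.  Only DEFINITE queries leave the
unknown pool; probable homology is reported but not acted on.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import AbstractSet, Mapping, Sequence

from .annotation_triage import NameBlacklist, is_uninformative_name
from .corpus_io import StructureHit, ValidationError

__all__ = [
    "ZScoreBands",
    "StructureOutcome",
    "StructureEvidence",
    "hit_is_admissible",
    "classify_z",
    "classify_structure_evidence",
    "summarize_structure_stage",
]


@dataclass(frozen=True)
class ZScoreBands:
    """Z-score breakpoints: definite strictly above 20, unrelated below 8."""

    definite_above: float = 20.0
    probable_floor: float = 8.0

    def __post_init__(self) -> None:
        if not self.definite_above > self.probable_floor > 0:
            raise ValidationError(
                f"Z bands require definite_above > probable_floor > 0, "
                f"got {self.definite_above}/{self.probable_floor}"
            )


class StructureOutcome(Enum):
    DEFINITE = "DEFINITE"
    PROBABLE = "PROBABLE"
    UNRELATED = "UNRELATED"
    NO_HITS = "NO_HITS"


@dataclass(frozen=True)
class StructureEvidence:
    """Outcome plus the best admissible hit that determined it."""

    value: StructureOutcome
    best_hit: StructureHit | None = None

    def __post_init__(self) -> None:
        if self.value is StructureOutcome.NO_HITS:
            if self.best_hit is not None:
                raise ValidationError("NO_HITS evidence cannot carry a best hit")
        elif self.best_hit is None:
            raise ValidationError(f"{self.value.value} evidence requires a best hit")


def hit_is_admissible(
    hit: StructureHit,
    initial_dataset: AbstractSet[str],
    blacklist: NameBlacklist | None = None,
) -> bool:
    """Whether a structural hit may donate an annotation.

    Inadmissible subjects: members of the query corpus itself, subjects
    classified "unknown function", and subjects whose classification or name
    is uninformative per the blacklist (an ambiguous functional description
    is no description).
    """
    if hit.subject_pdb_id in initial_dataset:
        return False
    if hit.subject_classification.strip().lower() == "unknown function":
        return False
    if is_uninformative_name(hit.subject_classification, blacklist):
        return False
    if is_uninformative_name(hit.subject_name, blacklist):
        return False
    return True


def classify_z(z: float, bands: ZScoreBands | None = None) -> StructureOutcome:
    """Band a Z-score: DEFINITE (> 20), PROBABLE ([8, 20]), UNRELATED (< 8)."""
    bands = bands or ZScoreBands()
    if z > bands.definite_above:
        return StructureOutcome.DEFINITE
    if z >= bands.probable_floor:
        return StructureOutcome.PROBABLE
    return StructureOutcome.UNRELATED


def classify_structure_evidence(
    hits: Sequence[StructureHit],
    bands: ZScoreBands | None = None,
    initial_dataset: AbstractSet[str] = frozenset(),
    blacklist: NameBlacklist | None = None,
) -> StructureEvidence:
    """Classify one query by its best (maximum-Z) admissible hit.

    Z-score is a per-alignment statistic, so a single best alignment — not a
    vote — sets the homology class.  Ties on Z break toward the
    lexicographically smallest subject ID for determinism.
    """
    bands = bands or ZScoreBands()
    admissible = [h for h in hits if hit_is_admissible(h, initial_dataset, blacklist)]
    if not admissible:
        return StructureEvidence(StructureOutcome.NO_HITS)
    best = min(admissible, key=lambda h: (-h.z_score, h.subject_pdb_id))
    return StructureEvidence(classify_z(best.z_score, bands), best)


def summarize_structure_stage(
    outcomes: Mapping[str, StructureEvidence],
) -> dict[str, int]:
    """Per-class counts; ``DEFINITE_OR_PROBABLE`` is a derived row."""
    counts = {o.value: 0 for o in StructureOutcome}
    for ev in outcomes.values():
        counts[ev.value.value] += 1
    counts["DEFINITE_OR_PROBABLE"] = (
        counts[StructureOutcome.DEFINITE.value]
        + counts[StructureOutcome.PROBABLE.value]
    )
    return counts
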