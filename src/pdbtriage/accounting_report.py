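"""Funnel accounting, report serialization, and pipeline orchestration.

The four screening stages reduce the corpus step by step::

    initial corpus
      -> stage 1 drops entries with sufficient annotation
      -> stage 2 drops entries with significant sequence homology
      -> stage 3 drops entries with definite structural homology
      -> what remains is the true-unknown set

Every count and percentage in the report is recomputed from the per-entry
verdicts at report time; percentages use round-half-away-from-zero to two
decimals.  Entries removed at stage 2 or 3 are the re-annotation candidates.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation_triage import (
    AnnotationStatus,
    classify_annotation_status,
)
from .config import TriageConfig
from .corpus_io import (
    ConsistencyError,
    StructureEntry,
    ValidationError,
    read_annotations,
    read_sequence_hits,
    read_structure_entries,
    read_structure_hits,
    round_percent,
)
from .provenance_dating import (
    DateAccounting,
    ProvenanceRecord,
    build_provenance,
    summarize_dates,
)
from .sequence_evidence import (
    SequenceEvidence,
    SequenceOutcome,
    classify_sequence_evidence,
    summarize_sequence_stage,
)
from .structure_evidence import (
    StructureEvidence,
    StructureOutcome,
    classify_structure_evidence,
    summarize_structure_stage,
)

logger = logging.getLogger("pdbtriage")

__all__ = [
    "FinalLabel",
    "EntryVerdict",
    "FunnelReport",
    "PipelineResult",
    "percentage",
    "build_funnel",
    "write_report",
    "read_report",
    "write_verdicts",
    "write_provenance",
    "run_pipeline",
]


class FinalLabel(Enum):
    TRUE_UNKNOWN = "TRUE_UNKNOWN"
    REANNOTATION_CANDIDATE = "REANNOTATION_CANDIDATE"
    CHARACTERIZED_IN_SEQUENCE_DB = "CHARACTERIZED_IN_SEQUENCE_DB"


def percentage(numerator: int, denominator: int) -> float:
    """100·numerator/denominator, 2 dp, round-half-away-from-zero."""
    return round_percent(numerator, denominator)


def _pct(numerator: int, denominator: int) -> float:
    return round_percent(numerator, denominator) if denominator > 0 else 0.0


@dataclass(frozen=True)
class EntryVerdict:
    """Accumulated stage outcomes and final label for one entry."""

    pdb_id: str
    annotation_status: AnnotationStatus
    sequence_evidence: SequenceEvidence | None = None
    structure_evidence: StructureEvidence | None = None
    provenance: ProvenanceRecord | None = None
    final_label: FinalLabel = FinalLabel.TRUE_UNKNOWN

    def __post_init__(self) -> None:
        sufficient = self.annotation_status is AnnotationStatus.SUFFICIENT
        if sufficient != (self.sequence_evidence is None):
            raise ConsistencyError(
                f"{self.pdb_id}: sequence evidence present iff entry was forwarded"
            )
        if self.sequence_evidence is not None:
            expect_struct = not self.sequence_evidence.is_significant
            if expect_struct != (self.structure_evidence is not None):
                raise ConsistencyError(
                    f"{self.pdb_id}: structure evidence present iff sequence "
                    f"outcome is not significant"
                )
        elif self.structure_evidence is not None:
            raise ConsistencyError(
                f"{self.pdb_id}: structure evidence on a non-forwarded entry"
            )
        if self.final_label is not _derive_label(
            self.annotation_status, self.sequence_evidence, self.structure_evidence
        ):
            raise ConsistencyError(f"{self.pdb_id}: final label inconsistent")

    @classmethod
    def derive(
        cls,
        pdb_id: str,
        annotation_status: AnnotationStatus,
        sequence_evidence: SequenceEvidence | None = None,
        structure_evidence: StructureEvidence | None = None,
        provenance: ProvenanceRecord | None = None,
    ) -> "EntryVerdict":
        return cls(
            pdb_id=pdb_id,
            annotation_status=annotation_status,
            sequence_evidence=sequence_evidence,
            structure_evidence=structure_evidence,
            provenance=provenance,
            final_label=_derive_label(
                annotation_status, sequence_evidence, structure_evidence
            ),
        )


def _derive_label(
    status: AnnotationStatus,
    seq: SequenceEvidence | None,
    struct: StructureEvidence | None,
) -> FinalLabel:
    if status is AnnotationStatus.SUFFICIENT:
        return FinalLabel.CHARACTERIZED_IN_SEQUENCE_DB
    if seq is not None and seq.is_significant:
        return FinalLabel.REANNOTATION_CANDIDATE
    if struct is not None and struct.value is StructureOutcome.DEFINITE:
        return FinalLabel.REANNOTATION_CANDIDATE
    return FinalLabel.TRUE_UNKNOWN


@dataclass(frozen=True)
class FunnelReport:
    """Corpus-level counts, derived percentages and the final ID lists."""

    initial: int
    annotation_counts: dict[str, int]
    sequence_counts: dict[str, int]
    structure_counts: dict[str, int]
    percentages: dict[str, float]
    true_unknown_ids: tuple[str, ...]
    reannotation_candidate_ids: tuple[str, ...]

    # -- derived counts -----------------------------------------------------
    @property
    def forwarded_to_sequence(self) -> int:
        return self.initial - self.annotation_counts[AnnotationStatus.SUFFICIENT.value]

    @property
    def sequence_significant(self) -> int:
        return (
            self.sequence_counts[SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED.value]
            + self.sequence_counts[SequenceOutcome.SIGNIFICANT_MIXED.value]
        )

    @property
    def forwarded_to_structure(self) -> int:
        return self.forwarded_to_sequence - self.sequence_significant

    @property
    def structure_definite(self) -> int:
        return self.structure_counts[StructureOutcome.DEFINITE.value]

    @property
    def true_unknown_count(self) -> int:
        return len(self.true_unknown_ids)

    @property
    def reannotation_candidate_count(self) -> int:
        return len(self.reannotation_candidate_ids)

    @property
    def annotated_in_sequence_db(self) -> int:
        """Entries whose mapped record carries any annotation data field."""
        return (
            self.annotation_counts[AnnotationStatus.SUFFICIENT.value]
            + self.annotation_counts[AnnotationStatus.INSUFFICIENT.value]
        )


def build_funnel(verdicts: Sequence[EntryVerdict]) -> FunnelReport:
    """Assemble the funnel report and verify every conservation identity."""
    if not verdicts:
        raise ValidationError("cannot build a funnel report from zero verdicts")
    initial = len(verdicts)
    ann = Counter(v.annotation_status.value for v in verdicts)
    seq = Counter(
        v.sequence_evidence.value.value
        for v in verdicts
        if v.sequence_evidence is not None
    )
    struct = Counter(
        v.structure_evidence.value.value
        for v in verdicts
        if v.structure_evidence is not None
    )
    annotation_counts = {s.value: ann.get(s.value, 0) for s in AnnotationStatus}
    sequence_counts = {o.value: seq.get(o.value, 0) for o in SequenceOutcome}
    structure_counts = {o.value: struct.get(o.value, 0) for o in StructureOutcome}

    labels = Counter(v.final_label for v in verdicts)
    true_unknown = tuple(
        sorted(v.pdb_id for v in verdicts if v.final_label is FinalLabel.TRUE_UNKNOWN)
    )
    candidates = tuple(
        sorted(
            v.pdb_id
            for v in verdicts
            if v.final_label is FinalLabel.REANNOTATION_CANDIDATE
        )
    )

    forwarded_seq = initial - annotation_counts[AnnotationStatus.SUFFICIENT.value]
    significant = (
        sequence_counts[SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED.value]
        + sequence_counts[SequenceOutcome.SIGNIFICANT_MIXED.value]
    )
    forwarded_struct = forwarded_seq - significant
    definite = structure_counts[StructureOutcome.DEFINITE.value]

    if sum(annotation_counts.values()) != initial:
        raise ConsistencyError("annotation buckets do not sum to the corpus size")
    if sum(sequence_counts.values()) != forwarded_seq:
        raise ConsistencyError("sequence classes do not sum to forwarded entries")
    if sum(structure_counts.values()) != forwarded_struct:
        raise ConsistencyError("structure classes do not sum to forwarded entries")
    if len(true_unknown) != forwarded_struct - definite:
        raise ConsistencyError("true-unknown count violates funnel conservation")
    if len(candidates) != significant + definite:
        raise ConsistencyError("candidate count violates funnel conservation")
    if labels[FinalLabel.CHARACTERIZED_IN_SEQUENCE_DB] + len(candidates) + len(
        true_unknown
    ) != initial:
        raise ConsistencyError("final labels do not partition the corpus")

    annotated = (
        annotation_counts[AnnotationStatus.SUFFICIENT.value]
        + annotation_counts[AnnotationStatus.INSUFFICIENT.value]
    )
    percentages = {
        "sufficient_of_initial": _pct(
            annotation_counts[AnnotationStatus.SUFFICIENT.value], initial
        ),
        "annotated_in_sequence_db_of_initial": _pct(annotated, initial),
        "forwarded_to_sequence_of_initial": _pct(forwarded_seq, initial),
        "sequence_significant_of_queries": _pct(significant, forwarded_seq),
        "sequence_all_characterized_of_queries": _pct(
            sequence_counts[SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED.value],
            forwarded_seq,
        ),
        "sequence_mixed_of_queries": _pct(
            sequence_counts[SequenceOutcome.SIGNIFICANT_MIXED.value], forwarded_seq
        ),
        "sequence_discarded_only_of_queries": _pct(
            sequence_counts[SequenceOutcome.DISCARDED_ONLY.value], forwarded_seq
        ),
        "sequence_sub_threshold_of_queries": _pct(
            sequence_counts[SequenceOutcome.SUB_THRESHOLD.value], forwarded_seq
        ),
        "sequence_no_hits_of_queries": _pct(
            sequence_counts[SequenceOutcome.NO_HITS.value], forwarded_seq
        ),
        "forwarded_to_structure_of_sequence_queries": _pct(
            forwarded_struct, forwarded_seq
        ),
        "structure_definite_of_queries": _pct(definite, forwarded_struct),
        "structure_probable_of_queries": _pct(
            structure_counts[StructureOutcome.PROBABLE.value], forwarded_struct
        ),
        "structure_unrelated_of_queries": _pct(
            structure_counts[StructureOutcome.UNRELATED.value], forwarded_struct
        ),
        "structure_no_hits_of_queries": _pct(
            structure_counts[StructureOutcome.NO_HITS.value], forwarded_struct
        ),
        "structure_definite_or_probable_of_queries": _pct(
            definite + structure_counts[StructureOutcome.PROBABLE.value],
            forwarded_struct,
        ),
        "reannotation_candidates_of_initial": _pct(len(candidates), initial),
        "true_unknown_of_initial": _pct(len(true_unknown), initial),
    }
    return FunnelReport(
        initial=initial,
        annotation_counts=annotation_counts,
        sequence_counts=sequence_counts,
        structure_counts=structure_counts,
        percentages=percentages,
        true_unknown_ids=true_unknown,
        reannotation_candidate_ids=candidates,
    )


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def _tsv_rows(report: FunnelReport) -> list[tuple[str, int, float]]:
    """One ``(stage, count, percent)`` row per funnel node.

    Denominators follow funnel convention: annotation and final rows are
    percentages of the initial corpus, sequence rows of the sequence-stage
    queries, structure rows of the structure-stage queries.
    """
    a, s, t, p = (
        report.annotation_counts,
        report.sequence_counts,
        report.structure_counts,
        report.percentages,
    )
    return [
        ("initial", report.initial, 100.0),
        ("annotation_sufficient", a["SUFFICIENT"], p["sufficient_of_initial"]),
        (
            "annotation_insufficient",
            a["INSUFFICIENT"],
            _pct(a["INSUFFICIENT"], report.initial),
        ),
        (
            "annotation_uncharacterized_equivalent",
            a["UNCHARACTERIZED_EQUIVALENT"],
            _pct(a["UNCHARACTERIZED_EQUIVALENT"], report.initial),
        ),
        ("annotation_no_mapping", a["NO_MAPPING"], _pct(a["NO_MAPPING"], report.initial)),
        (
            "annotated_in_sequence_db",
            report.annotated_in_sequence_db,
            p["annotated_in_sequence_db_of_initial"],
        ),
        (
            "forwarded_to_sequence",
            report.forwarded_to_sequence,
            p["forwarded_to_sequence_of_initial"],
        ),
        (
            "sequence_significant_all_characterized",
            s["SIGNIFICANT_ALL_CHARACTERIZED"],
            p["sequence_all_characterized_of_queries"],
        ),
        (
            "sequence_significant_mixed",
            s["SIGNIFICANT_MIXED"],
            p["sequence_mixed_of_queries"],
        ),
        (
            "sequence_significant",
            report.sequence_significant,
            p["sequence_significant_of_queries"],
        ),
        (
            "sequence_discarded_only",
            s["DISCARDED_ONLY"],
            p["sequence_discarded_only_of_queries"],
        ),
        (
            "sequence_sub_threshold",
            s["SUB_THRESHOLD"],
            p["sequence_sub_threshold_of_queries"],
        ),
        ("sequence_no_hits", s["NO_HITS"], p["sequence_no_hits_of_queries"]),
        (
            "forwarded_to_structure",
            report.forwarded_to_structure,
            p["forwarded_to_structure_of_sequence_queries"],
        ),
        ("structure_definite", t["DEFINITE"], p["structure_definite_of_queries"]),
        ("structure_probable", t["PROBABLE"], p["structure_probable_of_queries"]),
        (
            "structure_definite_or_probable",
            t["DEFINITE"] + t["PROBABLE"],
            p["structure_definite_or_probable_of_queries"],
        ),
        ("structure_unrelated", t["UNRELATED"], p["structure_unrelated_of_queries"]),
        ("structure_no_hits", t["NO_HITS"], p["structure_no_hits_of_queries"]),
        (
            "reannotation_candidates",
            report.reannotation_candidate_count,
            p["reannotation_candidates_of_initial"],
        ),
        ("true_unknown", report.true_unknown_count, p["true_unknown_of_initial"]),
    ]


def write_report(report: FunnelReport, path: str | Path, format: str = "json") -> None:
    """Serialize the report.

    ``json`` round-trips every count and both ID lists exactly (see
    :func:`read_report`); ``tsv`` is the human-readable funnel table with one
    ``stage  count  percent`` row per node.
    """
    path = Path(path)
    if format == "json":
        doc = {
            "initial": report.initial,
            "annotation_counts": report.annotation_counts,
            "sequence_counts": report.sequence_counts,
            "structure_counts": report.structure_counts,
            "percentages": report.percentages,
            "true_unknown_ids": list(report.true_unknown_ids),
            "reannotation_candidate_ids": list(report.reannotation_candidate_ids),
        }
        path.write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
    elif format == "tsv":
        lines = ["stage\tcount\tpercent"]
        for stage, count, pct in _tsv_rows(report):
            lines.append(f"{stage}\t{count}\t{pct:.2f}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValidationError(f"unknown report format {format!r} (want tsv or json)")


def read_report(path: str | Path, format: str = "json"):
    """Read a serialized report back.

    ``json`` reconstructs the full :class:`FunnelReport`; ``tsv`` returns a
    ``{stage: (count, percent)}`` mapping of the funnel rows.
    """
    path = Path(path)
    if format == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        return FunnelReport(
            initial=doc["initial"],
            annotation_counts=dict(doc["annotation_counts"]),
            sequence_counts=dict(doc["sequence_counts"]),
            structure_counts=dict(doc["structure_counts"]),
            percentages=dict(doc["percentages"]),
            true_unknown_ids=tuple(doc["true_unknown_ids"]),
            reannotation_candidate_ids=tuple(doc["reannotation_candidate_ids"]),
        )
    if format == "tsv":
        rows: dict[str, tuple[int, float]] = {}
        lines = path.read_text(encoding="utf-8").splitlines()
        for line in lines[1:]:
            stage, count, pct = line.split("\t")
            rows[stage] = (int(count), float(pct))
        return rows
    raise ValidationError(f"unknown report format {format!r} (want tsv or json)")


def write_verdicts(verdicts: Sequence[EntryVerdict], path: str | Path) -> None:
    lines = ["pdb_id\tannotation_status\tsequence_outcome\tstructure_outcome\tfinal_label"]
    for v in verdicts:
        lines.append(
            "\t".join(
                [
                    v.pdb_id,
                    v.annotation_status.value,
                    v.sequence_evidence.value.value if v.sequence_evidence else "",
                    v.structure_evidence.value.value if v.structure_evidence else "",
                    v.final_label.value,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_provenance(records: Sequence[ProvenanceRecord], path: str | Path) -> None:
    lines = [
        "query_id\tquery_date\tearliest_hit_date\thit_postdates_query\tlag_years\tdiscrepancy_flags"
    ]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.query_id,
                    r.query_date.isoformat(),
                    r.earliest_hit_date.isoformat() if r.earliest_hit_date else "",
                    "" if r.hit_postdates_query is None else str(r.hit_postdates_query).lower(),
                    "" if r.lag_years is None else str(r.lag_years),
                    ",".join(sorted(f.value for f in r.discrepancy_flags)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineResult:
    report: FunnelReport
    verdicts: tuple[EntryVerdict, ...]
    provenance: tuple[ProvenanceRecord, ...]
    date_accounting: DateAccounting


def run_pipeline(
    entries_path: str | Path,
    annotations_path: str | Path,
    sequence_hits_path: str | Path,
    structure_hits_path: str | Path,
    config: TriageConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run all four stages over the four input files.

    Deterministic given inputs and config.  When ``out_dir`` is given,
    writes ``report.json``, ``report.tsv``, ``verdicts.tsv``,
    ``provenance.tsv`` and ``date_accounting.json`` there.
    """
    config = config or TriageConfig()
    blacklist = config.blacklist
    entries = read_structure_entries(entries_path)
    annotations = read_annotations(annotations_path)
    seq_hits = read_sequence_hits(sequence_hits_path, annotations, config.strict_hits)
    struct_hits = read_structure_hits(structure_hits_path)
    initial_ids = {e.pdb_id for e in entries}
    logger.info(
        "inputs: %d entries, %d annotation records, %d/%d queries with "
        "sequence/structure hits",
        len(entries), len(annotations), len(seq_hits), len(struct_hits),
    )

    verdicts: list[EntryVerdict] = []
    seq_outcomes: dict[str, SequenceEvidence] = {}
    struct_outcomes: dict[str, StructureEvidence] = {}
    provenance: list[ProvenanceRecord] = []
    for entry in entries:
        status = classify_annotation_status(
            entry,
            annotations,
            blacklist,
            config.min_go_terms,
            config.accession_policy,
        )
        seq_ev = struct_ev = prov = None
        if status is not AnnotationStatus.SUFFICIENT:
            seq_ev = classify_sequence_evidence(
                seq_hits.get(entry.pdb_id, []), config.cutoffs, blacklist
            )
            seq_outcomes[entry.pdb_id] = seq_ev
            if not seq_ev.is_significant:
                struct_ev = classify_structure_evidence(
                    struct_hits.get(entry.pdb_id, []),
                    config.bands,
                    initial_ids,
                    blacklist,
                )
                struct_outcomes[entry.pdb_id] = struct_ev
            prov = build_provenance(
                entry, seq_ev, struct_ev, config.function_vocabulary, blacklist
            )
            provenance.append(prov)
        verdicts.append(
            EntryVerdict.derive(entry.pdb_id, status, seq_ev, struct_ev, prov)
        )

    report = build_funnel(verdicts)
    dates = summarize_dates(
        provenance, seq_outcomes, struct_outcomes, config.fraction_denominator
    )
    logger.info(
        "stage 1: %d in -> %d forwarded (dropped: %s)",
        report.initial, report.forwarded_to_sequence,
        dict(report.annotation_counts),
    )
    logger.info(
        "stage 2: %d in -> %d forwarded (classes: %s)",
        report.forwarded_to_sequence, report.forwarded_to_structure,
        summarize_sequence_stage(seq_outcomes),
    )
    logger.info(
        "stage 3: %d in -> %d true unknown (classes: %s)",
        report.forwarded_to_structure, report.true_unknown_count,
        summarize_structure_stage(struct_outcomes),
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(report, out_dir / "report.json", "json")
        write_report(report, out_dir / "report.tsv", "tsv")
        write_verdicts(verdicts, out_dir / "verdicts.tsv")
        write_provenance(provenance, out_dir / "provenance.tsv")
        (out_dir / "date_accounting.json").write_text(
            json.dumps(
                {
                    "fraction_hits_postdate_blast": dates.fraction_hits_postdate_blast,
                    "fraction_hits_postdate_dali": dates.fraction_hits_postdate_dali,
                    "predating_query_ids": list(dates.predating_query_ids),
                },
                indent=1,
            )
            + "\n",
            encoding="utf-8",
        )
    return PipelineResult(report, tuple(verdicts), tuple(provenance), dates)
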