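"""Seeded synthetic corpora with exactly prescribed funnel structure.

``generate_corpus`` writes the four fixture files so that running the
pipeline with default configuration reproduces a :class:`CorpusSpec`'s
per-class counts *exactly*: every record is built to land in its intended
class by construction (a sufficient entry gets an informative name plus a
qualifying annotation route; a significant query gets a characterized hit
strictly above the relevant identity cutoff; and so on).  Boundary records —
identity exactly at 40/50/60 and Z-scores exactly at 8/20 — are deliberately
injected into the sub-threshold and probable pools to police the strict
inequalities of the classification rules.

``printed_funnel_spec`` is the fixed specification whose funnel matches the
published survey of unknown-function PDB entries (2549 entries; 868/520/
1097/64 annotation categories; 299/79/335/647/321 sequence classes; 219/381
definite/probable structural classes).

Everything is deterministic given the spec's seed; changing the seed changes
names and dates but never class counts.  No residue content is generated:
no stage consumes sequences.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .annotation_triage import AnnotationStatus
from .corpus_io import (
    GoAnnotation,
    GoDomain,
    ProteinAnnotation,
    SequenceHit,
    StructureEntry,
    StructureHit,
    ValidationError,
    write_annotations,
    write_sequence_hits,
    write_structure_entries,
    write_structure_hits,
)
from .sequence_evidence import IdentityCutoffs, SequenceOutcome
from .structure_evidence import StructureOutcome

__all__ = [
    "CorpusSpec",
    "printed_funnel_spec",
    "random_corpus_spec",
    "generate_corpus",
    "perturb_corpus",
    "FILE_NAMES",
]

FILE_NAMES = {
    "entries": "structure_entries.tsv",
    "annotations": "annotations.tsv",
    "sequence_hits": "sequence_hits.tsv",
    "structure_hits": "structure_hits.tsv",
}

DEFAULT_DATE_WINDOW = (date(1999, 12, 13), date(2007, 12, 31))
DEFAULT_SEED = 107

# -- controlled vocabularies ------------------------------------------------

SPECIES = (
    "Thermus thermophilus",
    "Bacillus subtilis",
    "Escherichia coli",
    "Haemophilus influenzae",
    "Pseudomonas aeruginosa",
    "Pyrococcus furiosus",
)
INFORMATIVE_PROTEIN_NAMES = (
    "Thymidine kinase",
    "NAD(P)H-hydrate epimerase",
    "Glucosyl-3-phosphoglycerate synthase",
    "Triosephosphate isomerase",
    "Phosphoglycolate phosphatase",
    "Aspartate aminotransferase",
    "Carboxymuconate cyclase",
)
UNINFORMATIVE_PROTEIN_NAMES = (
    "Uncharacterized protein {tag}",
    "Putative uncharacterized protein",
    "Hypothetical protein {tag}",
    "Predicted protein",
    "Unknown protein {tag}",
    "Probable kinase {tag}",
    "Unnamed protein product",
)
FUNCTIONAL_CLASSIFICATIONS = (
    "isomerase",
    "ligase",
    "transferase",
    "hydrolase",
    "lyase",
    "oxidoreductase",
)
MF_INFORMATIVE_TERMS = (
    "kinase activity",
    "isomerase activity",
    "hydrolase activity",
    "lyase activity",
)
MF_BINDING_TERMS = (
    "ATP binding",
    "DNA binding",
    "zinc ion binding",
    "metal ion binding",
)
BP_TERMS = (
    "phosphorylation",
    "glycolytic process",
    "DNA repair",
    "proteolysis",
    "transmembrane transport",
)
CC_TERMS = ("cytoplasm", "nucleus", "plasma membrane", "ribosome")

_B36 = "0123456789abcdefghijklmnopqrstuvwxyz"


def _base36(n: int, width: int) -> str:
    out = []
    for _ in range(width):
        n, r = divmod(n, 36)
        out.append(_B36[r])
    return "".join(reversed(out))


def _make_pdb_id(index: int, prefix_base: int = 1) -> str:
    hi, lo = divmod(index, 36**3)
    first = prefix_base + hi
    if not 0 <= first <= 9:
        raise ValidationError(f"pdb id space exhausted at index {index}")
    return f"{first}{_base36(lo, 3)}"


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorpusSpec:
    """Prescription of a synthetic corpus' funnel structure.

    ``fraction_postdating_*`` give, per evidence channel, the percent of
    significant queries whose evidence enters its database only after the
    query structure was deposited (the annotation-staleness condition).
    """

    n_entries: int
    annotation_counts: dict[AnnotationStatus, int]
    sequence_counts: dict[SequenceOutcome, int]
    structure_counts: dict[StructureOutcome, int]
    date_window: tuple[date, date] = DEFAULT_DATE_WINDOW
    fraction_postdating_blast: float = 43.65
    fraction_postdating_dali: float = 69.10
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_entries <= 0:
            raise ValidationError("n_entries must be positive")
        if any(v < 0 for v in self.annotation_counts.values()):
            raise ValidationError("negative annotation count")
        if sum(self.annotation_counts.values()) != self.n_entries:
            raise ValidationError("annotation counts must sum to n_entries")
        forwarded = self.n_entries - self.annotation_counts.get(
            AnnotationStatus.SUFFICIENT, 0
        )
        if sum(self.sequence_counts.values()) != forwarded:
            raise ValidationError(
                "sequence-class counts must sum to the forwarded total "
                f"({forwarded})"
            )
        significant = self.sequence_counts.get(
            SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED, 0
        ) + self.sequence_counts.get(SequenceOutcome.SIGNIFICANT_MIXED, 0)
        structure_total = forwarded - significant
        if sum(self.structure_counts.values()) != structure_total:
            raise ValidationError(
                "structure-class counts must sum to the structure-stage total "
                f"({structure_total})"
            )
        if self.date_window[0] >= self.date_window[1]:
            raise ValidationError("date_window must be (earliest, latest)")
        for f in (self.fraction_postdating_blast, self.fraction_postdating_dali):
            if not 0.0 <= f <= 100.0:
                raise ValidationError("postdating fractions must be in [0, 100]")

    @property
    def forwarded_to_sequence(self) -> int:
        return self.n_entries - self.annotation_counts.get(
            AnnotationStatus.SUFFICIENT, 0
        )

    @property
    def forwarded_to_structure(self) -> int:
        return self.forwarded_to_sequence - (
            self.sequence_counts.get(SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED, 0)
            + self.sequence_counts.get(SequenceOutcome.SIGNIFICANT_MIXED, 0)
        )

    def replace(self, **kwargs) -> "CorpusSpec":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorpusSpec":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))

        def _date(v):
            return v if isinstance(v, date) else date.fromisoformat(str(v))

        window = doc.get("date_window")
        kwargs = {}
        if window:
            kwargs["date_window"] = (_date(window[0]), _date(window[1]))
        for k in ("fraction_postdating_blast", "fraction_postdating_dali", "seed"):
            if k in doc:
                kwargs[k] = doc[k]
        return cls(
            n_entries=int(doc["n_entries"]),
            annotation_counts={
                AnnotationStatus(k): int(v)
                for k, v in doc["annotation_counts"].items()
            },
            sequence_counts={
                SequenceOutcome(k): int(v) for k, v in doc["sequence_counts"].items()
            },
            structure_counts={
                StructureOutcome(k): int(v)
                for k, v in doc["structure_counts"].items()
            },
            **kwargs,
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_entries": self.n_entries,
            "annotation_counts": {
                k.value: v for k, v in self.annotation_counts.items()
            },
            "sequence_counts": {k.value: v for k, v in self.sequence_counts.items()},
            "structure_counts": {
                k.value: v for k, v in self.structure_counts.items()
            },
            "date_window": [d.isoformat() for d in self.date_window],
            "fraction_postdating_blast": self.fraction_postdating_blast,
            "fraction_postdating_dali": self.fraction_postdating_dali,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def printed_funnel_spec(seed: int = DEFAULT_SEED) -> CorpusSpec:
    """The fixed corpus whose funnel matches the published survey.

    The published structure stage prints only the definite (219) and probable
    (381) classes plus their 703-entry residual; the residual's split between
    unrelated-only and hitless queries is a generator choice (352/351) that
    no reported number depends on.
    """
    return CorpusSpec(
        n_entries=2549,
        annotation_counts={
            AnnotationStatus.SUFFICIENT: 868,
            AnnotationStatus.INSUFFICIENT: 520,
            AnnotationStatus.UNCHARACTERIZED_EQUIVALENT: 1097,
            AnnotationStatus.NO_MAPPING: 64,
        },
        sequence_counts={
            SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED: 299,
            SequenceOutcome.SIGNIFICANT_MIXED: 79,
            SequenceOutcome.DISCARDED_ONLY: 335,
            SequenceOutcome.NO_HITS: 647,
            SequenceOutcome.SUB_THRESHOLD: 321,
        },
        structure_counts={
            StructureOutcome.DEFINITE: 219,
            StructureOutcome.PROBABLE: 381,
            StructureOutcome.UNRELATED: 352,
            StructureOutcome.NO_HITS: 351,
        },
        seed=seed,
    )


def _partition(rng: random.Random, total: int, parts: int) -> list[int]:
    if total == 0:
        return [0] * parts
    cuts = sorted(rng.randint(0, total) for _ in range(parts - 1))
    bounds = [0, *cuts, total]
    return [bounds[i + 1] - bounds[i] for i in range(parts)]


def random_corpus_spec(
    rng: random.Random, n_entries: int | None = None
) -> CorpusSpec:
    """A random valid spec (for property-based pipeline testing)."""
    n = n_entries or rng.randint(8, 500)
    a = _partition(rng, n, 4)
    annotation = dict(zip(list(AnnotationStatus), a))
    forwarded = n - annotation[AnnotationStatus.SUFFICIENT]
    s = _partition(rng, forwarded, 5)
    sequence = dict(zip(list(SequenceOutcome), s))
    pool = forwarded - (
        sequence[SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED]
        + sequence[SequenceOutcome.SIGNIFICANT_MIXED]
    )
    t = _partition(rng, pool, 4)
    structure = dict(zip(list(StructureOutcome), t))
    return CorpusSpec(
        n_entries=n,
        annotation_counts=annotation,
        sequence_counts=sequence,
        structure_counts=structure,
        fraction_postdating_blast=round(rng.uniform(0, 100), 2),
        fraction_postdating_dali=round(rng.uniform(0, 100), 2),
        seed=rng.randrange(2**31),
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

class _Builder:
    """Mutable generation state: counters, collections, one seeded RNG."""

    def __init__(self, spec: CorpusSpec):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.entries: list[StructureEntry] = []
        self.annotations: list[ProteinAnnotation] = []
        self.seq_hits: list[SequenceHit] = []
        self.struct_hits: list[StructureHit] = []
        self._go_counter = 0
        self._subject_counter = 0
        self._subject_pdb_counter = 0
        self._tag_counter = 0

    # -- primitive draws ----------------------------------------------------
    def go(self, domain: GoDomain, name: str) -> GoAnnotation:
        self._go_counter += 1
        return GoAnnotation(f"GO:{self._go_counter:07d}", domain, name)

    def tag(self) -> str:
        self._tag_counter += 1
        return f"yb{self._tag_counter:04d}"

    def rand_date(self) -> date:
        lo, hi = self.spec.date_window
        return lo + timedelta(days=self.rng.randint(0, (hi - lo).days))

    def offset_date(self, anchor: date, postdating: bool) -> date:
        delta = timedelta(days=self.rng.randint(180, 2500))
        return anchor + delta if postdating else anchor - delta

    def informative_name(self) -> str:
        return self.rng.choice(INFORMATIVE_PROTEIN_NAMES)

    def uninformative_name(self) -> str:
        return self.rng.choice(UNINFORMATIVE_PROTEIN_NAMES).format(tag=self.tag())

    def subject_accession(self) -> str:
        self._subject_counter += 1
        return f"P{self._subject_counter:05d}"

    def subject_pdb_id(self) -> str:
        # prefix 9 keeps structural subjects disjoint from the corpus id space
        pid = f"9{_base36(self._subject_pdb_counter, 3)}"
        self._subject_pdb_counter += 1
        return pid

    def mixed_go_profile(self) -> list[GoAnnotation]:
        return [
            self.go(GoDomain.BIOLOGICAL_PROCESS, self.rng.choice(BP_TERMS)),
            self.go(GoDomain.MOLECULAR_FUNCTION, self.rng.choice(MF_INFORMATIVE_TERMS)),
            self.go(GoDomain.CELLULAR_COMPONENT, self.rng.choice(CC_TERMS)),
        ]


def _entry_annotation(b: _Builder, status: AnnotationStatus, accession: str) -> ProteinAnnotation:
    """Build the sequence record that puts an entry into ``status``."""
    rng = b.rng
    if status is AnnotationStatus.SUFFICIENT:
        route = rng.randrange(4)
        rec = dict(
            accession=accession,
            protein_name=b.informative_name(),
            reviewed=rng.random() < 0.5,
            integration_date=b.rand_date(),
        )
        if route == 0:
            rec["function_text"] = "Catalyzes the committed step of its pathway."
        elif route == 1:
            rec["catalytic_activity"] = "ATP + thymidine = ADP + thymidine 5'-phosphate"
        elif route == 2:
            rec["ec_numbers"] = (rng.choice(("2.7.1.21", "5.5.1.5", "2.7.1.-")),)
        else:
            rec["go_terms"] = tuple(b.mixed_go_profile())
        return ProteinAnnotation(**rec)
    if status is AnnotationStatus.INSUFFICIENT:
        # informative name but every sufficiency route fails
        mode = rng.randrange(4)
        if mode == 0:
            terms: tuple[GoAnnotation, ...] = ()
        elif mode == 1:
            terms = (b.go(GoDomain.MOLECULAR_FUNCTION, rng.choice(MF_INFORMATIVE_TERMS)),
                     b.go(GoDomain.BIOLOGICAL_PROCESS, rng.choice(BP_TERMS)))
        elif mode == 2:
            terms = tuple(b.go(GoDomain.CELLULAR_COMPONENT, rng.choice(CC_TERMS)) for _ in range(3))
        else:
            terms = tuple(b.go(GoDomain.MOLECULAR_FUNCTION, rng.choice(MF_BINDING_TERMS)) for _ in range(3))
        return ProteinAnnotation(
            accession=accession,
            protein_name=b.informative_name(),
            reviewed=rng.random() < 0.5,
            go_terms=terms,
            integration_date=b.rand_date(),
        )
    # UNCHARACTERIZED_EQUIVALENT: the blacklist dominates any GO richness
    terms = (
        tuple(b.mixed_go_profile()) + tuple(b.mixed_go_profile())
        if rng.random() < 0.4
        else ()
    )
    return ProteinAnnotation(
        accession=accession,
        protein_name=b.uninformative_name(),
        reviewed=rng.random() < 0.5,
        go_terms=terms,
        integration_date=b.rand_date(),
    )


def _subject_record(
    b: _Builder,
    name: str,
    go_terms: Sequence[GoAnnotation],
    integration_date: date,
) -> str:
    acc = b.subject_accession()
    b.annotations.append(
        ProteinAnnotation(
            accession=acc,
            protein_name=name,
            reviewed=True,
            go_terms=tuple(go_terms),
            integration_date=integration_date,
        )
    )
    return acc


def _blast_row(
    b: _Builder, query_id: str, subject_acc: str, pident: float
) -> SequenceHit:
    rng = b.rng
    length = rng.randint(80, 400)
    mism = int(length * (100.0 - pident) / 100.0)
    return SequenceHit(
        query_id=query_id,
        subject_accession=subject_acc,
        percent_identity=round(pident, 2),
        alignment_length=length,
        mismatches=min(mism, length),
        gap_opens=rng.randint(0, 3),
        query_start=1,
        query_end=length,
        subject_start=1,
        subject_end=length,
        e_value=10.0 ** -rng.uniform(3, 60),
        bit_score=round(rng.uniform(50, 400), 1),
    )


def _supporting_hit(
    b: _Builder, query_id: str, hit_date: date
) -> SequenceHit:
    """A characterized hit strictly above one domain's identity cutoff."""
    rng = b.rng
    cutoffs = IdentityCutoffs()
    domain = rng.choice(list(GoDomain))
    if domain is GoDomain.BIOLOGICAL_PROCESS:
        pident = rng.uniform(cutoffs.biological_process + 1, 95)
        terms = [b.go(domain, rng.choice(BP_TERMS))]
    elif domain is GoDomain.MOLECULAR_FUNCTION:
        pident = rng.uniform(cutoffs.molecular_function + 1, 95)
        terms = [b.go(domain, rng.choice(MF_INFORMATIVE_TERMS))]
        if rng.random() < 0.3:  # extra binding term must not disable MF support
            terms.append(b.go(domain, rng.choice(MF_BINDING_TERMS)))
    else:
        pident = rng.uniform(cutoffs.cellular_component + 1, 95)
        terms = [b.go(domain, rng.choice(CC_TERMS))]
    acc = _subject_record(b, b.informative_name(), terms, hit_date)
    return _blast_row(b, query_id, acc, pident)


def _sub_threshold_hit(b: _Builder, query_id: str, mode: int) -> SequenceHit:
    """A characterized hit with no supported domain (incl. exact boundaries)."""
    rng = b.rng
    if mode == 0:  # below every cutoff, full GO profile
        pident = rng.uniform(10, 39)
        terms = b.mixed_go_profile()
    elif mode == 1:  # exactly at the BP cutoff
        pident = 40.0
        terms = [b.go(GoDomain.BIOLOGICAL_PROCESS, rng.choice(BP_TERMS))]
    elif mode == 2:  # exactly at the MF cutoff
        pident = 50.0
        terms = [b.go(GoDomain.MOLECULAR_FUNCTION, rng.choice(MF_INFORMATIVE_TERMS))]
    elif mode == 3:  # exactly at the CC cutoff
        pident = 60.0
        terms = [b.go(GoDomain.CELLULAR_COMPONENT, rng.choice(CC_TERMS))]
    elif mode == 4:  # above the MF cutoff but only "*-binding" MF terms
        pident = rng.uniform(51, 95)
        terms = [b.go(GoDomain.MOLECULAR_FUNCTION, rng.choice(MF_BINDING_TERMS))]
    else:  # characterized subject with no GO profile at all
        pident = rng.uniform(41, 95)
        terms = []
    acc = _subject_record(b, b.informative_name(), terms, b.rand_date())
    return _blast_row(b, query_id, acc, pident)


def _discarded_hit(b: _Builder, query_id: str) -> SequenceHit:
    """A hit whose subject name is uncharacterized-style (never evidence)."""
    rng = b.rng
    terms = b.mixed_go_profile() if rng.random() < 0.5 else []
    acc = _subject_record(b, b.uninformative_name(), terms, b.rand_date())
    return _blast_row(b, query_id, acc, rng.uniform(20, 95))


def _dali_row(
    b: _Builder,
    query_id: str,
    z: float,
    classification: str,
    name: str,
    hit_date: date,
    subject_id: str | None = None,
) -> StructureHit:
    return StructureHit(
        query_id=query_id,
        subject_pdb_id=subject_id or b.subject_pdb_id(),
        z_score=round(z, 1),
        rmsd_angstrom=round(b.rng.uniform(0.5, 4.5), 1),
        subject_classification=classification,
        subject_name=name,
        subject_deposition_date=hit_date,
    )


def _postdating_flags(rng: random.Random, n: int, fraction: float) -> list[bool]:
    k = int(fraction / 100.0 * n + 0.5)
    flags = [True] * k + [False] * (n - k)
    rng.shuffle(flags)
    return flags


def generate_corpus(spec: CorpusSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the four fixture files for ``spec``; returns their paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    b = _Builder(spec)
    rng = b.rng

    statuses: list[AnnotationStatus] = []
    for status in AnnotationStatus:
        statuses.extend([status] * spec.annotation_counts.get(status, 0))
    rng.shuffle(statuses)

    seq_classes: list[SequenceOutcome] = []
    for outcome in SequenceOutcome:
        seq_classes.extend([outcome] * spec.sequence_counts.get(outcome, 0))
    rng.shuffle(seq_classes)

    struct_classes: list[StructureOutcome] = []
    for outcome in StructureOutcome:
        struct_classes.extend([outcome] * spec.structure_counts.get(outcome, 0))
    rng.shuffle(struct_classes)

    # ---- entries + stage-1 records ----------------------------------------
    forwarded: list[tuple[StructureEntry, SequenceOutcome]] = []
    seq_iter = iter(seq_classes)
    for i, status in enumerate(statuses):
        pdb_id = _make_pdb_id(i)
        qdate = b.rand_date()
        classification = "unknown function"
        molecule_name = f"hypothetical protein {b.tag().upper()}"
        r = rng.random()
        if r < 0.03:  # informative name under an unknown-function header
            molecule_name = "Walker type ATP-ase"
        elif r < 0.06:  # functional header over a placeholder name
            classification = rng.choice(FUNCTIONAL_CLASSIFICATIONS)
            molecule_name = f"Hypothetical protein {b.tag()}"
        accessions: tuple[str, ...] = ()
        if status is AnnotationStatus.NO_MAPPING:
            if rng.random() < 0.5:  # dangling accession also fails to resolve
                accessions = (f"Z{i:05d}",)
        else:
            acc = f"Q{i:05d}"
            accessions = (acc,)
            b.annotations.append(_entry_annotation(b, status, acc))
        entry = StructureEntry(
            pdb_id=pdb_id,
            molecule_name=molecule_name,
            classification_header=classification,
            deposition_date=qdate,
            species=rng.choice(SPECIES),
            accessions=accessions,
        )
        b.entries.append(entry)
        if status is not AnnotationStatus.SUFFICIENT:
            forwarded.append((entry, next(seq_iter)))

    # ---- stage-2 hit tables ------------------------------------------------
    significant = [
        (e, c)
        for e, c in forwarded
        if c
        in (
            SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED,
            SequenceOutcome.SIGNIFICANT_MIXED,
        )
    ]
    postdates_blast = {
        e.pdb_id: flag
        for (e, _), flag in zip(
            significant,
            _postdating_flags(rng, len(significant), spec.fraction_postdating_blast),
        )
    }

    sub_mode = 0
    for qi, (entry, outcome) in enumerate(forwarded):
        query_id = entry.pdb_id + ("_A" if qi % 7 == 0 else "")
        rows: list[SequenceHit] = []
        if outcome in (
            SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED,
            SequenceOutcome.SIGNIFICANT_MIXED,
        ):
            side = postdates_blast[entry.pdb_id]
            for _ in range(rng.randint(1, 3)):
                rows.append(
                    _supporting_hit(
                        b, query_id, b.offset_date(entry.deposition_date, side)
                    )
                )
            if outcome is SequenceOutcome.SIGNIFICANT_MIXED:
                rows.append(_discarded_hit(b, query_id))
            elif rng.random() < 0.25:  # extra sub-threshold hit keeps class
                rows.append(_sub_threshold_hit(b, query_id, 0))
        elif outcome is SequenceOutcome.DISCARDED_ONLY:
            for _ in range(rng.randint(1, 3)):
                rows.append(_discarded_hit(b, query_id))
        elif outcome is SequenceOutcome.SUB_THRESHOLD:
            for _ in range(rng.randint(1, 2)):
                rows.append(_sub_threshold_hit(b, query_id, sub_mode % 6))
                sub_mode += 1
        rows.sort(key=lambda h: -h.bit_score)
        b.seq_hits.extend(rows)

    # ---- stage-3 hit tables ------------------------------------------------
    structure_pool = [
        (e, c)
        for e, c in forwarded
        if c
        not in (
            SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED,
            SequenceOutcome.SIGNIFICANT_MIXED,
        )
    ]
    struct_iter = iter(struct_classes)
    assignments = [(e, next(struct_iter)) for e, _ in structure_pool]
    definite = [e for e, c in assignments if c is StructureOutcome.DEFINITE]
    postdates_dali = {
        e.pdb_id: flag
        for e, flag in zip(
            definite, _postdating_flags(rng, len(definite), spec.fraction_postdating_dali)
        )
    }
    probable_seen = 0
    corpus_ids = [e.pdb_id for e in b.entries]
    for entry, outcome in assignments:
        rows: list[StructureHit] = []
        if outcome is StructureOutcome.DEFINITE:
            side = postdates_dali[entry.pdb_id]
            hit_date = b.offset_date(entry.deposition_date, side)
            best_z = rng.uniform(20.5, 55)
            rows.append(
                _dali_row(
                    b, entry.pdb_id, best_z,
                    rng.choice(FUNCTIONAL_CLASSIFICATIONS),
                    b.informative_name(), hit_date,
                )
            )
            if rng.random() < 0.3:  # a weaker admissible hit never outranks
                rows.append(
                    _dali_row(
                        b, entry.pdb_id, rng.uniform(20.5, best_z - 0.2),
                        rng.choice(FUNCTIONAL_CLASSIFICATIONS),
                        b.informative_name(), hit_date,
                    )
                )
            if rng.random() < 0.2:  # inadmissible hit of any Z is inert
                rows.append(
                    _dali_row(
                        b, entry.pdb_id, 60.0, "unknown function",
                        b.uninformative_name(), b.rand_date(),
                    )
                )
        elif outcome is StructureOutcome.PROBABLE:
            if probable_seen == 0:
                z = 20.0  # exact ceiling: not a definite homolog
            elif probable_seen == 1:
                z = 8.0  # exact floor: still a probable homolog
            else:
                z = rng.uniform(8.5, 19.5)
            probable_seen += 1
            rows.append(
                _dali_row(
                    b, entry.pdb_id, z,
                    rng.choice(FUNCTIONAL_CLASSIFICATIONS),
                    b.informative_name(), b.rand_date(),
                )
            )
            if rng.random() < 0.2:  # blacklisted-name hit above 20 is inert
                rows.append(
                    _dali_row(
                        b, entry.pdb_id, 30.0,
                        rng.choice(FUNCTIONAL_CLASSIFICATIONS),
                        b.uninformative_name(), b.rand_date(),
                    )
                )
        elif outcome is StructureOutcome.UNRELATED:
            for _ in range(rng.randint(1, 2)):
                rows.append(
                    _dali_row(
                        b, entry.pdb_id, rng.uniform(1.5, 7.5),
                        rng.choice(FUNCTIONAL_CLASSIFICATIONS),
                        b.informative_name(), b.rand_date(),
                    )
                )
            if rng.random() < 0.2 and len(corpus_ids) > 1:
                # a self-dataset subject is excluded even at high Z
                other = rng.choice(corpus_ids)
                if other != entry.pdb_id:
                    rows.append(
                        _dali_row(
                            b, entry.pdb_id, 25.0,
                            rng.choice(FUNCTIONAL_CLASSIFICATIONS),
                            b.informative_name(), b.rand_date(),
                            subject_id=other,
                        )
                    )
        else:  # NO_HITS: nothing, or only inadmissible rows
            if rng.random() < 0.15:
                rows.append(
                    _dali_row(
                        b, entry.pdb_id, 25.0, "unknown function",
                        b.uninformative_name(), b.rand_date(),
                    )
                )
        rows.sort(key=lambda h: -h.z_score)
        b.struct_hits.extend(rows)

    paths = {k: out_dir / v for k, v in FILE_NAMES.items()}
    write_structure_entries(b.entries, paths["entries"])
    write_annotations(b.annotations, paths["annotations"])
    write_sequence_hits(b.seq_hits, paths["sequence_hits"])
    write_structure_hits(b.struct_hits, paths["structure_hits"])
    return paths


# ---------------------------------------------------------------------------
# Metamorphic perturbations
# ---------------------------------------------------------------------------

def perturb_corpus(
    paths: Mapping[str, Path | str],
    op: str,
    seed: int,
    out_dir: str | Path,
    relabel_map: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Perturb fixture files in ways the pipeline's counts must ignore.

    ``shuffle_rows`` permutes data rows within each file; ``relabel_ids``
    renames every corpus entry ID through a bijection (a supplied
    ``relabel_map`` must be bijective).  Class counts are invariant under
    both; ``relabel_ids`` relabels the reported ID lists accordingly.
    """
    if op not in ("shuffle_rows", "relabel_ids"):
        raise ValidationError(f"unknown perturbation {op!r}")
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: Path(v) for k, v in paths.items()}
    out_paths = {k: out_dir / p.name for k, p in paths.items()}

    def _lines(p: Path) -> list[str]:
        return p.read_text(encoding="utf-8").splitlines()

    if op == "shuffle_rows":
        for key, p in paths.items():
            lines = _lines(p)
            header = [] if key == "sequence_hits" else lines[:1]
            data = lines[len(header):]
            rng.shuffle(data)
            out_paths[key].write_text(
                "\n".join(header + data) + ("\n" if header + data else ""),
                encoding="utf-8",
            )
        return out_paths

    # relabel_ids
    entry_lines = _lines(paths["entries"])
    old_ids = [line.split("\t", 1)[0] for line in entry_lines[1:]]
    taken = set(old_ids)
    for line in _lines(paths["structure_hits"])[1:]:
        taken.add(line.split("\t")[1])
    if relabel_map is not None:
        mapping = dict(relabel_map)
        if len(set(mapping.values())) != len(mapping):
            raise ValidationError("relabel map is not bijective")
    else:
        mapping = {}
        counter = 0
        for old in old_ids:
            while True:
                candidate = f"8{_base36(counter, 3)}"
                counter += 1
                if candidate not in taken:
                    break
            mapping[old] = candidate
            taken.add(candidate)

    def _map_qseqid(qid: str) -> str:
        head, sep, tail = qid.partition("_")
        return mapping.get(head, head) + sep + tail

    out = [entry_lines[0]]
    for line in entry_lines[1:]:
        first, _, rest = line.partition("\t")
        out.append(mapping.get(first, first) + "\t" + rest)
    out_paths["entries"].write_text("\n".join(out) + "\n", encoding="utf-8")

    seq_lines = _lines(paths["sequence_hits"])
    out = []
    for line in seq_lines:
        first, _, rest = line.partition("\t")
        out.append(_map_qseqid(first) + "\t" + rest)
    out_paths["sequence_hits"].write_text(
        "\n".join(out) + ("\n" if out else ""), encoding="utf-8"
    )

    struct_lines = _lines(paths["structure_hits"])
    out = [struct_lines[0]]
    for line in struct_lines[1:]:
        fields = line.split("\t")
        fields[0] = mapping.get(fields[0], fields[0])
        fields[1] = mapping.get(fields[1], fields[1])
        out.append("\t".join(fields))
    out_paths["structure_hits"].write_text("\n".join(out) + "\n", encoding="utf-8")

    # annotations carry no PDB identifiers
    out_paths["annotations"].write_text(
        paths["annotations"].read_text(encoding="utf-8"), encoding="utf-8"
    )
    return out_paths
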