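"""Shared test utilities: record builders and an independent rule oracle.

``brute_force_labels`` re-implements the whole rule set straight-line from
the raw files (stdlib only, no package imports) so pipeline outputs can be
cross-checked against a second, structurally different implementation.
"""

from __future__ import annotations

import re
from collections import defaultdict
from datetime import date
from pathlib import Path

from pdbtriage import (
    GoAnnotation,
    GoDomain,
    ProteinAnnotation,
    SequenceHit,
    StructureEntry,
    StructureHit,
)

# ---------------------------------------------------------------------------
# Builders with sensible defaults (package-facing)
# ---------------------------------------------------------------------------

_go_counter = 0


def make_go(domain=GoDomain.MOLECULAR_FUNCTION, name="kinase activity"):
    global _go_counter
    _go_counter += 1
    return GoAnnotation(f"GO:{_go_counter:07d}", domain, name)


def make_entry(pdb_id="1abc", accessions=(), **kw):
    defaults = dict(
        molecule_name="hypothetical protein YB01",
        classification_header="unknown function",
        deposition_date=date(2003, 6, 1),
        species="Thermus thermophilus",
    )
    defaults.update(kw)
    return StructureEntry(pdb_id=pdb_id, accessions=tuple(accessions), **defaults)


def make_annotation(accession="Q00001", protein_name="Thymidine kinase", **kw):
    defaults = dict(reviewed=True, integration_date=date(2005, 1, 1))
    defaults.update(kw)
    return ProteinAnnotation(accession=accession, protein_name=protein_name, **defaults)


def make_seq_hit(
    query_id="1abc",
    subject_accession="P00001",
    percent_identity=55.0,
    subject_name="Thymidine kinase",
    subject_go_terms=(),
    subject_integration_date=date(2005, 1, 1),
    **kw,
):
    defaults = dict(
        alignment_length=200,
        mismatches=90,
        gap_opens=1,
        query_start=1,
        query_end=200,
        subject_start=1,
        subject_end=200,
        e_value=1e-30,
        bit_score=150.0,
        subject_reviewed=True,
    )
    defaults.update(kw)
    return SequenceHit(
        query_id=query_id,
        subject_accession=subject_accession,
        percent_identity=percent_identity,
        subject_name=subject_name,
        subject_go_terms=tuple(subject_go_terms),
        subject_integration_date=subject_integration_date,
        **defaults,
    )


def make_struct_hit(
    query_id="1abc",
    subject_pdb_id="9aaa",
    z_score=25.0,
    subject_classification="isomerase",
    subject_name="Triosephosphate isomerase",
    subject_deposition_date=date(2006, 1, 1),
    rmsd_angstrom=2.0,
):
    return StructureHit(
        query_id=query_id,
        subject_pdb_id=subject_pdb_id,
        z_score=z_score,
        rmsd_angstrom=rmsd_angstrom,
        subject_classification=subject_classification,
        subject_name=subject_name,
        subject_deposition_date=subject_deposition_date,
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle (stdlib only; no pdbtriage calls)
# ---------------------------------------------------------------------------

_BLACKLIST = {
    "uncharacterized",
    "putative",
    "unknown",
    "predicted",
    "unnamed",
    "probable",
    "hypothetical",
}
_CUTOFF = {
    "BIOLOGICAL_PROCESS": 40.0,
    "MOLECULAR_FUNCTION": 50.0,
    "CELLULAR_COMPONENT": 60.0,
}


def _words(text):
    return re.findall(r"[a-z0-9]+", text.lower())


def _bad_name(text):
    w = _words(text)
    return not w or any(t in _BLACKLIST for t in w)


def _is_binding(term_name):
    w = _words(term_name)
    return bool(w) and w[-1] == "binding"


def _rows(path, skip_header):
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if skip_header:
        lines = lines[1:]
    return [line.split("\t") for line in lines if line]


def brute_force_labels(entries_path, annotations_path, seq_path, struct_path):
    """Per-entry final label by straight-line application of every rule."""
    ann = {}
    for r in _rows(annotations_path, skip_header=True):
        go = []
        if r[6]:
            for token in r[6].split(";"):
                p = token.split("|")
                go.append((p[1], p[2]))
        ann[r[0]] = {
            "name": r[1],
            "func": r[3],
            "cat": r[4],
            "ecs": [e for e in r[5].split(",") if e],
            "go": go,
        }

    entries = [
        (r[0], [a for a in r[5].split(",") if a])
        for r in _rows(entries_path, skip_header=True)
    ]
    corpus_ids = {pid for pid, _ in entries}

    seq = defaultdict(list)
    for r in _rows(seq_path, skip_header=False):
        seq[r[0].split("_")[0]].append((r[1], float(r[2])))

    struct = defaultdict(list)
    for r in _rows(struct_path, skip_header=True):
        struct[r[0]].append((r[1], float(r[2]), r[4], r[5]))

    def record_status(a):
        if _bad_name(a["name"]):
            return "uncharacterized"
        if a["func"].strip() or a["cat"].strip() or a["ecs"]:
            return "sufficient"
        terms = a["go"]
        if (
            len(terms) >= 3
            and not all(d == "CELLULAR_COMPONENT" for d, _ in terms)
            and not all(_is_binding(n) for _, n in terms)
        ):
            return "sufficient"
        return "insufficient"

    labels = {}
    for pid, accs in entries:
        records = [ann[a] for a in accs if a in ann]
        if records:
            status = record_status(records[0])
            if status != "sufficient" and any(
                record_status(r) == "sufficient" for r in records[1:]
            ):
                status = "sufficient"
            if status == "sufficient":
                labels[pid] = "CHARACTERIZED_IN_SEQUENCE_DB"
                continue
        significant = False
        for sacc, pident in seq.get(pid, []):
            a = ann.get(sacc)
            if a is None or _bad_name(a["name"]):
                continue
            for domain, term_name in a["go"]:
                if pident > _CUTOFF[domain]:
                    if domain == "MOLECULAR_FUNCTION" and _is_binding(term_name):
                        continue
                    significant = True
        if significant:
            labels[pid] = "REANNOTATION_CANDIDATE"
            continue
        best_z = None
        for subj, z, cls, name in struct.get(pid, []):
            if subj in corpus_ids:
                continue
            if cls.strip().lower() == "unknown function":
                continue
            if _bad_name(cls) or _bad_name(name):
                continue
            if best_z is None or z > best_z:
                best_z = z
        labels[pid] = (
            "REANNOTATION_CANDIDATE"
            if best_z is not None and best_z > 20.0
            else "TRUE_UNKNOWN"
        )
    return labels
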