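"""Pipeline configuration: every threshold and vocabulary in one place.

The YAML layout mirrors the stage structure::

    triage:
      min_go_terms: 3
      name_blacklist: [uncharacterized, putative, ...]
      accession_policy: any-sufficient   # or: first
    seq:
      cutoff_bp: 40.0
      cutoff_mf: 50.0
      cutoff_cc: 60.0
    struct:
      z_definite: 20.0
      z_probable_floor: 8.0
    dates:
      fraction_denominator: queries      # or: alignments
      function_vocabulary: ["[a-z0-9]*ase$", ...]
    io:
      strict_hits: false
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .annotation_triage import DEFAULT_BLACKLIST_KEYWORDS, NameBlacklist
from .corpus_io import ValidationError
from .provenance_dating import DEFAULT_FUNCTION_VOCABULARY
from .sequence_evidence import IdentityCutoffs
from .structure_evidence import ZScoreBands

__all__ = ["TriageConfig"]


@dataclass(frozen=True)
class TriageConfig:
    min_go_terms: int = 3
    name_blacklist: tuple[str, ...] = tuple(sorted(DEFAULT_BLACKLIST_KEYWORDS))
    accession_policy: str = "any-sufficient"
    cutoff_bp: float = 40.0
    cutoff_mf: float = 50.0
    cutoff_cc: float = 60.0
    z_definite: float = 20.0
    z_probable_floor: float = 8.0
    fraction_denominator: str = "queries"
    function_vocabulary: tuple[str, ...] = DEFAULT_FUNCTION_VOCABULARY
    strict_hits: bool = False

    @property
    def blacklist(self) -> NameBlacklist:
        return NameBlacklist.from_keywords(self.name_blacklist)

    @property
    def cutoffs(self) -> IdentityCutoffs:
        return IdentityCutoffs(self.cutoff_bp, self.cutoff_mf, self.cutoff_cc)

    @property
    def bands(self) -> ZScoreBands:
        return ZScoreBands(self.z_definite, self.z_probable_floor)

    def replace(self, **kwargs) -> "TriageConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TriageConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path}: top level must be a mapping")
        triage = raw.get("triage", {})
        seq = raw.get("seq", {})
        struct = raw.get("struct", {})
        dates = raw.get("dates", {})
        io = raw.get("io", {})
        defaults = cls()
        return cls(
            min_go_terms=int(triage.get("min_go_terms", defaults.min_go_terms)),
            name_blacklist=tuple(
                triage.get("name_blacklist", defaults.name_blacklist)
            ),
            accession_policy=triage.get(
                "accession_policy", defaults.accession_policy
            ),
            cutoff_bp=float(seq.get("cutoff_bp", defaults.cutoff_bp)),
            cutoff_mf=float(seq.get("cutoff_mf", defaults.cutoff_mf)),
            cutoff_cc=float(seq.get("cutoff_cc", defaults.cutoff_cc)),
            z_definite=float(struct.get("z_definite", defaults.z_definite)),
            z_probable_floor=float(
                struct.get("z_probable_floor", defaults.z_probable_floor)
            ),
            fraction_denominator=dates.get(
                "fraction_denominator", defaults.fraction_denominator
            ),
            function_vocabulary=tuple(
                dates.get("function_vocabulary", defaults.function_vocabulary)
            ),
            strict_hits=bool(io.get("strict_hits", defaults.strict_hits)),
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "triage": {
                "min_go_terms": self.min_go_terms,
                "name_blacklist": list(self.name_blacklist),
                "accession_policy": self.accession_policy,
            },
            "seq": {
                "cutoff_bp": self.cutoff_bp,
                "cutoff_mf": self.cutoff_mf,
                "cutoff_cc": self.cutoff_cc,
            },
            "struct": {
                "z_definite": self.z_definite,
                "z_probable_floor": self.z_probable_floor,
            },
            "dates": {
                "fraction_denominator": self.fraction_denominator,
                "function_vocabulary": list(self.function_vocabulary),
            },
            "io": {"strict_hits": self.strict_hits},
        }
        Path(path).write_text(
            yaml.safe_dump(doc, sort_keys=False), encoding="utf-8"
        )
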