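# Methods

## The triage model

`pdbtriage` treats re-annotation screening as a deterministic decision
funnel over database metadata. The unit of accounting is the 4-character
PDB entry; all evidence is metadata (names, classifications, GO terms,
identities, Z-scores, dates) — no coordinates or residues are read. The
model assumes:

* **Annotation transfer by homology is valid above conservative
  thresholds.** Per-GO-domain identity cutoffs (BP > 40 %, MF > 50 %,
  CC > 60 %) correspond to the identity levels at which homologous pairs
  empirically share the large majority of their GO terms; structural
  homology is trusted only at Z > 20, the "definite homolog" regime of
  structural-alignment statistics.
* **Names carry signal.** A protein name containing any of the seven
  placeholder words (*uncharacterized, putative, unknown, predicted,
  unnamed, probable, hypothetical*) is treated as carrying no functional
  information; matching is case-insensitive and whole-word on alphanumeric
  token boundaries (so "probable" matches, "probability" does not), and an
  empty name is vacuously uninformative.
* **Localization and bare binding are not function.** A GO profile that is
  entirely cellular-component terms, or entirely terms ending in the token
  "binding", does not qualify as characterization. Both exclusions apply at
  any term count: the clause expresses "no informative non-localization,
  non-binding signal", not a rule about exactly three terms.

## Stage rules and their edge decisions

**Stage 1 (annotation sufficiency).** An entry with no resolvable accession
is `NO_MAPPING`. If the record's name is uninformative the entry is an
`UNCHARACTERIZED_EQUIVALENT` regardless of any other content (the blacklist
dominates). Otherwise any one of function text / catalytic activity / EC
number / qualifying GO profile makes it `SUFFICIENT`; else `INSUFFICIENT`.
The GO count requirement defaults to ≥ 3 (`triage.min_go_terms`): the
all-cellular-component exception presumes that exactly-three-term profiles
can qualify, so a strictly-more-than-three reading would be internally
inconsistent. With several mapped accessions, the first resolvable record
decides, except that under the default `any-sufficient` policy a sufficient
secondary record suffices — annotation evidence is disjunctive.

**Stage 2 (sequence homology).** Every hit splits into exactly one of:
*supporting* (informative subject name and at least one supported GO
domain), *name-discarded*, or *sub-threshold*. A domain is supported when
the subject has a GO term in it and identity **strictly** exceeds the
domain cutoff; for MF, at least one non-"binding" MF term must remain after
the binding exclusion. The binding exclusion is applied to GO term names,
not subject protein names, because the rule is tied to the
molecular-function class. A hit may support several domains at once; any
supported domain makes it evidence. E-values are parsed and carried but
never filtered on — identity is the sole significance statistic. Outcomes:
`SIGNIFICANT_ALL_CHARACTERIZED` (supporting hits, no discards),
`SIGNIFICANT_MIXED` (both), `DISCARDED_ONLY`, `SUB_THRESHOLD`, `NO_HITS`.
`SUB_THRESHOLD` completes the partition for queries whose hits survive the
name screen but clear no cutoff.

**Stage 3 (structural homology).** Admissibility removes subjects inside
the query corpus, subjects classified "unknown function", and subjects
whose classification or name fails the same blacklist (an "ambiguous
functional description" is operationalized as blacklist failure; no second
vocabulary exists for it). The class comes from the single best (maximum-Z)
admissible hit — Z is a per-alignment statistic, so voting across
alignments has no statistical meaning; ties break to the lexicographically
smallest subject ID. Band boundaries follow the literal wording: Z = 20 and
Z = 8 are both `PROBABLE`; only Z > 20 is `DEFINITE`, and only `DEFINITE`
removes an entry from the unknown pool.

**Stage 4 (provenance).** The earliest evidence date pools supporting
sequence hits' integration dates with the definite best structural hit's
deposition date. Lag is `floor(days / 365.25)` whole years (implemented as
exact integer arithmetic, `days*4 // 1461`), which reproduces both printed
staleness examples (10 years for an Aug 2000 → Mar 2011 pair, 9 years for
Feb 2002 → Apr 2011). Evidence dated on the deposition day itself counts as
*not* postdating — it could in principle have been cited. The per-channel
postdating fractions use per-query earliest dates by default
(`dates.fraction_denominator: queries`); a per-alignment mode is available
because the published denominators for these fractions are not
reconstructible, and the fractions are reported for orientation only. The
"names a function" test behind the discrepancy flags is: informative per
the blacklist *and* containing a function-vocabulary token (dominated by
the `…ase` suffix pattern, configurable) — the original check was manual,
and the suffix is the clearest mechanizable signal.

## Accounting

Percentages are recomputed from integer counts at report time with
round-half-away-from-zero to 2 decimals, in exact integer arithmetic.
Funnel convention for denominators: annotation and final rows are fractions
of the initial corpus; sequence rows of the sequence-stage queries;
structure rows of the structure-stage queries. The re-annotation-candidate
fraction follows the published convention of dividing the stage-mixed
numerator (sequence-significant + structure-definite) by the initial
corpus. One published inconsistency is resolved deliberately: the
sufficient-annotation category is reported as 34.05 % of 2549, the only
value consistent with the count 868. Sorted ID lists make report files
diff-stable; `report.json` is the canonical serialization (round-trips
all counts and ID lists), `report.tsv` is the human funnel table.

## The synthetic corpus generator

`generate_corpus` emulates the *decision-relevant structure* of the four
real-world sources: which annotation fields are populated, how identities
sit relative to the 40/50/60 cutoffs, how Z-scores sit relative to 8/20,
and how evidence dates sit relative to deposition dates. Per-class record
construction guarantees the prescribed counts exactly, e.g. significant
hits draw identity uniformly in (cutoff + 1, 95] with domain-appropriate GO
terms, sub-threshold hits cycle through six failure modes (below all
cutoffs; exactly 40/50/60; binding-only MF terms above cutoff; no GO), and
exact-boundary records (identity 40/50/60, Z = 8/20) are injected into the
sub-threshold and probable pools to police the strict inequalities.
Inadmissible structural hits (unknown-function subjects, self-dataset
subjects, blacklisted names) are planted where they must be inert.

Generator defaults are the published study conditions: 2549 entries with
annotation categories 868/520/1097/64, sequence classes 299/79/335/647/321,
structure classes 219/381 with a 703 residual, deposition dates in
1999-12-13 … 2007-12-31 (covering the cited examples), and postdating
fractions 43.65 % (sequence channel) / 69.10 % (structure channel),
realized to the nearest achievable count. The published residual 703 is
split 352 unrelated / 351 hitless; no reported number depends on the split.
The default generator seed is 107; the seed moves names, dates and
within-band values but never class counts.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: actual sequence content and alignment
statistics (identities are drawn, not computed; e-values and bit scores are
decorative), correlated evidence (each hit gets a fresh subject record;
real corpora reuse homolog families across queries), GO-graph structure
(terms are flat labels, as in the screening rules themselves), and
biological skew in species or date distributions. Count-fidelity results
certify the *rule implementation*, not the biological claims.

## Numerical and degenerate-input choices

* Strict inequalities at every threshold; boundary behaviour is pinned by
  tests and by injected boundary records.
* Percentages: exact integer round-half-away-from-zero (no binary-float
  ties).
* Ties on Z break lexicographically by subject ID; file row order is
  preserved within query groups.
* Empty inputs: a header-only entries file is an empty corpus (building a
  report from zero verdicts is an error); a query absent from a hit file is
  `NO_HITS`; a hit whose subject metadata is missing is excluded with a
  warning by default (`io.strict_hits: true` turns it into a validation
  error, under which row counts are conserved exactly).
* All readers report every malformed line with its line number and reject
  duplicate primary keys.

## Problem sizes

The published-funnel corpus (2549 entries, ≈ 10 000 annotation records and
hit rows) generates and triages in about a second; the property suite runs
100 random corpora of up to 500 entries plus brute-force cross-checks on
corpora of up to 50 entries, keeping the whole test run well under a
minute.

## Known limitations

* PDB-to-accession mapping multiplicity is handled by policy
  (`first` / `any-sufficient`) rather than by per-chain resolution.
* The discrepancy flags mechanize a manual check; the function vocabulary
  is deliberately small and will miss non-suffix activity names.
* The per-channel date fractions depend on an unrecoverable published
  denominator convention; both modes are provided, neither is asserted
  against published values.
* GO terms are flat labels; no ancestor closure is attempted, so a profile
  of three near-synonymous terms counts as three terms.
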