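"""Stage-1 sufficiency rules: blacklist, GO profiles, corpus partition."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdbtriage import (
    AnnotationStatus,
    GoDomain,
    NameBlacklist,
    classify_annotation_status,
    go_profile_sufficient,
    is_uninformative_name,
    partition_corpus,
)

from helpers import make_annotation, make_entry, make_go


@pytest.mark.parametrize(
    "name,expected",
    [
        ("Hypothetical protein ybdK", True),
        ("Putative uncharacterized protein", True),
        ("Walker type ATP-ase", False),
        ("", True),
        ("   ", True),
        ("UNKNOWN protein", True),  # case-insensitive
        ("probability density regulator", False),  # whole words only
        ("un-predicted element", True),  # token boundary at hyphen
        ("Thymidine kinase", False),
    ],
)
def test_uninformative_name_detection(name, expected):
    assert is_uninformative_name(name) is expected


class TestGoProfile:
    def test_three_mixed_domain_terms_qualify(self):
        terms = [
            make_go(GoDomain.BIOLOGICAL_PROCESS, "phosphorylation"),
            make_go(GoDomain.MOLECULAR_FUNCTION, "kinase activity"),
            make_go(GoDomain.CELLULAR_COMPONENT, "cytoplasm"),
        ]
        assert go_profile_sufficient(terms)

    def test_all_cellular_component_insufficient(self):
        terms = [make_go(GoDomain.CELLULAR_COMPONENT, n) for n in ("cytoplasm", "nucleus", "ribosome")]
        assert not go_profile_sufficient(terms)

    def test_all_binding_terms_insufficient(self):
        terms = [
            make_go(GoDomain.MOLECULAR_FUNCTION, n)
            for n in ("ATP binding", "DNA binding", "metal ion binding")
        ]
        assert not go_profile_sufficient(terms)

    def test_below_minimum_count_insufficient(self):
        terms = [make_go(GoDomain.MOLECULAR_FUNCTION, "kinase activity")] * 2
        assert not go_profile_sufficient(terms)

    def test_exclusions_generalize_beyond_three_terms(self):
        five_cc = [make_go(GoDomain.CELLULAR_COMPONENT, "cytoplasm") for _ in range(5)]
        assert not go_profile_sufficient(five_cc)
        four_binding_one_not = [
            make_go(GoDomain.MOLECULAR_FUNCTION, "ATP binding") for _ in range(4)
        ] + [make_go(GoDomain.MOLECULAR_FUNCTION, "kinase activity")]
        assert go_profile_sufficient(four_binding_one_not)

    def test_binding_match_is_suffix_token_not_substring(self):
        # "binding-site formation" does not END in "binding"
        terms = [
            make_go(GoDomain.MOLECULAR_FUNCTION, "binding-site formation")
            for _ in range(3)
        ]
        assert go_profile_sufficient(terms)


class TestClassification:
    def test_no_accessions_gives_no_mapping(self):
        assert (
            classify_annotation_status(make_entry(accessions=()), {})
            is AnnotationStatus.NO_MAPPING
        )

    def test_unresolvable_accession_gives_no_mapping(self):
        entry = make_entry(accessions=("Q99999",))
        assert classify_annotation_status(entry, {}) is AnnotationStatus.NO_MAPPING

    def test_uninformative_record_name_dominates_rich_go(self):
        record = make_annotation(
            protein_name="Uncharacterized protein yabc",
            go_terms=tuple(
                make_go(d, n)
                for d, n in [
                    (GoDomain.BIOLOGICAL_PROCESS, "phosphorylation"),
                    (GoDomain.MOLECULAR_FUNCTION, "kinase activity"),
                    (GoDomain.CELLULAR_COMPONENT, "cytoplasm"),
                    (GoDomain.BIOLOGICAL_PROCESS, "DNA repair"),
                    (GoDomain.MOLECULAR_FUNCTION, "hydrolase activity"),
                ]
            ),
        )
        entry = make_entry(accessions=(record.accession,))
        status = classify_annotation_status(entry, {record.accession: record})
        assert status is AnnotationStatus.UNCHARACTERIZED_EQUIVALENT

    @pytest.mark.parametrize(
        "kw",
        [
            dict(function_text="Catalyzes phosphoryl transfer."),
            dict(catalytic_activity="ATP + thymidine = ADP + dTMP"),
            dict(ec_numbers=("2.7.1.21",)),
            dict(
                go_terms=(
                    make_go(GoDomain.BIOLOGICAL_PROCESS, "phosphorylation"),
                    make_go(GoDomain.MOLECULAR_FUNCTION, "kinase activity"),
                    make_go(GoDomain.CELLULAR_COMPONENT, "cytoplasm"),
                )
            ),
        ],
    )
    def test_each_sufficiency_route_qualifies(self, kw):
        record = make_annotation(**kw)
        entry = make_entry(accessions=(record.accession,))
        status = classify_annotation_status(entry, {record.accession: record})
        assert status is AnnotationStatus.SUFFICIENT

    def test_informative_name_without_evidence_is_insufficient(self):
        record = make_annotation(
            go_terms=(
                make_go(GoDomain.MOLECULAR_FUNCTION, "kinase activity"),
                make_go(GoDomain.BIOLOGICAL_PROCESS, "phosphorylation"),
            )
        )
        entry = make_entry(accessions=(record.accession,))
        status = classify_annotation_status(entry, {record.accession: record})
        assert status is AnnotationStatus.INSUFFICIENT

    def test_any_sufficient_policy_rescues_secondary_record(self):
        weak = make_annotation(accession="Q1")
        strong = make_annotation(accession="Q2", function_text="A ligase.")
        entry = make_entry(accessions=("Q1", "Q2"))
        mapping = {"Q1": weak, "Q2": strong}
        assert (
            classify_annotation_status(entry, mapping, accession_policy="any-sufficient")
            is AnnotationStatus.SUFFICIENT
        )
        assert (
            classify_annotation_status(entry, mapping, accession_policy="first")
            is AnnotationStatus.INSUFFICIENT
        )


# -- properties --------------------------------------------------------------

_domains = st.sampled_from(list(GoDomain))
_term_names = st.sampled_from(
    ["kinase activity", "ATP binding", "cytoplasm", "phosphorylation", "DNA binding"]
)
_profiles = st.lists(st.tuples(_domains, _term_names), max_size=6)


@given(_profiles, st.tuples(_domains, _term_names))
def test_adding_a_go_term_never_revokes_sufficiency(profile, extra):
    terms = [make_go(d, n) for d, n in profile]
    if go_profile_sufficient(terms):
        assert go_profile_sufficient(terms + [make_go(*extra)])


@given(
    st.lists(
        st.tuples(st.booleans(), st.booleans(), _profiles), min_size=1, max_size=20
    )
)
def test_partition_is_disjoint_exhaustive_and_order_preserving(rows):
    entries, mapping = [], {}
    for i, (mapped, informative, profile) in enumerate(rows):
        pdb_id = f"1{i:03d}"
        acc = f"Q{i:05d}"
        entries.append(make_entry(pdb_id=pdb_id, accessions=(acc,) if mapped else ()))
        if mapped:
            mapping[acc] = make_annotation(
                accession=acc,
                protein_name="Thymidine kinase" if informative else "Putative protein",
                go_terms=tuple(make_go(d, n) for d, n in profile),
            )
    buckets = partition_corpus(entries, mapping)
    ids = [pid for bucket in buckets.values() for pid in bucket]
    assert sorted(ids) == sorted(e.pdb_id for e in entries)
    assert len(set(ids)) == len(ids)
    order = {e.pdb_id: i for i, e in enumerate(entries)}
    for bucket in buckets.values():
        assert bucket == sorted(bucket, key=order.__getitem__)


@given(_profiles)
def test_blacklisted_name_never_reaches_sufficient(profile):
    record = make_annotation(
        protein_name="Putative uncharacterized protein",
        function_text="Catalyzes something.",
        go_terms=tuple(make_go(d, n) for d, n in profile),
    )
    entry = make_entry(accessions=(record.accession,))
    status = classify_annotation_status(entry, {record.accession: record})
    assert status is AnnotationStatus.UNCHARACTERIZED_EQUIVALENT
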