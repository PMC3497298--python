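"""Generator guarantees: spec fidelity, determinism, perturbation invariance."""

import random

import pytest

from pdbtriage import (
    AnnotationStatus,
    CorpusSpec,
    SequenceOutcome,
    StructureOutcome,
    generate_corpus,
    perturb_corpus,
    printed_funnel_spec,
    random_corpus_spec,
    run_pipeline,
)
from pdbtriage.corpus_io import ValidationError


def _run(paths, **kw):
    return run_pipeline(
        paths["entries"],
        paths["annotations"],
        paths["sequence_hits"],
        paths["structure_hits"],
        **kw,
    )


class TestSpecs:
    def test_printed_funnel_totals(self):
        spec = printed_funnel_spec()
        assert spec.n_entries == 2549
        assert sum(spec.annotation_counts.values()) == 2549
        assert spec.forwarded_to_sequence == 1681
        assert sum(spec.sequence_counts.values()) == 1681
        assert spec.forwarded_to_structure == 1303
        assert sum(spec.structure_counts.values()) == 1303

    def test_inconsistent_sums_rejected(self):
        spec = printed_funnel_spec()
        bad = dict(spec.annotation_counts)
        bad[AnnotationStatus.NO_MAPPING] += 1
        with pytest.raises(ValidationError, match="sum"):
            CorpusSpec(
                n_entries=spec.n_entries,
                annotation_counts=bad,
                sequence_counts=spec.sequence_counts,
                structure_counts=spec.structure_counts,
            )

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = random_corpus_spec(random.Random(3), n_entries=40)
        spec.to_yaml(tmp_path / "spec.yaml")
        assert CorpusSpec.from_yaml(tmp_path / "spec.yaml") == spec


class TestDeterminism:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        spec = random_corpus_spec(random.Random(11), n_entries=50)
        p1 = generate_corpus(spec, tmp_path / "a")
        p2 = generate_corpus(spec, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_different_seed_changes_content_not_counts(self, tmp_path):
        spec = random_corpus_spec(random.Random(11), n_entries=50)
        other = spec.replace(seed=spec.seed + 1)
        p1 = generate_corpus(spec, tmp_path / "a")
        p2 = generate_corpus(other, tmp_path / "b")
        assert p1["annotations"].read_bytes() != p2["annotations"].read_bytes()
        r1, r2 = _run(p1).report, _run(p2).report
        assert r1.annotation_counts == r2.annotation_counts
        assert r1.sequence_counts == r2.sequence_counts
        assert r1.structure_counts == r2.structure_counts


class TestCountFidelity:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pipeline_counts_equal_spec_counts(self, seed, tmp_path):
        spec = random_corpus_spec(random.Random(seed))
        paths = generate_corpus(spec, tmp_path)
        report = _run(paths).report
        assert report.annotation_counts == {
            k.value: v for k, v in spec.annotation_counts.items()
        }
        assert report.sequence_counts == {
            k.value: v for k, v in spec.sequence_counts.items()
        }
        assert report.structure_counts == {
            k.value: v for k, v in spec.structure_counts.items()
        }

    def test_boundary_records_stay_outside_significant_classes(self, tmp_path):
        # a corpus made only of sub-threshold and probable queries exercises
        # every injected exact-boundary record (40/50/60 identity, Z = 8/20)
        spec = CorpusSpec(
            n_entries=40,
            annotation_counts={
                AnnotationStatus.SUFFICIENT: 0,
                AnnotationStatus.INSUFFICIENT: 40,
                AnnotationStatus.UNCHARACTERIZED_EQUIVALENT: 0,
                AnnotationStatus.NO_MAPPING: 0,
            },
            sequence_counts={
                SequenceOutcome.SIGNIFICANT_ALL_CHARACTERIZED: 0,
                SequenceOutcome.SIGNIFICANT_MIXED: 0,
                SequenceOutcome.DISCARDED_ONLY: 0,
                SequenceOutcome.SUB_THRESHOLD: 40,
                SequenceOutcome.NO_HITS: 0,
            },
            structure_counts={
                StructureOutcome.DEFINITE: 0,
                StructureOutcome.PROBABLE: 40,
                StructureOutcome.UNRELATED: 0,
                StructureOutcome.NO_HITS: 0,
            },
            seed=23,
        )
        report = _run(generate_corpus(spec, tmp_path)).report
        assert report.sequence_significant == 0
        assert report.structure_counts["DEFINITE"] == 0
        assert report.structure_counts["PROBABLE"] == 40


class TestPerturbations:
    def test_row_shuffle_preserves_the_whole_report(self, small_corpus, tmp_path):
        shuffled = perturb_corpus(small_corpus.paths, "shuffle_rows", 9, tmp_path / "s")
        base, pert = _run(small_corpus.paths).report, _run(shuffled).report
        assert pert == base  # sorted ID lists make full equality hold

    def test_double_shuffle_same_seed_identical_files(self, small_corpus, tmp_path):
        s1 = perturb_corpus(small_corpus.paths, "shuffle_rows", 9, tmp_path / "s1")
        s2 = perturb_corpus(small_corpus.paths, "shuffle_rows", 9, tmp_path / "s2")
        for key in s1:
            assert s1[key].read_bytes() == s2[key].read_bytes()

    def test_relabel_preserves_counts_and_maps_ids(self, small_corpus, tmp_path):
        relabeled = perturb_corpus(
            small_corpus.paths, "relabel_ids", 9, tmp_path / "r"
        )
        base, pert = _run(small_corpus.paths).report, _run(relabeled).report
        assert pert.annotation_counts == base.annotation_counts
        assert pert.sequence_counts == base.sequence_counts
        assert pert.structure_counts == base.structure_counts
        assert len(pert.true_unknown_ids) == len(base.true_unknown_ids)
        assert set(pert.true_unknown_ids).isdisjoint(base.true_unknown_ids) or not base.true_unknown_ids

    def test_non_bijective_relabel_map_rejected(self, small_corpus, tmp_path):
        with pytest.raises(ValidationError, match="bijective"):
            perturb_corpus(
                small_corpus.paths,
                "relabel_ids",
                9,
                tmp_path / "bad",
                relabel_map={"1aaa": "8aaa", "1aab": "8aaa"},
            )

    def test_unknown_perturbation_rejected(self, small_corpus, tmp_path):
        with pytest.raises(ValidationError, match="unknown perturbation"):
            perturb_corpus(small_corpus.paths, "reverse", 9, tmp_path / "x")
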