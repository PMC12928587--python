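"""Annotation handling: DSSP reduction, CATH labels, partitions, filtering, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plmsubnet import (
    AnnotationError,
    CathLevel,
    ConfigError,
    DomainRecord,
    SuppressionSpec,
    build_partition,
    filter_by_length,
    reduce_dssp,
    sanitize_records,
    split_dataset,
    truncate_cath,
)


class TestReduceDssp:
    @pytest.mark.parametrize(
        "eight,three",
        [
            ("HGIEBTS-", "HHHEELLL"),
            ("", ""),
            ("TTEEHH", "LLEEHH"),
        ],
    )
    def test_mapping(self, eight, three):
        assert reduce_dssp(eight) == three

    def test_unknown_character_names_position(self):
        with pytest.raises(AnnotationError, match="'X' at position 2"):
            reduce_dssp("HGX")

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet="HGIEBTS-", max_size=64))
    def test_length_preserved_and_three_state(self, s):
        out = reduce_dssp(s)
        assert len(out) == len(s)
        assert set(out) <= set("HEL")

    def test_helix_strand_inputs_are_fixed_points(self):
        # H and E appear in both alphabets and map to themselves
        assert reduce_dssp("HHEE") == "HHEE"


class TestTruncateCath:
    @pytest.mark.parametrize(
        "level,expected",
        [
            (CathLevel.CLASS, "3"),
            (CathLevel.ARCHITECTURE, "3.40"),
            (CathLevel.TOPOLOGY, "3.40.50"),
            (CathLevel.HOMOLOGOUS_SUPERFAMILY, "3.40.50.720"),
        ],
    )
    def test_prefix(self, level, expected):
        assert truncate_cath("3.40.50.720", level) == expected

    def test_too_few_fields(self):
        with pytest.raises(AnnotationError):
            truncate_cath("3.40", CathLevel.HOMOLOGOUS_SUPERFAMILY)

    def test_partial_label_accepted_at_available_level(self):
        assert truncate_cath("3.40", CathLevel.ARCHITECTURE) == "3.40"


class TestBuildPartition:
    def test_sequence_level_by_class(self):
        recs = [
            DomainRecord("a", "AAAA", cath_label="1.10"),
            DomainRecord("b", "CCCC", cath_label="2.40"),
            DomainRecord("c", "DDDD", cath_label="1.20"),
        ]
        spec = SuppressionSpec("sequence", "1", CathLevel.CLASS)
        part = build_partition(recs, spec)
        assert part.suppressed_ids == {"a", "c"}
        assert part.maintained_ids == {"b"}

    def test_residue_level_positions(self):
        recs = [DomainRecord("r", "ACDEFG", ss3="HHLLEE")]
        part = build_partition(recs, SuppressionSpec("residue", "E"))
        assert part.suppressed_positions("r").tolist() == [4, 5]
        assert part.maintained_positions("r").tolist() == [0, 1, 2, 3]

    def test_empty_suppression_side_is_error(self):
        recs = [DomainRecord("a", "AAAA", cath_label="1.10")]
        with pytest.raises(AnnotationError, match="no record matches"):
            build_partition(recs, SuppressionSpec("sequence", "9", CathLevel.CLASS))

    def test_missing_annotation_lists_ids(self):
        recs = [
            DomainRecord("ok", "AAAA", cath_label="1.1"),
            DomainRecord("bad", "CCCC"),
        ]
        with pytest.raises(AnnotationError, match="bad"):
            build_partition(recs, SuppressionSpec("sequence", "1", CathLevel.CLASS))

    @settings(max_examples=40, derandomize=True)
    @given(
        labels=st.lists(st.sampled_from(["1.1", "2.1", "3.2"]), min_size=1, max_size=20),
        target=st.sampled_from(["1", "2", "3"]),
    )
    def test_disjoint_and_exhaustive(self, labels, target):
        recs = [
            DomainRecord(f"r{i}", "ACDE", cath_label=lab) for i, lab in enumerate(labels)
        ]
        spec = SuppressionSpec("sequence", target, CathLevel.CLASS)
        try:
            part = build_partition(recs, spec)
        except AnnotationError:
            assert all(not lab.startswith(target) for lab in labels)
            return
        assert part.suppressed_ids | part.maintained_ids == {r.id for r in recs}
        assert not (part.suppressed_ids & part.maintained_ids)

    @settings(max_examples=40, derandomize=True)
    @given(ss3=st.text(alphabet="HEL", min_size=1, max_size=40), target=st.sampled_from("HEL"))
    def test_residue_sides_partition_every_position(self, ss3, target):
        recs = [DomainRecord("r", "A" * len(ss3), ss3=ss3)]
        try:
            part = build_partition(recs, SuppressionSpec("residue", target))
        except AnnotationError:
            assert target not in ss3
            return
        jstar = set(part.suppressed_positions("r").tolist())
        jprime = set(part.maintained_positions("r").tolist())
        assert jstar | jprime == set(range(len(ss3)))
        assert not (jstar & jprime)


class TestFilterAndSplit:
    def test_length_bounds_inclusive(self):
        recs = [DomainRecord(str(n), "A" * n) for n in (63, 64, 500, 1024, 1025)]
        kept = filter_by_length(recs)
        assert [len(r) for r in kept] == [64, 500, 1024]

    def test_bad_bounds(self):
        with pytest.raises(ConfigError):
            filter_by_length([], min_len=10, max_len=5)

    def test_identity_bounds(self):
        recs = [DomainRecord("a", "AA")]
        assert filter_by_length(recs, 0, 10**9) == recs
        assert filter_by_length([], 0, 10) == []

    def test_split_sizes_ten_records(self):
        recs = [DomainRecord(f"r{i}", "A" * 64) for i in range(10)]
        split = split_dataset(recs, seed=5)
        assert split.counts() == {"train": 7, "validation": 2, "test": 1}

    def test_split_exact_fraction_at_1000(self):
        recs = [DomainRecord(f"r{i}", "A" * 64) for i in range(1000)]
        split = split_dataset(recs, seed=1)
        assert split.counts()["train"] == 700

    def test_split_deterministic(self):
        recs = [DomainRecord(f"r{i}", "A" * 64) for i in range(37)]
        a = split_dataset(recs, seed=9)
        b = split_dataset(recs, seed=9)
        assert a.assignment == b.assignment

    def test_floor_allocation_with_remainder_to_train(self):
        for n in range(1, 201):
            recs = [DomainRecord(f"r{i}", "A") for i in range(n)]
            c = split_dataset(recs, seed=0).counts()
            assert c["validation"] == int(n * 0.2)
            assert c["test"] == int(n * 0.1)
            assert c["train"] == n - c["validation"] - c["test"]

    def test_invalid_fractions(self):
        recs = [DomainRecord("a", "A")]
        with pytest.raises(ConfigError):
            split_dataset(recs, fractions=(0.7, 0.2, 0.2))
        with pytest.raises(ConfigError):
            split_dataset(recs, fractions=(1.0, -0.1, 0.1))

    def test_stratified_preserves_class_balance(self):
        recs = [
            DomainRecord(f"x{i}", "A" * 64, cath_label="1.1") for i in range(50)
        ] + [DomainRecord(f"y{i}", "A" * 64, cath_label="2.1") for i in range(50)]
        split = split_dataset(recs, seed=3, stratify=True)
        val_x = sum(1 for i, p in split.assignment.items() if p == "validation" and i.startswith("x"))
        val_y = sum(1 for i, p in split.assignment.items() if p == "validation" and i.startswith("y"))
        assert val_x == val_y == 10


class TestSanitize:
    def test_noncanonical_replaced_with_unknown(self):
        recs = sanitize_records([DomainRecord("a", "ACXBZ")])
        assert recs[0].sequence == "ACXXX"

    def test_reject_policy(self):
        with pytest.raises(AnnotationError):
            sanitize_records([DomainRecord("a", "ACXU")], policy="reject")

    def test_truly_invalid_character(self):
        with pytest.raises(AnnotationError):
            sanitize_records([DomainRecord("a", "AC1")])

    def test_ss3_length_mismatch_rejected(self):
        with pytest.raises(AnnotationError):
            DomainRecord("a", "ACDE", ss3="HH")
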