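import itertools

import pytest

from mlstpg.mlst_core import (
    DEFAULT_LOCI,
    AlleleDatabase,
    IsolateRecord,
    LocusDef,
    ProfileTableError,
    STProfile,
    SequenceValidationError,
    assign_sts,
    build_allele_database,
    call_allele,
    concatenate,
    read_profiles,
    type_isolates,
    validate_sequence,
    write_profiles,
)

TOY9 = LocusDef("toy", 9, 0, 1)


def test_default_panel_lengths_sum_to_concatenated_fragment():
    assert sum(l.expected_length for l in DEFAULT_LOCI) == 4261
    assert [l.order_index for l in DEFAULT_LOCI] == list(range(1, 9))


@pytest.mark.parametrize(
    "seq,expected_fragments",
    [
        ("ATGGCAGGG", []),
        ("ATGGCAGG", ["wrong length"]),
        ("ATGNCAGGG", ["non-ACGT"]),
        ("ATGTAAGGG", ["internal stop codon TAA"]),  # codon 2 is TAA
        ("ATGTGAGGG", ["internal stop codon TGA"]),
    ],
)
def test_validate_sequence_reports_each_rule(seq, expected_fragments):
    report = validate_sequence(TOY9, seq)
    assert len(report) == len(expected_fragments)
    for fragment, violation in zip(expected_fragments, report):
        assert fragment in violation


def test_validate_respects_frame_offset():
    # TAA spans positions 2-4; only a stop in frame 1
    seq = "GTAAGGGCA"
    assert validate_sequence(LocusDef("f0", 9, 0, 1), seq) == []
    report = validate_sequence(LocusDef("f1", 9, 1, 1), seq)
    assert report and "stop codon" in report[0]


class TestAlleleDatabase:
    def test_first_occurrence_numbering_matches_dedup_oracle(self, rng):
        pool = ["ATGGCAGGG", "ATGGCCGGG", "ATGGCGGGG", "ATGGCTGGG"]
        stream = [pool[i] for i in rng.integers(0, 4, size=10)]
        db = build_allele_database({"toy": stream}, [TOY9])
        oracle = list(dict.fromkeys(stream))  # order-preserving dedup
        assert [a.sequence for a in db.alleles("toy")] == oracle
        assert [a.allele_id for a in db.alleles("toy")] == list(
            range(1, len(oracle) + 1)
        )

    def test_duplicates_collapse_and_rebuild_is_idempotent(self):
        stream = ["ATGGCAGGG", "ATGGCAGGG", "ATGGCCGGG"]
        db1 = build_allele_database({"toy": stream}, [TOY9])
        db2 = build_allele_database({"toy": stream}, [TOY9])
        assert db1.n_alleles("toy") == 2
        assert [a.sequence for a in db1.alleles("toy")] == [
            a.sequence for a in db2.alleles("toy")
        ]

    def test_invalid_sequence_names_isolate_and_locus(self):
        with pytest.raises(SequenceValidationError) as err:
            build_allele_database({"toy": [("iso7", "ATGTAAGGG")]}, [TOY9])
        assert "iso7" in str(err.value) and "toy" in str(err.value)

    def test_permuting_input_permutes_ids_but_not_classes(self, rng):
        pool = ["ATGGCAGGG", "ATGGCCGGG", "ATGGCGGGG"]
        stream = [pool[i] for i in rng.integers(0, 3, size=12)]
        db = build_allele_database({"toy": stream}, [TOY9])
        perm = rng.permutation(len(stream))
        db_p = build_allele_database({"toy": [stream[i] for i in perm]}, [TOY9])
        # same set of allele classes, possibly renumbered
        assert {a.sequence for a in db.alleles("toy")} == {
            a.sequence for a in db_p.alleles("toy")
        }
        assert db.n_alleles("toy") == db_p.n_alleles("toy")


def test_call_allele_query_and_extend_modes():
    db = build_allele_database({"toy": ["ATGGCAGGG"]}, [TOY9])
    assert call_allele(db, "toy", "ATGGCAGGG") == 1
    assert call_allele(db, "toy", "ATGGCCGGG") is None  # novel marker
    assert call_allele(db, "toy", "ATGGCCGGG", extend=True) == 2
    assert db.n_alleles("toy") == 2
    with pytest.raises(KeyError):
        call_allele(db, "nope", "ATGGCAGGG")


class TestAssignSts:
    def test_identical_vectors_share_an_st(self):
        st_ids, registry = assign_sts([[1] * 8, [1] * 8, [1, 1, 1, 1, 1, 1, 1, 2]])
        assert st_ids == [1, 1, 2]
        assert len(registry) == 2
        assert registry[0].alleles == (1,) * 8

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            assign_sts([[1, 2, 3]])

    def test_permutation_covariance(self, rng):
        vecs = [list(rng.integers(1, 3, size=8)) for _ in range(20)]
        st_ids, _ = assign_sts(vecs)
        perm = list(rng.permutation(20))
        st_p, _ = assign_sts([vecs[i] for i in perm])

        def classes(ids):
            groups: dict[int, set[int]] = {}
            for pos, st in enumerate(ids):
                groups.setdefault(st, set()).add(pos)
            return {frozenset(g) for g in groups.values()}

        # map permuted positions back to original positions: the partition
        # into ST classes must be identical (never merged or split)
        permuted_in_original = {
            frozenset(perm[p] for p in g) for g in classes(st_p)
        }
        assert classes(st_ids) == permuted_in_original

    def test_distinct_count_bounded_by_inputs(self, rng):
        vecs = [list(rng.integers(1, 3, size=8)) for _ in range(30)]
        st_ids, registry = assign_sts(vecs)
        assert len(registry) <= len(vecs)
        assert len(registry) == len({tuple(v) for v in vecs})


class TestConcatenate:
    def test_default_panel_record_concatenates_to_4261(self, clonal_population):
        records, _ = clonal_population
        assert len(concatenate(records[0])) == 4261

    def test_toy_scheme_length_is_sum_rule(self):
        loci = [LocusDef(f"l{i}", 3, 0, i) for i in range(1, 9)]
        rec = IsolateRecord("x", {f"l{i}": "ATG" for i in range(1, 9)})
        assert len(concatenate(rec, loci=loci)) == 24

    def test_missing_locus_is_named(self, clonal_population):
        records, _ = clonal_population
        rec = IsolateRecord("x", dict(records[0].sequences))
        del rec.sequences["rpoB"]
        with pytest.raises(KeyError, match="rpoB"):
            concatenate(rec)

def test_allele_vector_concatenation_matches_record(small_population):
    records, _ = small_population
    from conftest import SMALL_PANEL

    typing = type_isolates(records, SMALL_PANEL)
    rec = records[0]
    st = typing.st_of[rec.isolate_id]
    profile = typing.registry[st - 1]
    assert concatenate(profile, db=typing.db) == concatenate(
        rec, loci=SMALL_PANEL
    )


class TestProfileTable:
    PROFILES = [
        STProfile(1, (1, 1, 1, 1, 1, 1, 1, 1)),
        STProfile(2, (1, 2, 1, 1, 1, 1, 1, 1)),
        STProfile(3, (2, 2, 2, 2, 2, 2, 2, 2)),
    ]

    def test_roundtrip_and_byte_stability(self, tmp_path):
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        write_profiles(self.PROFILES, p1)
        back = read_profiles(p1)
        assert back == self.PROFILES
        write_profiles(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_locus_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("ST\tclpX\n1\t1\n")
        with pytest.raises(ProfileTableError, match="dnaA"):
            read_profiles(path)

    def test_duplicate_st_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        write_profiles(self.PROFILES, path)
        lines = path.read_text().splitlines()
        lines.append(lines[1])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ProfileTableError, match="duplicated ST"):
            read_profiles(path)

    def test_non_integer_cell_rejected(self, tmp_path):
        path = tmp_path / "nonint.tsv"
        names = "\t".join(l.name for l in DEFAULT_LOCI)
        path.write_text(f"ST\t{names}\n1\t1\t1\t1\t1\tx\t1\t1\t1\n")
        with pytest.raises(ProfileTableError, match="non-integer"):
            read_profiles(path)


def test_type_isolates_counts_and_novel_mode(small_population):
    records, truth = small_population
    from conftest import SMALL_PANEL

    typing = type_isolates(records, SMALL_PANEL)
    assert typing.n_sts <= len(records)
    assert sum(typing.isolate_counts().values()) == len(records)
    # query mode against a database missing later alleles must name the isolate
    db = AlleleDatabase(SMALL_PANEL)
    for l in SMALL_PANEL:
        db.add(l.name, records[0].sequences[l.name])
    distinct = {
        tuple(r.sequences[l.name] for l in SMALL_PANEL) for r in records
    }
    if len(distinct) > 1:
        with pytest.raises(KeyError, match="novel allele"):
            type_isolates(records, SMALL_PANEL, db=db, extend=False)
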