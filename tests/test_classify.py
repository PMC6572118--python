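import pytest

from ame_smallrna import classify as cl
from ame_smallrna.io_formats import SeqRecord, load_catalog_fixture


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def brute_distance(a, b, max_shift=2):
    """Independent shifted-Hamming: enumerate all alignments explicitly."""
    best = None
    for shift in range(-max_shift, max_shift + 1):
        mm = 0
        matched_a, matched_b = 0, 0
        for i in range(len(b)):
            j = i + shift
            if 0 <= j < len(a):
                matched_a += 1
                matched_b += 1
                if a[j] != b[i]:
                    mm += 1
        if matched_b == 0:
            continue
        mm += (len(a) - matched_a) + (len(b) - matched_b)
        best = mm if best is None else min(best, mm)
    return best


class TestMatchReference:
    def test_identical_is_zero_mismatches(self):
        ref = [SeqRecord("gma-miR156u", "TGACAGAAGAGAGTGAGCAC")]
        assert cl.match_reference("TGACAGAAGAGAGTGAGCAC", ref) == ("gma-miR156u", 0)

    def test_four_mismatches_is_no_hit(self):
        ref = [SeqRecord("x", "TGACAGAAGAGAGTGAGCAC")]
        #       mutate 4 positions
        assert cl.match_reference("AGACAGTAGAGAGTGACCAA", ref) is None

    def test_matches_exhaustive_oracle(self, rng):
        refs = [SeqRecord(f"ref{i:02d}", _random_seq(rng, int(rng.integers(18, 23))))
                for i in range(50)]
        for _ in range(30):
            q = _random_seq(rng, 21)
            dists = {r.id: brute_distance(q, r.seq) for r in refs}
            best_d = min(dists.values())
            hit = cl.match_reference(q, refs)
            if best_d > 3:
                assert hit is None
            else:
                expect_id = min(i for i, d in dists.items() if d == best_d)
                assert hit == (expect_id, best_d)

    def test_distance_symmetry_and_identity(self, rng):
        for _ in range(20):
            a = _random_seq(rng, int(rng.integers(18, 23)))
            b = _random_seq(rng, int(rng.integers(18, 23)))
            assert cl.shifted_hamming(a, b) == cl.shifted_hamming(b, a)
            assert cl.shifted_hamming(a, a) == 0
            if a != b:
                assert cl.shifted_hamming(a, b) > 0

    def test_empty_reference_is_error(self):
        with pytest.raises(ValueError):
            cl.match_reference("ACGT" * 5, [])


class TestClassify:
    REF = [SeqRecord("gma-miR9000a", "TGACAGAAGAGAGTGAGCAC")]

    def test_precursor_with_two_mismatches_is_conserved(self):
        mclass, hom, mm = cl.classify_mirna("TCACAGAAGAGAGTGACCAC", True, self.REF)
        assert mclass is cl.MirnaClass.CONSERVED_PRECURSOR and mm == 2

    def test_precursor_without_homolog_is_non_conserved(self):
        mclass, hom, mm = cl.classify_mirna("GGGGCCCCAAAATTTTGGCC", True, self.REF)
        assert mclass is cl.MirnaClass.NON_CONSERVED and hom == ""

    def test_no_precursor_needs_perfect_match(self):
        mclass, _, mm = cl.classify_mirna("TGACAGAAGAGAGTGAGCAC", False, self.REF)
        assert mclass is cl.MirnaClass.CONSERVED_NO_PRECURSOR and mm == 0
        mclass, _, _ = cl.classify_mirna("TAACAGAAGAGAGTGAGCAC", False, self.REF)
        assert mclass is None  # 1 mismatch, dropped


class TestAssignFamily:
    @pytest.mark.parametrize(
        "homolog,family",
        [("gma-miR167g", "MIR167_1"), ("ath-miR319a", "MIR159"),
         ("gma-miR156u", "MIR156"), (None, "novel"), ("", "novel"),
         ("xyz-miR9999z", "MIR9999")],  # regex fallback for unregistered ids
    )
    def test_family_resolution(self, homolog, family):
        assert cl.assign_family(homolog) == family


class TestNaming:
    def _rec(self, seq, reads, mclass, family="MIR9000", hom="syn-miR9000a"):
        return cl.MirnaRecord(
            name="", mature_seq=seq, mirna_class=mclass, family=family,
            homolog_id=hom if mclass is not cl.MirnaClass.NON_CONSERVED else "",
            reads=reads,
            precursor_ids=["p"] if mclass is not cl.MirnaClass.CONSERVED_NO_PRECURSOR else [],
        )

    def test_novel_named_by_descending_reads(self):
        a = self._rec("ACGTACGTACGTACGTACGTA", 2043, cl.MirnaClass.NON_CONSERVED, "novel")
        b = self._rec("TGCATGCATGCATGCATGCAT", 8, cl.MirnaClass.NON_CONSERVED, "novel")
        named = cl.name_records([b, a])
        assert next(r for r in named if r.name == "ame-miRN-1").reads == 2043

    def test_single_family_member_gets_suffix_1(self):
        r = self._rec("ACGTACGTACGTACGTACGTA", 10, cl.MirnaClass.CONSERVED_PRECURSOR)
        assert cl.name_records([r])[0].name == "ame-miR9000-1"

    def test_naming_stable_under_permutation(self, rng):
        recs = [self._rec(_random_seq(rng, 21), int(rng.integers(1, 5000)),
                          cl.MirnaClass.NON_CONSERVED, "novel") for _ in range(10)]
        names1 = [(r.name, r.mature_seq) for r in cl.name_records(list(recs))]
        perm = [recs[i] for i in rng.permutation(len(recs))]
        for r in perm:
            r.name = ""
        names2 = [(r.name, r.mature_seq) for r in cl.name_records(perm)]
        assert sorted(names1) == sorted(names2)

    def test_hyphen_insensitive_novel_names(self):
        assert cl.canonical_name("ame-miRN2") == cl.canonical_name("ame-miRN-2")


class TestFamilySummaries:
    @staticmethod
    def _records_from_fixture(which):
        rows = load_catalog_fixture(which)
        return [
            cl.MirnaRecord(
                name=r.name, mature_seq=r.mature_seq,
                mirna_class=(cl.MirnaClass.CONSERVED_PRECURSOR if which == "table2"
                             else cl.MirnaClass.NON_CONSERVED),
                family=r.family, homolog_id=r.homolog, reads=r.reads,
                precursor_ids=["p"],
            )
            for r in rows
        ]

    def test_mir166_is_top_family_with_88223_reads(self):
        summaries = cl.family_summaries(self._records_from_fixture("table2"))
        assert summaries[0].family == "MIR166"
        assert summaries[0].total_reads == 88223

    def test_totals_conserve(self):
        recs = self._records_from_fixture("table2")
        summaries = cl.family_summaries(recs)
        assert sum(s.total_reads for s in summaries) == sum(r.reads for r in recs)

    def test_two_novel_mirnas_above_1000_reads(self):
        recs = self._records_from_fixture("table3")
        assert sum(r.reads > 1000 for r in recs) == 2

    def test_empty_input(self):
        assert cl.family_summaries([]) == []


class TestMfeSummary:
    class _P:
        def __init__(self, mfe, length):
            self.mfe = mfe
            self.mfe_per_nt = mfe / length

    def test_single_precursor(self):
        s = cl.mfe_summary([self._P(-40.0, 100)])
        assert s["mfe_per_nt_mean"] == -0.40

    def test_mean_of_two(self):
        s = cl.mfe_summary([self._P(-30.0, 100), self._P(-50.0, 100)])
        assert s["mfe_mean"] == -40.0


def test_fixture_partition_into_classes():
    """Every catalog record belongs to exactly one class; counts sum up."""
    t2 = TestFamilySummaries._records_from_fixture("table2")
    t3 = TestFamilySummaries._records_from_fixture("table3")
    classes = [r.mirna_class for r in t2 + t3]
    assert len(classes) == 83
    assert sum(c is cl.MirnaClass.CONSERVED_PRECURSOR for c in classes) == 69
    assert sum(c is cl.MirnaClass.NON_CONSERVED for c in classes) == 14
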