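import pytest

from ame_smallrna import discovery as disc
from ame_smallrna import synthetic_data as syn
from ame_smallrna.io_formats import SeqRecord, revcomp
from ame_smallrna.preprocess import SequenceTag


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestMapTags:
    def _multi_locus_transcriptome(self, rng, tag, n_loci):
        spacer = lambda: _random_seq(rng, 30)
        seq = spacer()
        for _ in range(n_loci):
            seq += tag + spacer()
        return [SeqRecord("t1", seq)]

    @pytest.mark.parametrize("n_loci,kept", [(20, True), (21, False)])
    def test_multimapping_boundary(self, rng, n_loci, kept):
        tag = "TGCACGTTAGCCATGCATGCA"
        trs = self._multi_locus_transcriptome(rng, tag, n_loci)
        hits, discarded = disc.map_tags([SequenceTag(tag, 5)], trs)
        if kept:
            assert len(hits) == n_loci and discarded == []
        else:
            assert hits == [] and discarded == [tag]

    def test_planted_mature_maps_to_its_locus(self, planted):
        transcripts, _, ledger = planted
        for m in ledger.mirnas:
            if not m.transcript_id:
                continue
            hits, _ = disc.map_tags([SequenceTag(m.mature, 1)], transcripts)
            plus = [h for h in hits if h.strand == "+"]
            assert [(h.transcript_id, h.start) for h in plus] == [
                (m.transcript_id, m.mature_start)
            ]

    def test_minus_strand_hit(self):
        tag = "TGCACGTTAGCCATGCATGCA"
        tr = SeqRecord("t1", "AC" * 20 + revcomp(tag) + "GT" * 20)
        hits, _ = disc.map_tags([SequenceTag(tag, 1)], [tr])
        assert [h.strand for h in hits] == ["-"]

    def test_empty_transcriptome_is_error(self):
        with pytest.raises(ValueError):
            disc.map_tags([SequenceTag("ACGT" * 5, 1)], [])


class TestExcise:
    def test_truncation_at_transcript_start(self):
        hit = disc.GenomeHit("A" * 21, "t", 5, 26, "+")
        windows = disc.excise_candidates(hit, {"t": "A" * 500})
        assert (0, 46) in windows  # upstream flank truncated to 5

    def test_interior_window_size(self):
        hit = disc.GenomeHit("A" * 21, "t", 250, 271, "+")
        windows = disc.excise_candidates(hit, {"t": "A" * 600})
        assert (50, 471) in windows  # flank 200 both sides
        assert all(w0 <= 250 and w1 >= 271 for w0, w1 in windows)


class TestFold:
    def test_homopolymer_is_unpaired(self):
        structure, mfe = disc.fold("A" * 60)
        assert set(structure) == {"."} and mfe == 0.0

    def test_inverted_repeat_forms_hairpin(self, rng):
        stem = _random_seq(rng, 30)
        seq = stem + "TTTCGG" + revcomp(stem)
        structure, mfe = disc.fold(seq)
        assert mfe < 0
        assert "(" in structure and ")" in structure

    def test_refolding_is_deterministic(self, rng):
        seq = _random_seq(rng, 120)
        assert disc.fold(seq) == disc.fold(seq)


class TestEvaluateHairpin:
    def _perfect_window(self, rng, mature_len=21):
        mature = _random_seq(rng, mature_len)
        window = (_random_seq(rng, 20) + mature + _random_seq(rng, 12)
                  + revcomp(mature) + _random_seq(rng, 20))
        return window, 20, mature_len

    def test_perfect_duplex_passes(self, rng):
        for _ in range(3):
            window, off, n = self._perfect_window(rng)
            cand = disc.evaluate_hairpin(window, off, n)
            if cand.verdict:
                assert cand.failure_reasons == []
                assert cand.mfe_per_nt <= disc.MFE_PER_NT_MAX
                return
        pytest.fail("no perfect-duplex window passed")

    def test_weak_fold_fails_mfe_criterion(self):
        # an unstructured window: mfe close to 0 -> mfe/nt above the floor
        window = ("ACAAACAAACAAACAAACAAAC" * 4)[:80]
        cand = disc.evaluate_hairpin(window, 20, 21)
        assert not cand.verdict
        assert "mfe_per_nt" in cand.failure_reasons

    def test_short_window_fails_length_criterion(self, rng):
        mature = _random_seq(rng, 21)
        window = mature + "TTTCGG" + revcomp(mature)  # 48 nt < 60
        cand = disc.evaluate_hairpin(window, 0, 21)
        assert "precursor_length" in cand.failure_reasons

    def test_mature_outside_window_is_programming_error(self):
        with pytest.raises(ValueError):
            disc.evaluate_hairpin("A" * 60, 50, 21)

    def test_star_reads_counted(self, planted):
        transcripts, _, ledger = planted
        tr = {t.id: t.seq for t in transcripts}
        m = next(m for m in ledger.mirnas if m.transcript_id)
        seq = tr[m.transcript_id]
        w0 = m.mature_start - 50
        cand = disc.evaluate_hairpin(
            seq[w0 : m.mature_start + len(m.mature) + 50], 50, len(m.mature),
            tags={m.star: 17},
        )
        assert cand.star_seq == m.star
        assert cand.star_reads == 17


class TestSelectPrecursor:
    def _cand(self, mfe_per_nt, length, verdict=True, start=0):
        c = disc.HairpinCandidate(
            precursor_seq="A" * length, structure="." * length, mfe=mfe_per_nt * length,
            mfe_per_nt=mfe_per_nt, mature_offset=0, mature_seq="A" * 21, arm="5p",
            star_seq="", star_reads=0, verdict=verdict)
        c.window_start = start
        return c

    def test_lowest_mfe_per_nt_wins(self):
        a, b = self._cand(-0.40, 100), self._cand(-0.30, 100)
        assert disc.select_precursor([b, a]) is a

    def test_matches_brute_force_argmin(self, rng):
        cands = [self._cand(round(float(-rng.uniform(0.2, 0.6)), 3),
                            int(rng.integers(60, 300)), start=int(rng.integers(100)))
                 for _ in range(20)]
        chosen = disc.select_precursor(cands)
        brute = min(cands, key=lambda c: (c.mfe_per_nt, len(c.precursor_seq),
                                          c.transcript_id, c.window_start))
        assert chosen is brute

    def test_none_when_no_pass(self):
        assert disc.select_precursor([self._cand(-0.4, 100, verdict=False)]) is None


class TestRecovery:
    def test_zero_noise_planted_matures_all_recovered(self, planted):
        transcripts, _, ledger = planted
        tags = [SequenceTag(m.mature, m.reads) for m in ledger.mirnas if m.transcript_id]
        best, discarded = disc.discover_mirnas(tags, transcripts)
        assert discarded == []
        for m in ledger.mirnas:
            if not m.transcript_id:
                continue
            assert m.mature in best, f"{m.name} not recovered"
            cand = best[m.mature]
            assert cand.verdict
            # refolding the emitted precursor reproduces structure and MFE
            assert disc.fold(cand.precursor_seq) == (cand.structure, cand.mfe)

    def test_no_hairpins_planted_yields_empty_catalog(self):
        transcripts, _, ledger = syn.generate_transcriptome(
            n_transcripts=5, n_hairpins=0, n_no_precursor=0, seed=3
        )
        assert ledger.mirnas == []
        # degradation-like tags from random background find no passing hairpin
        tags = [SequenceTag(t.seq[i : i + 21], 1)
                for t in transcripts[:2] for i in range(0, 100, 25)]
        best, _ = disc.discover_mirnas(tags, transcripts)
        assert best == {}
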