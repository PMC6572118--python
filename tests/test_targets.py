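import pytest

from ame_smallrna import targets as tg
from ame_smallrna.io_formats import SeqRecord, revcomp


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------- independent oracle: explicit enumeration of every alignment ----------

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _state(m, t):
    if COMP[m] == t:
        return "match"
    if (m, t) in (("G", "T"), ("T", "G")):
        return "gu"
    return "mm"


def _score(position_states):
    total, seed_mm = 0.0, 0
    for pos, st in position_states:
        w = 1.5 if 2 <= pos <= 13 else 1.0
        if st == "gu":
            total += 0.5 * w
        elif st == "mm":
            total += 1.0 * w
            if 2 <= pos <= 13:
                seed_mm += 1
        elif st == "gap":
            total += 2.0 * w
    return total, seed_mm


def oracle_hits(mirna, transcript_seq, cutoff=3.0, max_seed_mm=2):
    """All qualifying (start, end, expectation) spans, best alignment per span."""
    n = len(mirna)
    found = {}

    def consider(j, L, states):
        exp, seed_mm = _score(states)
        if exp <= cutoff and seed_mm <= max_seed_mm:
            key = (j, j + L)
            if key not in found or exp < found[key]:
                found[key] = exp

    for j in range(len(transcript_seq)):
        # ungapped
        L = n
        if j + L <= len(transcript_seq):
            site = transcript_seq[j : j + L]
            states = [(i, _state(mirna[i - 1], site[L - i])) for i in range(1, n + 1)]
            consider(j, L, states)
        # one bulged target nucleotide after miRNA position g (g >= 13)
        L = n + 1
        if j + L <= len(transcript_seq):
            site = transcript_seq[j : j + L]
            for g in range(13, n):
                states = [(i, _state(mirna[i - 1], site[L - i])) for i in range(1, g + 1)]
                states.append((g, "gap"))
                states += [(i, _state(mirna[i - 1], site[L - 1 - i]))
                           for i in range(g + 1, n + 1)]
                consider(j, L, states)
        # one unopposed miRNA nucleotide at position g (g == 1 or g >= 14)
        L = n - 1
        if j + L <= len(transcript_seq):
            site = transcript_seq[j : j + L]
            for g in [1] + list(range(14, n + 1)):
                states = []
                for i in range(1, n + 1):
                    if i == g:
                        states.append((i, "gap"))
                    else:
                        jj = i if i < g else i - 1
                        states.append((i, _state(mirna[i - 1], site[L - jj])))
                consider(j, L, states)
    return found


# ---------- unit behaviour ----------


class TestScoreAlignment:
    def test_perfect_complement_scores_zero(self, rng):
        m = _random_seq(rng, 21)
        exp, states = tg.score_alignment(m, revcomp(m))
        assert exp == 0.0 and set(states) == {"="}

    def test_single_gu_in_seed(self):
        m = "A" * 4 + "G" + "A" * 16  # G at position 5
        site = list(revcomp(m))
        site[21 - 5] = "T"  # opposite position 5: G:U wobble
        exp, states = tg.score_alignment(m, "".join(site))
        assert exp == pytest.approx(0.75)  # 0.5 x 1.5
        assert states[4] == "o"

    def test_single_mismatch_outside_seed(self):
        m = "A" * 21
        site = list(revcomp(m))
        site[21 - 20] = "G"  # mismatch opposite position 20
        exp, states = tg.score_alignment(m, "".join(site))
        assert exp == pytest.approx(1.0)
        assert states[19] == "x"

    def test_seed_weighting_is_positional(self):
        m = "A" * 21
        for pos, expected in ((5, 1.5), (20, 1.0)):
            site = list(revcomp(m))
            site[21 - pos] = "C"  # A:C mismatch (not a wobble)
            exp, _ = tg.score_alignment(m, "".join(site))
            assert exp == pytest.approx(expected)

    def test_monotonicity_adding_mismatches(self, rng):
        m = _random_seq(rng, 21)
        site = list(revcomp(m))
        prev = 0.0
        for pos in rng.permutation(21)[:6]:
            cur = site[20 - int(pos)]
            site[20 - int(pos)] = {"A": "C", "C": "A", "G": "A", "T": "C"}[cur]
            exp, _ = tg.score_alignment(m, "".join(site))
            assert exp >= prev
            prev = exp

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            tg.ScoringParams(gu_penalty=-1)


class TestScan:
    def test_exact_complement_found_at_expectation_zero(self, rng):
        m = _random_seq(rng, 21)
        tr = SeqRecord("t1", _random_seq(rng, 100) + revcomp(m) + _random_seq(rng, 100))
        hits = tg.scan_transcriptome("q", m, [tr])
        best = hits[0]
        assert best.expectation == 0.0 and best.t_start == 100

    def test_three_seed_mismatches_never_a_hit(self, rng):
        m = _random_seq(rng, 21)
        site = list(revcomp(m))
        for pos in (3, 6, 9):  # 3 seed mismatches
            cur = site[21 - pos]
            site[21 - pos] = {"A": "C", "C": "A", "G": "A", "T": "C"}[cur]
        tr = SeqRecord("t1", "".join(site))
        assert tg.scan_transcriptome("q", m, [tr]) == []

    def test_hits_sorted_and_capped(self, rng):
        m = _random_seq(rng, 21)
        seq = ("".join(revcomp(m) + _random_seq(rng, 10) for _ in range(5)))
        tr = SeqRecord("t1", seq)
        params = tg.ScoringParams(top_n=3)
        hits = tg.scan_transcriptome("q", m, [tr], params)
        assert len(hits) == 3
        assert hits == sorted(hits, key=lambda h: (h.expectation, h.transcript_id, h.t_start))

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            m = _random_seq(rng, int(rng.integers(20, 23)))
            base = _random_seq(rng, 300)
            # plant a near-complement so qualifying sites actually occur
            site = list(revcomp(m))
            for pos in rng.permutation(len(m))[: int(rng.integers(0, 3))]:
                cur = site[int(pos)]
                site[int(pos)] = {"A": "C", "C": "A", "G": "A", "T": "C"}[cur]
            seq = base[:150] + "".join(site) + base[150:]
            tr = SeqRecord("t1", seq)
            hits = tg.scan_transcriptome("q", m, [tr])
            got = {(h.t_start, h.t_end): h.expectation for h in hits}
            assert got == oracle_hits(m, seq)


class TestMechanism:
    def _hit(self, alignment, n=21):
        return tg.TargetHit("q", "t", 0, n, 0.0, 0, alignment, mirna_seq="A" * n)

    def test_perfect_complement_is_cleavage(self):
        assert tg.infer_mechanism(self._hit("=" * 21)) == "cleavage"

    def test_central_mismatch_is_translation(self):
        aln = "=" * 9 + "x" + "=" * 11  # mismatch at position 10
        assert tg.infer_mechanism(self._hit(aln)) == "translation"

    def test_gu_in_center_is_still_cleavage(self):
        aln = "=" * 9 + "o" + "=" * 11
        assert tg.infer_mechanism(self._hit(aln)) == "cleavage"

    def test_cleavage_site_coordinate(self):
        h = self._hit("=" * 21)
        h.t_start, h.t_end = 100, 121
        assert tg.cleavage_site(h) == 111  # between nt opposite positions 10/11
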