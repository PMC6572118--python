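"""miRNA target prediction with expectation scoring.

A target site is scored antiparallel against the miRNA: each position
contributes penalty x weight, with penalties 0 (Watson-Crick match),
0.5 (G:U wobble), 1 (other mismatch), 2 (gap), and weight 1.5 inside the
seed region (miRNA positions 2-13 from the 5' end), 1.0 elsewhere. Hits are
kept when the summed expectation is at most the cutoff (default 3, inclusive)
and the seed carries at most 2 mismatches (G:U pairs do not count against the
seed cap). At most one gap per alignment, never in the seed.

Alignment state strings use '=' match, 'o' G:U, 'x' mismatch, '-' gap,
ordered 5'->3' along the miRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import SeqRecord

WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "T"), ("T", "G")}

SEED_START, SEED_END = 2, 13  # 1-based miRNA positions, inclusive


@dataclass
class ScoringParams:
    expectation_cutoff: float = 3.0
    gu_penalty: float = 0.5
    mismatch_penalty: float = 1.0
    gap_penalty: float = 2.0
    seed_weight: float = 1.5
    max_seed_mismatches: int = 2
    max_gaps: int = 1
    top_n: int = 200

    def __post_init__(self) -> None:
        for name in ("expectation_cutoff", "gu_penalty", "mismatch_penalty",
                     "gap_penalty", "seed_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class TargetHit:
    mirna_name: str
    transcript_id: str
    t_start: int  # 0-based half-open on the transcript
    t_end: int
    expectation: float
    seed_mismatches: int
    alignment: str
    mechanism: str = ""  # 'cleavage' or 'translation'
    mirna_seq: str = ""


def _pair_state(m: str, t: str) -> str:
    if (m, t) in WC:
        return "="
    if (m, t) in GU:
        return "o"
    return "x"


def _weight(pos: int, params: ScoringParams) -> float:
    return params.seed_weight if SEED_START <= pos <= SEED_END else 1.0


def score_alignment(
    mirna_seq: str, site_seq: str, params: ScoringParams | None = None
) -> tuple[float, str]:
    """Score an ungapped antiparallel alignment (site 5'->3', same length).

    Returns (expectation, per-position state string along the miRNA).
    """
    params = params or ScoringParams()
    n = len(mirna_seq)
    if len(site_seq) != n:
        raise ValueError("ungapped scoring requires equal lengths")
    expectation = 0.0
    states = []
    for i in range(n):  # miRNA position i+1 pairs site index n-1-i
        st = _pair_state(mirna_seq[i], site_seq[n - 1 - i])
        states.append(st)
        if st == "o":
            expectation += params.gu_penalty * _weight(i + 1, params)
        elif st == "x":
            expectation += params.mismatch_penalty * _weight(i + 1, params)
    return expectation, "".join(states)


def _score_states(states: list[tuple[int, str]], params: ScoringParams) -> float:
    total = 0.0
    for pos, st in states:
        if st == "o":
            total += params.gu_penalty * _weight(pos, params)
        elif st == "x":
            total += params.mismatch_penalty * _weight(pos, params)
        elif st == "-":
            total += params.gap_penalty * _weight(pos, params)
    return total


def _gapped_alignments(mirna: str, site: str, params: ScoringParams):
    """Yield (expectation, seed_mm, state_string) for every allowed alignment
    of the miRNA against a site of length n-1, n, or n+1 (at most one gap,
    never inside the seed)."""
    n = len(mirna)
    L = len(site)
    if L == n:
        exp, states = score_alignment(mirna, site, params)
        seed_mm = sum(1 for i, st in enumerate(states) if st == "x"
                      and SEED_START <= i + 1 <= SEED_END)
        yield exp, seed_mm, states
    elif L == n + 1 and params.max_gaps >= 1:
        # one bulged target nucleotide between miRNA positions g and g+1
        for g in range(SEED_END, n):
            states: list[tuple[int, str]] = []
            out = []
            for i in range(1, g + 1):
                st = _pair_state(mirna[i - 1], site[L - i])
                states.append((i, st)); out.append(st)
            states.append((g, "-")); out.append("-")  # bulge, weight outside seed
            for i in range(g + 1, n + 1):
                st = _pair_state(mirna[i - 1], site[L - 1 - i])
                states.append((i, st)); out.append(st)
            seed_mm = sum(1 for p, st in states if st == "x" and SEED_START <= p <= SEED_END)
            yield _score_states(states, params), seed_mm, "".join(out)
    elif L == n - 1 and params.max_gaps >= 1:
        # one unopposed miRNA nucleotide at position g (outside the seed)
        for g in [1] + list(range(SEED_END + 1, n + 1)):
            states = []
            out = []
            for i in range(1, n + 1):
                if i == g:
                    states.append((i, "-")); out.append("-")
                    continue
                j = i if i < g else i - 1  # consumed site positions
                st = _pair_state(mirna[i - 1], site[L - j])
                states.append((i, st)); out.append(st)
            seed_mm = sum(1 for p, st in states if st == "x" and SEED_START <= p <= SEED_END)
            yield _score_states(states, params), seed_mm, "".join(out)


def scan_transcript(
    mirna_name: str,
    mirna_seq: str,
    transcript: SeqRecord,
    params: ScoringParams | None = None,
) -> list[TargetHit]:
    """All qualifying sites of one miRNA on one transcript (best alignment per
    site span)."""
    params = params or ScoringParams()
    n = len(mirna_seq)
    seq = transcript.seq
    hits: dict[tuple[int, int], TargetHit] = {}
    for L in (n - 1, n, n + 1):
        if L < 1 or (L != n and params.max_gaps < 1):
            continue
        for j in range(0, len(seq) - L + 1):
            site = seq[j : j + L]
            for exp, seed_mm, states in _gapped_alignments(mirna_seq, site, params):
                if exp > params.expectation_cutoff or seed_mm > params.max_seed_mismatches:
                    continue
                key = (j, j + L)
                prev = hits.get(key)
                if prev is None or exp < prev.expectation:
                    hits[key] = TargetHit(
                        mirna_name=mirna_name,
                        transcript_id=transcript.id,
                        t_start=j,
                        t_end=j + L,
                        expectation=exp,
                        seed_mismatches=seed_mm,
                        alignment=states,
                        mirna_seq=mirna_seq,
                    )
    return list(hits.values())


def scan_transcriptome(
    mirna_name: str,
    mirna_seq: str,
    transcripts: list[SeqRecord],
    params: ScoringParams | None = None,
) -> list[TargetHit]:
    """Qualifying sites across all transcripts, ascending by expectation
    (ties: lower transcript id, then leftmost), capped at ``top_n``."""
    params = params or ScoringParams()
    hits: list[TargetHit] = []
    for tr in transcripts:
        hits.extend(scan_transcript(mirna_name, mirna_seq, tr, params))
    hits.sort(key=lambda h: (h.expectation, h.transcript_id, h.t_start))
    for h in hits:
        h.mechanism = infer_mechanism(h)
    return hits[: params.top_n]


def infer_mechanism(hit: TargetHit) -> str:
    """'translation' when any mismatch/gap falls at miRNA positions 9-11
    (the cleavage-competent center), else 'cleavage'."""
    # walk the state string tracking miRNA position (target-bulge gaps do not
    # advance the miRNA position)
    pos = 0
    n = len(hit.mirna_seq)
    for st in hit.alignment:
        advance = True
        if st == "-" and len(hit.alignment) > n:
            advance = False  # bulged target nucleotide
        if advance:
            pos += 1
        if st in ("x", "-") and 9 <= pos <= 11:
            return "translation"
    return "cleavage"


def cleavage_site(hit: TargetHit) -> int:
    """Transcript coordinate of the cut, between the target nucleotides
    opposite miRNA positions 10 and 11 (0-based: cut before this index)."""
    return hit.t_end - 10
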