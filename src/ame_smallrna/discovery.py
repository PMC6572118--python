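"""Candidate miRNA discovery: map distinct tags to the transcriptome, excise
flanking windows, fold them, and apply plant-miRNA hairpin criteria.

A candidate passes when the folded window forms a single stem-loop with the
mature entirely in one arm, the mature/star duplex has at most 4 unpaired
mature positions, at most 2 asymmetric bulges totalling at most 3 bulged
nucleotides, folding free energy at most -0.19 kcal/mol per nucleotide, and a
precursor length of 60-300 nt. The star sequence is placed with the canonical
2-nt 3' overhang of Dicer products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import RNA

from .io_formats import SeqRecord, revcomp
from .preprocess import SequenceTag

DEFAULT_MAX_LOCI = 20
DEFAULT_FLANKS = (20, 50, 100, 150, 200)
MAX_DUPLEX_MISMATCHES = 4
MAX_ASYMMETRIC_BULGES = 2
MAX_BULGED_NT = 3
MFE_PER_NT_MAX = -0.19  # kcal/mol/nt, weakest value accepted
MIN_PRECURSOR_LEN = 60
MAX_PRECURSOR_LEN = 300


@dataclass
class GenomeHit:
    """An exact match of a tag on a transcript (0-based half-open)."""

    tag_seq: str
    transcript_id: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class HairpinCandidate:
    precursor_seq: str
    structure: str
    mfe: float
    mfe_per_nt: float
    mature_offset: int  # 0-based offset of the mature within the precursor
    mature_seq: str
    arm: str  # '5p' or '3p'
    star_seq: str
    star_reads: int
    verdict: bool
    failure_reasons: list[str] = field(default_factory=list)
    transcript_id: str = ""
    window_start: int = 0  # precursor start on the transcript


def map_tags(
    tags: list[SequenceTag],
    transcripts: list[SeqRecord],
    max_loci: int = DEFAULT_MAX_LOCI,
) -> tuple[list[GenomeHit], list[str]]:
    """Exact ungapped mapping on both strands.

    Tags with more than ``max_loci`` total hits are discarded (multi-mapping
    repeats) and returned separately as flagged sequences.
    """
    if not transcripts:
        raise ValueError("empty transcriptome reference")
    hits: list[GenomeHit] = []
    discarded: list[str] = []
    for tag in tags:
        tag_hits: list[GenomeHit] = []
        rc = revcomp(tag.seq)
        for tr in transcripts:
            for strand, query in (("+", tag.seq), ("-", rc)):
                start = tr.seq.find(query)
                while start != -1:
                    tag_hits.append(
                        GenomeHit(tag.seq, tr.id, start, start + len(query), strand)
                    )
                    start = tr.seq.find(query, start + 1)
        if len(tag_hits) > max_loci:
            discarded.append(tag.seq)
        else:
            hits.extend(tag_hits)
    return hits, discarded


def excise_candidates(
    hit: GenomeHit,
    transcripts: dict[str, str],
    flank_set: tuple[int, ...] = DEFAULT_FLANKS,
) -> list[tuple[int, int]]:
    """Candidate precursor windows around a hit, one per flank size.

    Windows are (start, end) on the transcript, truncated at its ends, and
    always contain the mature hit.
    """
    seq = transcripts[hit.transcript_id]
    windows = []
    for flank in flank_set:
        start = max(0, hit.start - flank)
        end = min(len(seq), hit.end + flank)
        windows.append((start, end))
    return sorted(set(windows))


def fold(seq: str) -> tuple[str, float]:
    """Thermodynamic MFE fold (dot-bracket, kcal/mol) at default temperature."""
    if len(seq) < 40:
        raise ValueError("precursor windows shorter than 40 nt are not folded")
    structure, mfe = RNA.fold(seq.replace("T", "U"))
    return structure, float(mfe)


def _pair_table(structure: str) -> list[int]:
    """0-based partner index per position, -1 when unpaired."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pt[i], pt[j] = j, i
    return pt


def _duplex_geometry(pt: list[int], m0: int, m1: int) -> dict:
    """Mismatch/bulge accounting for the mature span [m0, m1) against its arm."""
    paired = [i for i in range(m0, m1) if pt[i] >= 0]
    mismatches = (m1 - m0) - len(paired)
    self_paired = any(m0 <= pt[i] < m1 for i in paired)
    partners = [pt[i] for i in paired]
    arm_5p = bool(partners) and all(p >= m1 for p in partners)
    arm_3p = bool(partners) and all(p < m0 for p in partners)

    asym_bulges = 0
    bulged_nt = 0
    for a, b in zip(paired, paired[1:]):
        gap_m = b - a - 1  # unpaired mature nt between anchors
        gap_s = abs(pt[a] - pt[b]) - 1  # unpaired star nt between anchors
        if gap_m != gap_s:
            asym_bulges += 1
            bulged_nt += abs(gap_m - gap_s)
    return {
        "mismatches": mismatches,
        "self_paired": self_paired,
        "one_arm": arm_5p or arm_3p,
        "arm": "5p" if arm_5p else "3p",
        "asym_bulges": asym_bulges,
        "bulged_nt": bulged_nt,
        "paired": paired,
    }


def _star_coords(pt: list[int], paired: list[int], m0: int, m1: int, n: int) -> tuple[int, int]:
    """Star span with a 2-nt 3' overhang relative to the mature duplex."""
    first, last = paired[0], paired[-1]
    lo = min(pt[first], pt[last])
    hi = max(pt[first], pt[last]) + 1
    # extend partner span to the mature's unpaired ends, then apply overhangs:
    # star 5' end pairs opposite mature 3' end minus 2; star 3' end extends 2 nt
    lo -= (m1 - 1) - last  # unpaired mature 3' tail
    hi += first - m0  # unpaired mature 5' tail
    lo += 2
    hi += 2
    return max(0, lo), min(n, hi)


def evaluate_hairpin(
    window_seq: str,
    mature_offset: int,
    mature_len: int,
    tags: dict[str, int] | None = None,
    structure: str | None = None,
    mfe: float | None = None,
) -> HairpinCandidate:
    """Fold a precursor window and apply the hairpin criteria.

    ``tags`` maps tag sequence -> read count and is used to count reads
    supporting the computed star sequence.
    """
    m0, m1 = mature_offset, mature_offset + mature_len
    if m0 < 0 or m1 > len(window_seq):
        raise ValueError("mature span not inside the window")
    if structure is None or mfe is None:
        structure, mfe = fold(window_seq)
    n = len(window_seq)
    mfe_per_nt = mfe / n
    pt = _pair_table(structure)
    geo = _duplex_geometry(pt, m0, m1)

    reasons: list[str] = []
    if geo["self_paired"] or not geo["one_arm"]:
        reasons.append("mature_not_in_single_arm")
    if geo["mismatches"] > MAX_DUPLEX_MISMATCHES:
        reasons.append("duplex_mismatches")
    if geo["asym_bulges"] > MAX_ASYMMETRIC_BULGES or geo["bulged_nt"] > MAX_BULGED_NT:
        reasons.append("duplex_bulges")
    if mfe_per_nt > MFE_PER_NT_MAX:
        reasons.append("mfe_per_nt")
    if not (MIN_PRECURSOR_LEN <= n <= MAX_PRECURSOR_LEN):
        reasons.append("precursor_length")

    star_seq = ""
    star_reads = 0
    if geo["paired"] and geo["one_arm"]:
        s0, s1 = _star_coords(pt, geo["paired"], m0, m1, n)
        if s1 > s0:
            star_seq = window_seq[s0:s1]
            if tags:
                star_reads = tags.get(star_seq, 0)

    return HairpinCandidate(
        precursor_seq=window_seq,
        structure=structure,
        mfe=mfe,
        mfe_per_nt=mfe_per_nt,
        mature_offset=m0,
        mature_seq=window_seq[m0:m1],
        arm=geo["arm"] if geo["one_arm"] else "",
        star_seq=star_seq,
        star_reads=star_reads,
        verdict=not reasons,
        failure_reasons=reasons,
    )


def select_precursor(candidates: list[HairpinCandidate]) -> HairpinCandidate | None:
    """Best passing window: lowest MFE/nt, then shortest, then leftmost."""
    passing = [c for c in candidates if c.verdict]
    if not passing:
        return None
    return min(
        passing,
        key=lambda c: (c.mfe_per_nt, len(c.precursor_seq), c.transcript_id, c.window_start),
    )


def discover_mirnas(
    tags: list[SequenceTag],
    transcripts: list[SeqRecord],
    max_loci: int = DEFAULT_MAX_LOCI,
    flank_set: tuple[int, ...] = DEFAULT_FLANKS,
    min_reads: int = 1,
) -> tuple[dict[str, HairpinCandidate], list[str]]:
    """End-to-end discovery: returns {mature_seq: best passing hairpin} plus
    the over-mapped tag sequences that were discarded."""
    tag_counts = {t.seq: t.count for t in tags}
    eligible = [t for t in tags if t.count >= min_reads]
    hits, discarded = map_tags(eligible, transcripts, max_loci=max_loci)
    tr_seqs = {t.id: t.seq for t in transcripts}

    best: dict[str, HairpinCandidate] = {}
    per_mature: dict[str, list[HairpinCandidate]] = {}
    fold_cache: dict[str, tuple[str, float]] = {}
    for hit in hits:
        seq = tr_seqs[hit.transcript_id]
        if hit.strand == "-":
            # fold the orientation on which the tag reads 5'->3'
            seq = revcomp(seq)
            start = len(seq) - hit.end
        else:
            start = hit.start
        mature_len = hit.end - hit.start
        key = hit.transcript_id if hit.strand == "+" else hit.transcript_id + "(-)"
        for w0, w1 in excise_candidates(
            GenomeHit(hit.tag_seq, key, start, start + mature_len, "+"),
            {key: seq},
            flank_set,
        ):
            window = seq[w0:w1]
            if len(window) < 40:
                continue
            if window not in fold_cache:
                fold_cache[window] = fold(window)
            structure, mfe = fold_cache[window]
            cand = evaluate_hairpin(
                window, start - w0, mature_len, tags=tag_counts,
                structure=structure, mfe=mfe,
            )
            cand.transcript_id = key
            cand.window_start = w0
            per_mature.setdefault(hit.tag_seq, []).append(cand)
    for mature, cands in per_mature.items():
        chosen = select_precursor(cands)
        if chosen is not None:
            best[mature] = chosen
    return best, discarded
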