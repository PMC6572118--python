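"""TAS3-like locus detection by the two-hit trigger signature and extraction
of in-register phasiRNAs.

TAS3 transcripts carry two miR390 complementary sites; only the downstream
(3') site is cleaved, and 21-nt phased siRNAs are processed 5'-ward from the
cut in fixed 21-nt steps. Detection here is trigger-anchored: transcripts with
exactly two trigger sites at least 50 nt apart are TAS candidates, the phasing
register originates at the downstream cleavage point (between target
nucleotides opposite trigger positions 10 and 11), and tags of the phase
length whose start offset from the register is a multiple of the phase length
are reported as phasiRNAs. Minus-strand tags are reported in-register with the
canonical 2-nt offset of the siRNA duplex overhang.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import SeqRecord, revcomp
from .preprocess import SequenceTag
from .targets import ScoringParams, TargetHit, cleavage_site, scan_transcript

PHASE_LENGTH = 21
MIN_SITE_SEPARATION = 50

# relaxed scan so the non-cleavable upstream site is still detected
TRIGGER_SCAN_PARAMS = ScoringParams(expectation_cutoff=5.0, max_seed_mismatches=3)


@dataclass
class PhasiRna:
    seq: str
    count: int
    phase_index: int  # 1 = window immediately upstream of the cleavage site
    start: int  # transcript coordinate
    strand: str = "+"


@dataclass
class TasLocus:
    transcript_id: str
    site5: TargetHit
    site3: TargetHit
    register_origin: int  # cleavage point of the downstream site
    phase_length: int = PHASE_LENGTH
    phasirnas: list[PhasiRna] = field(default_factory=list)


def find_trigger_sites(
    transcript: SeqRecord,
    trigger_seq: str,
    params: ScoringParams | None = None,
) -> list[TargetHit]:
    """Trigger-complementary sites on one transcript under the relaxed cutoff."""
    params = params or TRIGGER_SCAN_PARAMS
    hits = scan_transcript("trigger", trigger_seq, transcript, params)
    # overlapping alignment variants (shifted/bulged spans of the same
    # complementary region) collapse to the single best-scoring site
    hits.sort(key=lambda h: (h.t_start, h.expectation))
    merged: list[TargetHit] = []
    for h in hits:
        if merged and h.t_start < merged[-1].t_end:
            if h.expectation < merged[-1].expectation:
                merged[-1] = h
        else:
            merged.append(h)
    from .targets import infer_mechanism

    for h in merged:
        h.mechanism = infer_mechanism(h)
    return merged


def detect_tas_loci(
    transcripts: list[SeqRecord],
    trigger_seq: str,
    phase_length: int = PHASE_LENGTH,
    min_separation: int = MIN_SITE_SEPARATION,
) -> tuple[list[TasLocus], list[str]]:
    """Transcripts with exactly two trigger sites >= min_separation apart.

    Transcripts with three or more sites are not called loci but returned as
    flagged ids for manual review.
    """
    loci: list[TasLocus] = []
    flagged: list[str] = []
    for tr in transcripts:
        sites = find_trigger_sites(tr, trigger_seq)
        if len(sites) > 2:
            flagged.append(tr.id)
            continue
        if len(sites) != 2:
            continue
        site5, site3 = sites
        if site3.t_start - site5.t_start < min_separation:
            continue
        loci.append(
            TasLocus(
                transcript_id=tr.id,
                site5=site5,
                site3=site3,
                register_origin=cleavage_site(site3),
                phase_length=phase_length,
            )
        )
    return loci, flagged


def extract_phasirnas(
    locus: TasLocus,
    tags: list[SequenceTag],
    transcript: SeqRecord,
) -> TasLocus:
    """Fill in the tags that sit in-register between the two trigger sites.

    A plus-strand tag of the phase length starting at s is in-register when
    (origin - s) is a positive multiple of the phase length; minus-strand tags
    are in-register when offset additionally by the 2-nt duplex overhang.
    """
    region_start = locus.site5.t_end
    origin = locus.register_origin
    plen = locus.phase_length
    seq = transcript.seq
    found: list[PhasiRna] = []
    for tag in tags:
        if len(tag.seq) != plen:
            continue
        for strand, query in (("+", tag.seq), ("-", revcomp(tag.seq))):
            start = seq.find(query)
            while start != -1:
                end = start + plen
                if start >= region_start and end <= origin:
                    offset = origin - start if strand == "+" else origin - start - 2
                    if offset % plen == 0 and offset > 0:
                        found.append(
                            PhasiRna(
                                seq=tag.seq,
                                count=tag.count,
                                phase_index=offset // plen,
                                start=start,
                                strand=strand,
                            )
                        )
                start = seq.find(query, start + 1)
    found.sort(key=lambda p: (p.phase_index, p.strand, p.seq))
    locus.phasirnas = found
    return locus


def phase_score(
    locus: TasLocus,
    tags: list[SequenceTag],
    transcript: SeqRecord,
) -> float | None:
    """Fraction of inter-site reads that are in-register; None when the
    inter-site region carries no reads."""
    region_start = locus.site5.t_end
    origin = locus.register_origin
    plen = locus.phase_length
    seq = transcript.seq
    in_register = 0
    total = 0
    for tag in tags:
        for strand, query in (("+", tag.seq), ("-", revcomp(tag.seq))):
            start = seq.find(query)
            while start != -1:
                end = start + len(tag.seq)
                if start >= region_start and end <= origin:
                    total += tag.count
                    offset = origin - start if strand == "+" else origin - start - 2
                    if len(tag.seq) == plen and offset % plen == 0 and offset > 0:
                        in_register += tag.count
                start = seq.find(query, start + 1)
    if total == 0:
        return None
    return in_register / total
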