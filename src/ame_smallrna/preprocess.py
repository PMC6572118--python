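"""Raw-read cleaning: adapter trimming, length/junk filtering, tag collapsing,
ncRNA annotation, and the library accounting report.

The cleaning convention follows standard small-RNA practice: a read must carry
the 3' sequencing adapter (otherwise the insert ran past the read or ligation
failed), the insert must be 18-25 nt after trimming, and low-complexity /
poly(A) inserts are discarded as junk. ncRNA contaminants (rRNA, tRNA, snoRNA,
snRNA, other Rfam families) are flagged by exact substring matching against a
labeled reference set; tags matching a supplied repeat library are flagged the
same way. Everything surviving is a "clean" distinct tag with a read count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from .io_formats import SeqRecord, revcomp

MIN_LEN = 18
MAX_LEN = 25
POLY_A_FRAC = 0.80
LOW_COMPLEXITY_FRAC = 0.90
MIN_ADAPTER_OVERLAP = 6


class NcrnaClass(str, Enum):
    NONE = "none"
    RRNA = "rRNA"
    TRNA = "tRNA"
    SNORNA = "snoRNA"
    SNRNA = "snRNA"
    OTHER_RFAM = "other_rfam"
    REPEAT = "repeat"


# tie-break priority when a tag matches several reference classes
_CLASS_PRIORITY = [
    NcrnaClass.RRNA,
    NcrnaClass.TRNA,
    NcrnaClass.SNORNA,
    NcrnaClass.SNRNA,
    NcrnaClass.OTHER_RFAM,
]

_LABEL_ALIASES = {
    "rrna": NcrnaClass.RRNA,
    "trna": NcrnaClass.TRNA,
    "snorna": NcrnaClass.SNORNA,
    "snrna": NcrnaClass.SNRNA,
}


@dataclass
class SequenceTag:
    """A distinct small-RNA sequence with its collapsed read count."""

    seq: str
    count: int
    ncrna_class: NcrnaClass = NcrnaClass.NONE

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclass
class LibraryStats:
    """Per-category read accounting (totals and distinct sequences)."""

    raw_total: int = 0
    raw_distinct: int = 0
    adapter_or_length_total: int = 0
    adapter_or_length_distinct: int = 0
    junk_total: int = 0
    junk_distinct: int = 0
    rfam_total: int = 0
    rfam_distinct: int = 0
    repeats_total: int = 0
    repeats_distinct: int = 0
    clean_total: int = 0
    clean_distinct: int = 0
    per_class_total: dict = field(default_factory=dict)
    per_class_distinct: dict = field(default_factory=dict)

    def conserved(self) -> bool:
        """Category counts partition the raw input (both totals and distincts)."""
        tot = (
            self.adapter_or_length_total
            + self.junk_total
            + self.rfam_total
            + self.repeats_total
            + self.clean_total
        )
        dis = (
            self.adapter_or_length_distinct
            + self.junk_distinct
            + self.rfam_distinct
            + self.repeats_distinct
            + self.clean_distinct
        )
        return tot == self.raw_total and dis == self.raw_distinct


def percentage(part: int, whole: int) -> float:
    """Percent of ``whole``, rounded to 2 decimals; 0 when whole is 0."""
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, 2)


def trim_adapter(
    read: SeqRecord, adapter3: str, adapter5: str | None = None
) -> SeqRecord | None:
    """Return the insert upstream of the leftmost 3' adapter match, or None.

    A read is rejected (None) when the 3' adapter is absent (even as a
    >=6 nt prefix at the read end), when the 5' adapter occurs in the read,
    or when the trimmed insert is empty.
    """
    if len(adapter3) < MIN_ADAPTER_OVERLAP:
        raise ValueError("3' adapter must be at least 6 nt")
    seq = read.seq
    if adapter5 and adapter5.upper().replace("U", "T") in seq:
        return None
    ad = adapter3.upper().replace("U", "T")
    pos = seq.find(ad)
    if pos == -1:
        # adapter may run off the read end: accept a terminal prefix >= 6 nt
        for k in range(len(ad) - 1, MIN_ADAPTER_OVERLAP - 1, -1):
            if seq.endswith(ad[:k]):
                pos = len(seq) - k
                break
    if pos <= 0:
        return None
    insert = seq[:pos]
    qual = read.quality[:pos] if read.quality else None
    return SeqRecord(id=read.id, seq=insert, quality=qual)


def is_junk(seq: str) -> bool:
    """Any N, >=90% a single nucleotide, or >=80% A (poly-A artifact)."""
    if "N" in seq:
        return True
    counts = Counter(seq)
    n = len(seq)
    if counts.get("A", 0) >= POLY_A_FRAC * n:
        return True
    return max(counts.values()) >= LOW_COMPLEXITY_FRAC * n


def filter_reads(
    reads: list[SeqRecord],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Drop out-of-range-length and junk inserts; count removals per category."""
    kept: list[SeqRecord] = []
    removed = {"length": 0, "junk": 0}
    for r in reads:
        if not (min_len <= len(r.seq) <= max_len):
            removed["length"] += 1
        elif is_junk(r.seq):
            removed["junk"] += 1
        else:
            kept.append(r)
    return kept, removed


def collapse(reads: list[SeqRecord]) -> list[SequenceTag]:
    """One tag per distinct sequence; counts sum to the number of reads."""
    counts = Counter(r.seq for r in reads)
    return [SequenceTag(seq=s, count=c) for s, c in sorted(counts.items())]


def _reference_matcher(ncrna_ref: list[SeqRecord]) -> list[tuple[NcrnaClass, str]]:
    refs = []
    for rec in ncrna_ref:
        if rec.label is None:
            raise ValueError(
                f"ncRNA reference record '{rec.id}' has no class label "
                "(expected '>id class' headers)"
            )
        label = rec.label.strip()
        cls = _LABEL_ALIASES.get(label.lower())
        if cls is None:
            cls = NcrnaClass.OTHER_RFAM
        refs.append((cls, rec.seq))
        refs.append((cls, revcomp(rec.seq)))
    return refs


def annotate_ncrna(
    tags: list[SequenceTag], ncrna_ref: list[SeqRecord]
) -> list[SequenceTag]:
    """Label tags occurring as exact substrings of a classed reference record.

    Ties across classes resolve by priority rRNA > tRNA > snoRNA > snRNA >
    other_rfam. Unmatched tags keep class 'none'. Matching covers both strands.
    """
    refs = _reference_matcher(ncrna_ref)
    out = []
    for tag in tags:
        hit_classes = {cls for cls, refseq in refs if tag.seq in refseq}
        cls = NcrnaClass.NONE
        for candidate in _CLASS_PRIORITY:
            if candidate in hit_classes:
                cls = candidate
                break
        out.append(SequenceTag(seq=tag.seq, count=tag.count, ncrna_class=cls))
    return out


def annotate_repeats(
    tags: list[SequenceTag], repeat_ref: list[SeqRecord] | None
) -> list[SequenceTag]:
    """Flag tags matching a repeat library; no-op when no library is given."""
    if not repeat_ref:
        return tags
    refs = [r.seq for r in repeat_ref] + [revcomp(r.seq) for r in repeat_ref]
    out = []
    for tag in tags:
        if tag.ncrna_class is NcrnaClass.NONE and any(tag.seq in ref for ref in refs):
            out.append(SequenceTag(tag.seq, tag.count, NcrnaClass.REPEAT))
        else:
            out.append(tag)
    return out


def clean_library(
    reads: list[SeqRecord],
    adapter3: str,
    ncrna_ref: list[SeqRecord],
    repeat_ref: list[SeqRecord] | None = None,
    adapter5: str | None = None,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[list[SequenceTag], LibraryStats]:
    """Full cleaning pass: trim, filter, collapse, annotate; return clean tags
    (ncRNA/repeat tags excluded) plus the library accounting."""
    stats = LibraryStats()
    stats.raw_total = len(reads)
    stats.raw_distinct = len({r.seq for r in reads})

    trimmed: list[SeqRecord] = []
    failed_adapter: list[SeqRecord] = []
    for r in reads:
        t = trim_adapter(r, adapter3, adapter5=adapter5)
        if t is None:
            failed_adapter.append(r)
        else:
            trimmed.append(t)

    kept, removed = filter_reads(trimmed, min_len=min_len, max_len=max_len)
    # adapter failures and length failures share the published accounting row;
    # distinct counts are over raw read sequences so the partition is exact
    failed_len = [r for r in trimmed if not (min_len <= len(r.seq) <= max_len)]
    junk = [r for r in trimmed if (min_len <= len(r.seq) <= max_len) and is_junk(r.seq)]
    stats.adapter_or_length_total = len(failed_adapter) + len(failed_len)
    stats.junk_total = len(junk)

    tags = collapse(kept)
    tags = annotate_ncrna(tags, ncrna_ref)
    tags = annotate_repeats(tags, repeat_ref)

    clean = [t for t in tags if t.ncrna_class is NcrnaClass.NONE]
    rfam = [t for t in tags if t.ncrna_class not in (NcrnaClass.NONE, NcrnaClass.REPEAT)]
    repeats = [t for t in tags if t.ncrna_class is NcrnaClass.REPEAT]

    stats.rfam_total = sum(t.count for t in rfam)
    stats.rfam_distinct = len(rfam)
    stats.repeats_total = sum(t.count for t in repeats)
    stats.repeats_distinct = len(repeats)
    stats.clean_total = sum(t.count for t in clean)
    stats.clean_distinct = len(clean)
    stats.junk_distinct = len({r.seq for r in junk})
    # distinct adapter/length removals: raw distinct minus everything else
    stats.adapter_or_length_distinct = stats.raw_distinct - (
        stats.junk_distinct
        + stats.rfam_distinct
        + stats.repeats_distinct
        + stats.clean_distinct
    )
    for cls in _CLASS_PRIORITY:
        members = [t for t in rfam if t.ncrna_class is cls]
        stats.per_class_total[cls.value] = sum(t.count for t in members)
        stats.per_class_distinct[cls.value] = len(members)
    return clean, stats


def length_distribution(tags: list[SequenceTag]) -> pd.DataFrame:
    """Reads and percent-of-clean-reads per tag length (2-decimal percents)."""
    total = sum(t.count for t in tags)
    per_len: Counter = Counter()
    for t in tags:
        per_len[len(t.seq)] += t.count
    rows = [
        {"length": ln, "reads": n, "percent": percentage(n, total)}
        for ln, n in sorted(per_len.items())
    ]
    return pd.DataFrame(rows, columns=["length", "reads", "percent"])


def stats_report(stats: LibraryStats) -> pd.DataFrame:
    """Library accounting table: type, total, % of raw, distinct, % of raw distinct."""
    rows = [
        ("Raw reads", stats.raw_total, stats.raw_distinct),
        ("3ADT & length filter", stats.adapter_or_length_total, stats.adapter_or_length_distinct),
        ("Junk reads", stats.junk_total, stats.junk_distinct),
        ("Rfam", stats.rfam_total, stats.rfam_distinct),
        ("Repeats", stats.repeats_total, stats.repeats_distinct),
        ("Clean reads", stats.clean_total, stats.clean_distinct),
    ]
    for cls in _CLASS_PRIORITY:
        label = "Other Rfam RNA" if cls is NcrnaClass.OTHER_RFAM else cls.value
        rows.append(
            (
                label,
                stats.per_class_total.get(cls.value, 0),
                stats.per_class_distinct.get(cls.value, 0),
            )
        )
    df = pd.DataFrame(rows, columns=["type", "total", "distinct"])
    df["pct_total"] = [percentage(t, stats.raw_total) for t in df["total"]]
    df["pct_distinct"] = [percentage(d, stats.raw_distinct) for d in df["distinct"]]
    return df[["type", "total", "pct_total", "distinct", "pct_distinct"]]


def write_clean_tags(tags: list[SequenceTag], path: str | Path) -> None:
    df = pd.DataFrame(
        [(t.seq, t.count, t.ncrna_class.value) for t in tags],
        columns=["seq", "count", "ncrna_class"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_clean_tags(path: str | Path) -> list[SequenceTag]:
    df = pd.read_csv(path, sep="\t")
    return [
        SequenceTag(seq=r.seq, count=int(r.count), ncrna_class=NcrnaClass(r.ncrna_class))
        for r in df.itertuples()
    ]
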