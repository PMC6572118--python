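"""Conservation classification, naming, and family summaries.

A candidate with a validated precursor is "conserved" when its mature is
within 3 mismatches of a known plant mature miRNA, otherwise "non-conserved"
(novel). High-abundance tags without a recoverable precursor are accepted as
conserved only on a perfect reference match (precursors often cannot be found
when only a transcriptome, not a genome, is available).

Mismatch distance between unequal-length sequences is a shifted Hamming
distance: the reference is slid by up to +-2 positions and overhanging
nucleotides count as mismatches.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .io_formats import SeqRecord, load_family_registry

MAX_MISMATCHES = 3
MAX_SHIFT = 2

_FAMILY_RE = re.compile(r"miR[N]?(\d+)", re.IGNORECASE)


class MirnaClass(str, Enum):
    CONSERVED_PRECURSOR = "conserved_precursor"
    CONSERVED_NO_PRECURSOR = "conserved_no_precursor"
    NON_CONSERVED = "non_conserved"


@dataclass
class MirnaRecord:
    name: str
    mature_seq: str
    mirna_class: MirnaClass
    family: str
    homolog_id: str = ""
    homolog_mismatches: int | None = None
    reads: int = 0
    precursor_ids: list[str] = field(default_factory=list)

    @property
    def length_nt(self) -> int:
        return len(self.mature_seq)


@dataclass
class FamilySummary:
    family: str
    n_distinct_matures: int
    total_reads: int


def shifted_hamming(a: str, b: str, max_shift: int = MAX_SHIFT) -> int:
    """Minimum mismatch count over relative shifts of |shift| <= max_shift.

    Overlap positions are compared Hamming-style; nucleotides of either
    sequence overhanging the overlap each count as one mismatch. Symmetric in
    its arguments and 0 iff a == b.
    """
    best = len(a) + len(b)
    for shift in range(-max_shift, max_shift + 1):
        # b[i] is compared against a[i + shift]
        lo = max(0, -shift)
        hi = min(len(b), len(a) - shift)
        if hi <= lo:
            continue
        overlap = hi - lo
        mm = sum(1 for i in range(lo, hi) if b[i] != a[i + shift])
        mm += (len(a) - overlap) + (len(b) - overlap)
        best = min(best, mm)
    return best


def match_reference(
    mature_seq: str,
    reference: list[SeqRecord],
    max_mm: int = MAX_MISMATCHES,
) -> tuple[str, int] | None:
    """Best reference homolog within max_mm shifted-Hamming mismatches.

    Ties resolve to the lexicographically first reference id; None when no
    reference is close enough.
    """
    if not reference:
        raise ValueError("empty mature miRNA reference")
    best: tuple[int, str] | None = None
    for ref in reference:
        d = shifted_hamming(mature_seq, ref.seq)
        if best is None or (d, ref.id) < best:
            best = (d, ref.id)
    if best is None or best[0] > max_mm:
        return None
    return best[1], best[0]


def classify_mirna(
    mature_seq: str,
    has_precursor: bool,
    reference: list[SeqRecord],
    max_mm: int = MAX_MISMATCHES,
) -> tuple[MirnaClass | None, str, int | None]:
    """Class assignment; returns (class, homolog_id, mismatches).

    Candidates without a precursor and without a perfect reference match are
    unclassifiable and return class None.
    """
    hit = match_reference(mature_seq, reference, max_mm=max_mm)
    if has_precursor:
        if hit is not None:
            return MirnaClass.CONSERVED_PRECURSOR, hit[0], hit[1]
        return MirnaClass.NON_CONSERVED, "", None
    if hit is not None and hit[1] == 0:
        return MirnaClass.CONSERVED_NO_PRECURSOR, hit[0], 0
    return None, "", None


def assign_family(homolog_id: str | None, registry: dict[str, str] | None = None) -> str:
    """Family label for a homolog id; 'novel' for records without a homolog.

    The packaged registry resolves ids whose family label is not derivable
    from the name (e.g. miR319 homologs belong to MIR159); unknown ids fall
    back to parsing the numeric family from the id.
    """
    if not homolog_id:
        return "novel"
    if registry is None:
        registry = load_family_registry()
    if homolog_id in registry:
        return registry[homolog_id]
    m = _FAMILY_RE.search(homolog_id)
    if m:
        return f"MIR{m.group(1)}"
    return "unknown"


_NOVEL_NAME_RE = re.compile(r"^(.*miRN)-?(\d+)$")


def canonical_name(name: str) -> str:
    """Novel-miRNA names are matched hyphen-insensitively (miRN-2 == miRN2)."""
    m = _NOVEL_NAME_RE.match(name)
    if m:
        return f"{m.group(1)}-{m.group(2)}"
    return name


def name_records(records: list[MirnaRecord], prefix: str = "ame") -> list[MirnaRecord]:
    """Assign names: conserved records get <prefix>-miR<fam#>-k per family by
    descending reads; novel records get <prefix>-miRN-k globally by descending
    reads. Ties break on sequence so naming is input-order independent."""
    conserved = [r for r in records if r.mirna_class is not MirnaClass.NON_CONSERVED]
    novel = [r for r in records if r.mirna_class is MirnaClass.NON_CONSERVED]

    by_family: dict[str, list[MirnaRecord]] = defaultdict(list)
    for r in conserved:
        by_family[r.family].append(r)
    for family, members in by_family.items():
        fam_num = re.sub(r"^MIR", "", family).split("_")[0]
        members.sort(key=lambda r: (-r.reads, r.mature_seq))
        for k, r in enumerate(members, start=1):
            r.name = f"{prefix}-miR{fam_num}-{k}"

    novel.sort(key=lambda r: (-r.reads, r.mature_seq))
    for k, r in enumerate(novel, start=1):
        r.name = f"{prefix}-miRN-{k}"
    return sorted(records, key=lambda r: r.name)


def family_summaries(records: list[MirnaRecord]) -> list[FamilySummary]:
    """Per-family distinct-mature counts and read totals, by reads descending."""
    grouped: dict[str, list[MirnaRecord]] = defaultdict(list)
    for r in records:
        grouped[r.family].append(r)
    out = [
        FamilySummary(
            family=f,
            n_distinct_matures=len({r.mature_seq for r in members}),
            total_reads=sum(r.reads for r in members),
        )
        for f, members in grouped.items()
    ]
    out.sort(key=lambda s: (-s.total_reads, s.family))
    return out


def mfe_summary(precursors: list) -> dict[str, float]:
    """Min/max/mean of MFE and MFE/nt over hairpin candidates (2 decimals)."""
    if not precursors:
        raise ValueError("no precursors to summarize")
    mfes = [p.mfe for p in precursors]
    per_nt = [p.mfe_per_nt for p in precursors]
    return {
        "mfe_min": round(min(mfes), 2),
        "mfe_max": round(max(mfes), 2),
        "mfe_mean": round(sum(mfes) / len(mfes), 2),
        "mfe_per_nt_min": round(min(per_nt), 2),
        "mfe_per_nt_max": round(max(per_nt), 2),
        "mfe_per_nt_mean": round(sum(per_nt) / len(per_nt), 2),
    }


def records_to_frame(records: list[MirnaRecord]) -> pd.DataFrame:
    from .io_formats import to_rna

    return pd.DataFrame(
        [
            {
                "name": r.name,
                "mature_seq": to_rna(r.mature_seq),
                "length_nt": r.length_nt,
                "class": r.mirna_class.value,
                "family": r.family,
                "homolog": r.homolog_id,
                "homolog_mismatches": r.homolog_mismatches,
                "reads": r.reads,
                "precursors": ";".join(r.precursor_ids),
            }
            for r in records
        ]
    )
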