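"""Readers and writers for the external formats the pipeline consumes and emits.

All sequences are stored internally as uppercase DNA (U -> T on input);
human-readable catalog reports render lowercase RNA (t -> u) because mature
miRNA sequences are conventionally printed that way. Coordinates are 0-based
half-open internally and 1-based closed in reports.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# sha256 of the packaged catalog fixtures, guarding against silent edits
_FIXTURE_SHA256 = {
    "table1": "table1_library_stats.tsv",
    "table2": "table2_conserved.tsv",
    "table3": "table3_nonconserved.tsv",
}


class ParseError(ValueError):
    """Malformed FASTA/FASTQ/TSV input."""


class FixtureCorruptionError(RuntimeError):
    """A packaged table fixture does not match its recorded checksum."""


def normalize_seq(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet (T)."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set("ACGTN")
    if bad:
        raise ParseError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def to_rna(seq: str) -> str:
    """Render an internal DNA sequence as lowercase RNA for reports."""
    return seq.lower().replace("t", "u")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named nucleotide sequence (internal DNA alphabet).

    ``quality`` is carried opaquely for FASTQ input and never interpreted.
    ``label`` holds an optional annotation class (e.g. an ncRNA class parsed
    from a reference header).
    """

    id: str
    seq: str
    quality: str | None = None
    label: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class CatalogRow:
    """One row of a miRNA catalog (mirrors the published table layout)."""

    name: str
    mature_seq: str
    length_nt: int
    homolog: str
    reads: int
    family: str

    def __post_init__(self) -> None:
        if self.length_nt != len(self.mature_seq):
            raise ValueError(
                f"{self.name}: declared length {self.length_nt} != "
                f"sequence length {len(self.mature_seq)}"
            )
        if self.reads < 0:
            raise ValueError(f"{self.name}: negative read count")


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords, normalizing to uppercase DNA."""
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: empty sequence for record '{rec.id}'")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id '{rec.id}'")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=normalize_seq(seq)))
    if not records and path.stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records parsed")
    return records


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read a 4-line FASTQ file; qualities are retained but never used."""
    path = Path(path)
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 != 0:
        # allow a single trailing blank line
        if lines and lines[-1] == "":
            lines = lines[:-1]
        if len(lines) % 4 != 0:
            raise ParseError(f"{path}: truncated FASTQ (line count not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ParseError(f"{path}: malformed FASTQ record near line {i + 1}")
        if len(seq) != len(qual):
            raise ParseError(f"{path}: sequence/quality length mismatch at line {i + 1}")
        if not seq:
            raise ParseError(f"{path}: empty sequence at line {i + 1}")
        records.append(SeqRecord(id=head[1:].split()[0], seq=normalize_seq(seq), quality=qual))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality or "I" * len(rec.seq)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def read_labeled_fasta(path: str | Path, sep: str = " ") -> list[SeqRecord]:
    """FASTA whose headers carry a class label after the id (``>id class``)."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(sep, 1)
        label = parts[1].strip() if len(parts) > 1 else None
        records.append(SeqRecord(id=rec.id, seq=normalize_seq(str(rec.seq)), label=label))
    return records


def _fixture_path(which: str) -> Path:
    try:
        fname = _FIXTURE_SHA256[which]
    except KeyError:
        raise ValueError(f"unknown fixture '{which}' (expected table1/table2/table3)")
    return Path(str(resources.files("ame_smallrna.data") / fname))


def _fixture_df(which: str) -> pd.DataFrame:
    path = _fixture_path(which)
    data = path.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = FIXTURE_CHECKSUMS.get(which)
    if expected is not None and digest != expected:
        raise FixtureCorruptionError(
            f"fixture {path.name} checksum {digest[:12]}… != expected {expected[:12]}…"
        )
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def load_catalog_fixture(which: str) -> list[CatalogRow]:
    """Load the packaged conserved (table2) or non-conserved (table3) catalog."""
    if which not in ("table2", "table3"):
        raise ValueError("catalog fixtures are 'table2' and 'table3'")
    df = _fixture_df(which)
    rows = []
    for _, r in df.iterrows():
        rows.append(
            CatalogRow(
                name=r["name"],
                mature_seq=normalize_seq(r["mature_seq"]),
                length_nt=int(r["length_nt"]),
                homolog=r.get("homolog", ""),
                reads=int(r["reads"]),
                family=r.get("family", "novel"),
            )
        )
    return rows


def load_library_stats_fixture() -> pd.DataFrame:
    """The published library accounting table (read totals and percentages)."""
    return _fixture_df("table1")


def load_family_registry() -> dict[str, str]:
    """Packaged mapping from reference miRNA ids to family labels."""
    path = Path(str(resources.files("ame_smallrna.data") / "family_registry.tsv"))
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["homolog_id"], df["family"]))


# Checksums are over the raw fixture bytes; regenerate with
#   python -c "import hashlib,sys;print(hashlib.sha256(open(sys.argv[1],'rb').read()).hexdigest())"
FIXTURE_CHECKSUMS: dict[str, str] = {
    "table1": "31ba325454c974fa3197d8777a16fdbf48d6ed1510cba6138637e2400b9573fd",
    "table2": "17410ac0a81cebf63c152e5f1633a9054fa2cd1fb32c626db85fb0c03e7983db",
    "table3": "d641a55f97e5f035ef5da03a78f930df3a055bf90280544372e222e0d27f9ab3",
}
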