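"""Synthetic small-RNA study generator with a machine-readable truth ledger.

Emulates the statistical structure of a plant small-RNA sequencing library:
miRNA hairpins planted in a transcriptome (mature read counts far above star
counts), a TAS3-like locus with two trigger-complementary sites flanking a
21-nt phased siRNA region, ncRNA contaminants drawn from a labeled reference,
degradation noise (random transcript fragments), a 3' sequencing adapter on
every read, and qRT-PCR Ct tables with planted fold changes. Read counts are
emitted exactly (not sampled) by default so downstream assertions can be
equalities; every read traces to a ledger entry or the declared noise
fraction.

All generators are pure functions of their parameters and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import evaluate_hairpin
from .io_formats import SeqRecord, revcomp, write_fasta, write_fastq
from .preprocess import is_junk

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter
NUCS = np.array(list("ACGT"))


@dataclass
class PlantedMirna:
    name: str
    mature: str
    star: str
    transcript_id: str  # empty for matures planted without a precursor
    mature_start: int
    intended_class: str  # conserved_precursor | conserved_no_precursor | non_conserved
    intended_family: str
    homolog_id: str
    homolog_mismatches: int
    reads: int
    star_reads: int


@dataclass
class PlantedTas:
    transcript_id: str
    site5_start: int
    site3_start: int
    cleavage_origin: int
    phase_length: int
    phasirnas: list[tuple[str, int, int]]  # (seq, count, phase_index)


@dataclass
class PlantedContaminant:
    ncrna_class: str
    seq: str
    count: int


@dataclass
class PlantedCtEffect:
    gene: str
    condition: str
    true_log2_fold: float
    sigma: float


@dataclass
class TruthLedger:
    mirnas: list[PlantedMirna] = field(default_factory=list)
    tas_loci: list[PlantedTas] = field(default_factory=list)
    contaminants: list[PlantedContaminant] = field(default_factory=list)
    ct_effects: list[PlantedCtEffect] = field(default_factory=list)
    noise_reads: int = 0

    def planted_read_total(self) -> int:
        total = sum(m.reads + m.star_reads for m in self.mirnas)
        total += sum(c for t in self.tas_loci for _, c, _ in t.phasirnas)
        total += sum(c.count for c in self.contaminants)
        return total

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.mirnas:
            rows.append(
                {"kind": "mirna", "name": m.name, "seq": m.mature,
                 "count": m.reads, "detail": m.intended_class,
                 "locus": f"{m.transcript_id}:{m.mature_start}"}
            )
        for t in self.tas_loci:
            for seq, count, idx in t.phasirnas:
                rows.append(
                    {"kind": "phasirna", "name": f"phase_{idx}", "seq": seq,
                     "count": count, "detail": str(idx),
                     "locus": t.transcript_id}
                )
        for c in self.contaminants:
            rows.append(
                {"kind": "contaminant", "name": c.ncrna_class, "seq": c.seq,
                 "count": c.count, "detail": c.ncrna_class, "locus": ""}
            )
        for e in self.ct_effects:
            rows.append(
                {"kind": "ct_effect", "name": e.gene, "seq": "",
                 "count": 0, "detail": f"{e.condition}:{e.true_log2_fold}",
                 "locus": ""}
            )
        rows.append({"kind": "noise", "name": "noise", "seq": "",
                     "count": self.noise_reads, "detail": "", "locus": ""})
        return pd.DataFrame(rows)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(NUCS, size=n))


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Substitute n_mut interior positions with different nucleotides."""
    s = list(seq)
    if n_mut == 0:
        return seq
    positions = rng.choice(np.arange(2, len(s) - 2), size=n_mut, replace=False)
    for p in positions:
        choices = [c for c in "ACGT" if c != s[p]]
        s[p] = choices[rng.integers(len(choices))]
    return "".join(s)


def _build_hairpin(
    rng: np.random.Generator, duplex_mismatches: int
) -> tuple[str, str, str, int]:
    """(precursor, mature, star_by_geometry, mature_offset_in_precursor).

    mature on the 5' arm, loop 10-14 nt, star = reverse complement of the
    mature (with the requested duplex mismatches); 2 random overhang
    nucleotides close the 3' end. The true star (2-nt 3' overhang) is
    recomputed from the fold by the caller.
    """
    mlen = int(rng.integers(20, 23))
    mature = _random_seq(rng, mlen)
    loop = _random_seq(rng, int(rng.integers(10, 15)))
    star_core = _mutate(rng, revcomp(mature), duplex_mismatches)
    lead = _random_seq(rng, 6)
    tail = _random_seq(rng, 2)
    precursor = lead + mature + loop + star_core + tail
    return precursor, mature, star_core, len(lead)


def generate_transcriptome(
    n_transcripts: int = 24,
    length_range: tuple[int, int] = (500, 800),
    n_hairpins: int = 20,
    seed: int = 0,
    duplex_mismatches: int = 0,
    n_conserved: int | None = None,
    n_no_precursor: int = 4,
    max_retries: int = 80,
) -> tuple[list[SeqRecord], list[SeqRecord], TruthLedger]:
    """Transcriptome with planted miRNA hairpins plus a matching mature-miRNA
    reference set.

    Returns (transcripts, reference_matures, ledger). The first n_conserved
    planted hairpins (default: half) carry a reference homolog within 0-3
    mismatches; the rest have none within 3 (novel). n_no_precursor additional
    matures are listed in the ledger and reference but planted in no
    transcript, emulating conserved miRNAs whose precursor is unrecoverable
    from a transcriptome-only reference.
    """
    rng = np.random.default_rng(seed)
    if n_conserved is None:
        n_conserved = n_hairpins // 2
    if n_conserved > n_hairpins:
        raise ValueError("n_conserved cannot exceed n_hairpins")

    transcripts: list[SeqRecord] = []
    ledger = TruthLedger()
    reference: list[SeqRecord] = []
    matures_seen: set[str] = set()

    lo, hi = length_range
    margin = 210  # keeps every excision window untruncated

    for i in range(n_transcripts):
        tlen = int(rng.integers(lo, hi + 1))
        tid = f"synth_t{i + 1:03d}"
        if i < n_hairpins:
            for _ in range(max_retries):
                precursor, mature, _star_core, m_in_pre = _build_hairpin(
                    rng, duplex_mismatches
                )
                if is_junk(mature) or mature in matures_seen:
                    continue
                pos_max = tlen - margin - len(precursor)
                if pos_max <= margin:
                    tlen = len(precursor) + 2 * margin + 50
                    pos_max = tlen - margin - len(precursor)
                pre_start = int(rng.integers(margin, pos_max + 1))
                left = _random_seq(rng, pre_start)
                right = _random_seq(rng, tlen - pre_start - len(precursor))
                seq = left + precursor + right
                m_start = pre_start + m_in_pre
                # validate the hairpin in its final context on the 50-nt window
                w0 = m_start - 50
                w1 = m_start + len(mature) + 50
                cand = evaluate_hairpin(seq[w0:w1], 50, len(mature))
                if not cand.verdict:
                    continue
                # plus strand: the planted locus only; minus strand: at most
                # the star arm (a perfect duplex is its own reverse complement)
                if seq.count(mature) != 1 or revcomp(seq).count(mature) > 1:
                    continue
                break
            else:
                raise RuntimeError("failed to plant a canonical hairpin")
            matures_seen.add(mature)
            conserved = i < n_conserved
            mm = int(rng.integers(0, 4)) if conserved else 0
            name = f"planted-{i + 1}"
            fam_num = 9000 + i
            if conserved:
                homolog_seq = _mutate(rng, mature, mm)
                hom_id = f"syn-miR{fam_num}a"
                reference.append(SeqRecord(id=hom_id, seq=homolog_seq))
                family = f"MIR{fam_num}"
            else:
                hom_id, family, mm = "", "novel", -1
            reads = int(rng.integers(20, 3000))
            ledger.mirnas.append(
                PlantedMirna(
                    name=name, mature=mature, star=cand.star_seq,
                    transcript_id=tid, mature_start=m_start,
                    intended_class=(
                        "conserved_precursor" if conserved else "non_conserved"
                    ),
                    intended_family=family, homolog_id=hom_id,
                    homolog_mismatches=mm, reads=reads,
                    star_reads=max(1, round(0.05 * reads)),
                )
            )
            transcripts.append(SeqRecord(id=tid, seq=seq))
        else:
            transcripts.append(SeqRecord(id=tid, seq=_random_seq(rng, tlen)))

    # conserved matures without a recoverable precursor: in the reference and
    # the read pool, absent from every transcript
    for j in range(n_no_precursor):
        for _ in range(max_retries):
            mature = _random_seq(rng, int(rng.integers(20, 23)))
            if is_junk(mature) or mature in matures_seen:
                continue
            if any(mature in t.seq or mature in revcomp(t.seq) for t in transcripts):
                continue
            break
        else:
            raise RuntimeError("failed to draw a non-mapping mature")
        matures_seen.add(mature)
        fam_num = 9500 + j
        hom_id = f"syn-miR{fam_num}a"
        reference.append(SeqRecord(id=hom_id, seq=mature))
        reads = int(rng.integers(50, 2000))
        ledger.mirnas.append(
            PlantedMirna(
                name=f"planted-np-{j + 1}", mature=mature, star="",
                transcript_id="", mature_start=-1,
                intended_class="conserved_no_precursor",
                intended_family=f"MIR{fam_num}", homolog_id=hom_id,
                homolog_mismatches=0, reads=reads, star_reads=0,
            )
        )

    # novel matures must really have no reference neighbor within 3 mismatches
    from .classify import shifted_hamming

    for m in ledger.mirnas:
        if m.intended_class == "non_conserved":
            assert all(shifted_hamming(m.mature, r.seq) > 3 for r in reference)
    return transcripts, reference, ledger


def generate_ncrna_reference(seed: int = 0) -> list[SeqRecord]:
    """Small labeled ncRNA reference (two records per Rfam-style class)."""
    rng = np.random.default_rng(seed + 101)
    records = []
    for cls, length in (("rRNA", 220), ("tRNA", 80), ("snoRNA", 130),
                        ("snRNA", 160), ("other_rfam", 110)):
        for k in (1, 2):
            records.append(
                SeqRecord(id=f"{cls}_{k}", seq=_random_seq(rng, length), label=cls)
            )
    return records


def simulate_tas_locus(
    trigger_seq: str,
    n_phases: int = 8,
    counts: list[int] | None = None,
    seed: int = 0,
    phase_length: int = 21,
    transcript_id: str = "synth_tas1",
) -> tuple[SeqRecord, PlantedTas]:
    """A TAS3-like transcript: a non-cleavable upstream trigger site (one
    central mismatch, opposite trigger position 10) and a perfect downstream
    site, with n_phases in-register phasiRNA windows walking 5'-ward from the
    downstream cleavage point."""
    rng = np.random.default_rng(seed + 202)
    if counts is None:
        counts = [104, 77] + [30] * max(0, n_phases - 2)
    if len(counts) != n_phases:
        raise ValueError("counts must have n_phases entries")
    n = len(trigger_seq)
    site3 = revcomp(trigger_seq)
    # upstream site: mismatch opposite trigger position 10 -> mutate the
    # complementary site nucleotide at index n-10
    s5 = list(site3)
    idx = n - 10
    s5[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s5[idx]]
    site5 = "".join(s5)

    filler = _random_seq(rng, phase_length * n_phases + 9)
    bg1, bg2 = _random_seq(rng, 150), _random_seq(rng, 150)
    seq = bg1 + site5 + filler + site3 + bg2
    site5_start = len(bg1)
    site3_start = len(bg1) + n + len(filler)
    origin = site3_start + n - 10  # cut opposite trigger positions 10/11

    phasirnas = []
    for k in range(1, n_phases + 1):
        s = origin - phase_length * k
        phasirnas.append((seq[s : s + phase_length], counts[k - 1], k))
    tas = PlantedTas(
        transcript_id=transcript_id,
        site5_start=site5_start,
        site3_start=site3_start,
        cleavage_origin=origin,
        phase_length=phase_length,
        phasirnas=phasirnas,
    )
    return SeqRecord(id=transcript_id, seq=seq), tas


def simulate_reads(
    ledger: TruthLedger,
    transcripts: list[SeqRecord],
    ncrna_ref: list[SeqRecord] | None = None,
    depth: int = 1,
    noise_frac: float = 0.0,
    adapter: str | None = DEFAULT_ADAPTER,
    contaminant_reads: int = 0,
    seed: int = 0,
) -> list[SeqRecord]:
    """Emit the library as FASTQ-ready records, counts exact (times ``depth``).

    Contaminant reads are 18-25 nt windows of the ncRNA reference; noise reads
    are 18-25 nt windows of random transcripts, noise_frac of the planted
    total. ``adapter=None`` emits inserts without a 3' adapter (every read is
    then rejected by trimming, as for adapter-free libraries).
    """
    rng = np.random.default_rng(seed + 303)
    reads: list[SeqRecord] = []
    serial = 0

    def emit(seq: str, count: int, tag: str) -> None:
        nonlocal serial
        full = seq + adapter if adapter else seq
        for _ in range(count * depth):
            serial += 1
            reads.append(SeqRecord(id=f"r{serial}_{tag}", seq=full))

    for m in ledger.mirnas:
        emit(m.mature, m.reads, "mat")
        if m.star and m.star_reads:
            emit(m.star, m.star_reads, "star")
    for t in ledger.tas_loci:
        for seq, count, idx in t.phasirnas:
            emit(seq, count, f"ph{idx}")

    if contaminant_reads and ncrna_ref:
        per_rec = max(1, contaminant_reads // len(ncrna_ref))
        for rec in ncrna_ref:
            for _ in range(per_rec):
                ln = int(rng.integers(18, 26))
                start = int(rng.integers(0, len(rec.seq) - ln + 1))
                frag = rec.seq[start : start + ln]
                ledger.contaminants.append(
                    PlantedContaminant(rec.label or "other_rfam", frag, 1)
                )
                emit(frag, 1, "nc")

    planted = ledger.planted_read_total()
    n_noise = round(noise_frac * planted)
    ledger.noise_reads = n_noise * depth
    for _ in range(n_noise):
        tr = transcripts[int(rng.integers(len(transcripts)))]
        ln = int(rng.integers(18, 26))
        start = int(rng.integers(0, len(tr.seq) - ln + 1))
        emit(tr.seq[start : start + ln], 1, "noise")
    return reads


def simulate_ct_table(
    effects: list[PlantedCtEffect],
    reference_gene: str = "U6",
    control_condition: str = "0h",
    n_replicates: int = 3,
    seed: int = 0,
    baseline_range: tuple[float, float] = (22.0, 28.0),
    reference_ct: float = 18.0,
    reference_sigma: float | None = None,
) -> pd.DataFrame:
    """Ct table with planted fold changes: Ct = baseline - log2(fold) + noise.

    The reference gene is constant across conditions up to its own noise
    (``reference_sigma``; defaults to the first gene's sigma). Because the
    reference measurement is shared by every gene in a replicate, its noise
    correlates the per-gene estimates; pass ``reference_sigma=0.0`` for
    experiments that need independent per-gene errors. Every gene appearing
    in ``effects`` is also measured in the control condition at its baseline.
    """
    rng = np.random.default_rng(seed + 404)
    genes = sorted({e.gene for e in effects})
    conditions = [control_condition] + sorted(
        {e.condition for e in effects} - {control_condition}
    )
    sigma_by_gene = {e.gene: e.sigma for e in effects}
    ref_sigma = (
        reference_sigma if reference_sigma is not None else sigma_by_gene[genes[0]]
    )
    effect_map = {(e.gene, e.condition): e.true_log2_fold for e in effects}
    baselines = {g: float(rng.uniform(*baseline_range)) for g in genes}

    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for g in genes:
                sigma = sigma_by_gene[g]
                lf = effect_map.get((g, cond), 0.0)
                noise = float(rng.normal(0, sigma)) if sigma > 0 else 0.0
                rows.append(
                    {"gene": g, "condition": cond, "replicate": rep,
                     "ct": baselines[g] - lf + noise}
                )
            ref_noise = float(rng.normal(0, ref_sigma)) if ref_sigma > 0 else 0.0
            rows.append(
                {"gene": reference_gene, "condition": cond, "replicate": rep,
                 "ct": reference_ct + ref_noise}
            )
    return pd.DataFrame(rows)


def cold_panel(
    n_up_conserved: int = 4,
    n_down_conserved: int = 17,
    n_up_novel: int = 6,
    n_ns_conserved: int = 1,
    conditions: tuple[str, ...] = ("3h", "6h", "24h", "72h"),
    effect_log2: float = 2.0,
    sigma: float = 0.1,
) -> tuple[list[PlantedCtEffect], dict[str, str]]:
    """The cold-stress qPCR panel emulating the headline study design:
    cold-induced and cold-repressed conserved miRNAs plus cold-induced
    non-conserved miRNAs, each responsive at every cold timepoint."""
    effects: list[PlantedCtEffect] = []
    classes: dict[str, str] = {}

    def add(gene: str, lf: float, cls: str) -> None:
        classes[gene] = cls
        for cond in conditions:
            effects.append(PlantedCtEffect(gene, cond, lf, sigma))

    for i in range(n_up_conserved):
        add(f"cons-up-{i + 1}", effect_log2, "conserved")
    for i in range(n_down_conserved):
        add(f"cons-down-{i + 1}", -effect_log2, "conserved")
    for i in range(n_ns_conserved):
        add(f"cons-ns-{i + 1}", 0.0, "conserved")
    for i in range(n_up_novel):
        add(f"novel-up-{i + 1}", effect_log2, "non_conserved")
    return effects, classes


def simulate_bundle(
    out_dir: str | Path,
    seed: int = 0,
    n_transcripts: int = 24,
    n_hairpins: int = 20,
    noise_frac: float = 0.0,
    contaminant_reads: int = 200,
    trigger_seq: str = "AAGCTCAGGAGGGATAGCGCC",
    adapter: str = DEFAULT_ADAPTER,
) -> dict[str, Path]:
    """Generate the full study bundle on disk: transcriptome.fasta,
    reads.fastq, ncrna.fasta, mature_ref.fasta, ct_table.tsv, truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transcripts, reference, ledger = generate_transcriptome(
        n_transcripts=n_transcripts, n_hairpins=n_hairpins, seed=seed
    )
    tas_tr, tas = simulate_tas_locus(trigger_seq.upper().replace("U", "T"), seed=seed)
    transcripts.append(tas_tr)
    ledger.tas_loci.append(tas)
    ncrna = generate_ncrna_reference(seed=seed)
    reads = simulate_reads(
        ledger, transcripts, ncrna_ref=ncrna, noise_frac=noise_frac,
        contaminant_reads=contaminant_reads, adapter=adapter, seed=seed,
    )

    effects, classes = cold_panel()
    ct = simulate_ct_table(effects, seed=seed)
    for e in effects:
        ledger.ct_effects.append(e)

    paths = {
        "transcriptome": out / "transcriptome.fasta",
        "reads": out / "reads.fastq",
        "ncrna": out / "ncrna.fasta",
        "mature_ref": out / "mature_ref.fasta",
        "ct_table": out / "ct_table.tsv",
        "truth": out / "truth.tsv",
        "classes": out / "panel_classes.tsv",
    }
    write_fasta(transcripts, paths["transcriptome"])
    write_fastq(reads, paths["reads"])
    with open(paths["ncrna"], "w") as fh:
        for rec in ncrna:
            fh.write(f">{rec.id} {rec.label}\n{rec.seq}\n")
    write_fasta(reference, paths["mature_ref"])
    ct.to_csv(paths["ct_table"], sep="\t", index=False)
    ledger.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    pd.DataFrame(
        [{"gene": g, "class": c} for g, c in classes.items()]
    ).to_csv(paths["classes"], sep="\t", index=False)
    return paths
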