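"""End-to-end orchestration: cleaning -> discovery -> classification ->
targets -> phasing (-> expression), with report tables and a run manifest.

Each stage communicates through declared files only, so any stage can be
re-run from the previous stage's outputs. Re-running with the same config is
bit-identical. Biologically empty results (no reads, no candidates) are
warnings, not errors; only I/O and configuration problems fail the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify as cl
from . import discovery as disc
from . import expression as expr
from . import phasing as ph
from . import preprocess as pp
from . import targets as tg
from .io_formats import (
    SeqRecord,
    read_fasta,
    read_fastq,
    read_labeled_fasta,
    to_rna,
)

log = logging.getLogger("ame_smallrna")

DEFAULT_TRIGGER = "AAGCTCAGGAGGGATAGCGCC"  # miR390 mature, DNA alphabet


@dataclass
class PipelineConfig:
    reads: str = ""
    transcriptome: str = ""
    ncrna_ref: str = ""
    mature_ref: str = ""
    repeat_ref: str = ""
    ct_table: str = ""
    out_dir: str = "out"
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = ""
    min_len: int = 18
    max_len: int = 25
    max_loci: int = 20
    flank_set: tuple[int, ...] = (20, 50, 100, 150, 200)
    max_mismatches: int = 3
    min_reads_discovery: int = 1
    min_reads_no_precursor: int = 5
    expectation_cutoff: float = 3.0
    trigger_seq: str = DEFAULT_TRIGGER
    phase_length: int = 21
    reference_gene: str = "U6"
    control_condition: str = "0h"
    seed: int = 0
    name_prefix: str = "ame"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "flank_set" in data:
            data["flank_set"] = tuple(data["flank_set"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["flank_set"] = list(self.flank_set)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _load_reads(path: str) -> list[SeqRecord]:
    if path.endswith((".fa", ".fasta", ".fna")):
        return read_fasta(path)
    return read_fastq(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a manifest dict (also written to the out dir)."""
    out = Path(config.out_dir)
    for name in ("reads", "transcriptome", "ncrna_ref", "mature_ref"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"required input '{name}' missing: {p!r}")
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"parameters": {"seed": config.seed}, "stages": {}}

    reads = _load_reads(config.reads)
    ncrna = read_labeled_fasta(config.ncrna_ref)
    repeat_ref = read_fasta(config.repeat_ref) if config.repeat_ref else None
    transcripts = read_fasta(config.transcriptome)
    reference = read_fasta(config.mature_ref)

    # --- clean ---
    clean_tags, stats = pp.clean_library(
        reads, config.adapter3, ncrna, repeat_ref=repeat_ref,
        adapter5=config.adapter5 or None,
        min_len=config.min_len, max_len=config.max_len,
    )
    if not stats.conserved():
        raise AssertionError("library accounting does not partition raw reads")
    pp.write_clean_tags(clean_tags, out / "clean_tags.tsv")
    pp.stats_report(stats).to_csv(out / "library_stats.tsv", sep="\t", index=False)
    pp.length_distribution(clean_tags).to_csv(
        out / "length_dist.tsv", sep="\t", index=False
    )
    manifest["stages"]["clean"] = {
        "raw_reads": stats.raw_total,
        "clean_reads": stats.clean_total,
        "clean_distinct": stats.clean_distinct,
    }
    if stats.raw_total == 0:
        log.warning("empty read input: downstream catalogs will be empty")

    # --- discover ---
    best, discarded = disc.discover_mirnas(
        clean_tags, transcripts,
        max_loci=config.max_loci, flank_set=config.flank_set,
        min_reads=config.min_reads_discovery,
    )
    pd.DataFrame({"seq": discarded}).to_csv(
        out / "discarded_overmapped.tsv", sep="\t", index=False
    )
    hp_rows = [
        {
            "mature_seq": to_rna(m), "transcript": c.transcript_id,
            "window_start": c.window_start + 1,  # 1-based in reports
            "precursor_len": len(c.precursor_seq),
            "mfe": round(c.mfe, 2), "mfe_per_nt": round(c.mfe_per_nt, 4),
            "arm": c.arm, "star_seq": to_rna(c.star_seq),
            "star_reads": c.star_reads, "structure": c.structure,
        }
        for m, c in sorted(best.items())
    ]
    pd.DataFrame(hp_rows).to_csv(out / "hairpins.tsv", sep="\t", index=False)
    manifest["stages"]["discover"] = {
        "passing_matures": len(best), "overmapped_tags": len(discarded),
    }

    # --- classify ---
    tag_counts = {t.seq: t.count for t in clean_tags}
    records: list[cl.MirnaRecord] = []
    for mature, cand in best.items():
        mclass, hom, mm = cl.classify_mirna(
            mature, True, reference, max_mm=config.max_mismatches
        )
        records.append(
            cl.MirnaRecord(
                name="", mature_seq=mature, mirna_class=mclass,
                family=cl.assign_family(hom),
                homolog_id=hom, homolog_mismatches=mm,
                reads=tag_counts.get(mature, 0),
                precursor_ids=[f"{cand.transcript_id}:{cand.window_start + 1}"],
            )
        )
    known = {r.mature_seq for r in records}
    for tag in clean_tags:
        if tag.seq in known or tag.count < config.min_reads_no_precursor:
            continue
        mclass, hom, mm = cl.classify_mirna(
            tag.seq, False, reference, max_mm=config.max_mismatches
        )
        if mclass is None:
            continue
        records.append(
            cl.MirnaRecord(
                name="", mature_seq=tag.seq, mirna_class=mclass,
                family=cl.assign_family(hom), homolog_id=hom,
                homolog_mismatches=mm, reads=tag.count,
            )
        )
    records = cl.name_records(records, prefix=config.name_prefix)
    catalog = cl.records_to_frame(records)
    catalog.to_csv(out / "catalog.tsv", sep="\t", index=False)
    fam = cl.family_summaries(records)
    pd.DataFrame(
        [
            {"family": s.family, "n_distinct": s.n_distinct_matures,
             "total_reads": s.total_reads}
            for s in fam
        ]
    ).to_csv(out / "family_summary.tsv", sep="\t", index=False)
    manifest["stages"]["classify"] = {
        "catalog_size": len(records),
        "conserved_precursor": sum(
            r.mirna_class is cl.MirnaClass.CONSERVED_PRECURSOR for r in records
        ),
        "conserved_no_precursor": sum(
            r.mirna_class is cl.MirnaClass.CONSERVED_NO_PRECURSOR for r in records
        ),
        "non_conserved": sum(
            r.mirna_class is cl.MirnaClass.NON_CONSERVED for r in records
        ),
    }

    # --- targets ---
    params = tg.ScoringParams(expectation_cutoff=config.expectation_cutoff)
    target_rows = []
    for r in records:
        for h in tg.scan_transcriptome(r.name, r.mature_seq, transcripts, params):
            target_rows.append(
                {
                    "mirna": h.mirna_name, "transcript": h.transcript_id,
                    "start": h.t_start + 1, "end": h.t_end,
                    "expectation": h.expectation,
                    "seed_mm": h.seed_mismatches,
                    "mechanism": h.mechanism, "alignment": h.alignment,
                }
            )
    pd.DataFrame(target_rows).to_csv(out / "targets.tsv", sep="\t", index=False)
    manifest["stages"]["targets"] = {"n_hits": len(target_rows)}

    # --- phasing ---
    trigger = config.trigger_seq.upper().replace("U", "T")
    loci, flagged = ph.detect_tas_loci(
        transcripts, trigger, phase_length=config.phase_length
    )
    tr_map = {t.id: t for t in transcripts}
    tas_rows = []
    for locus in loci:
        tr = tr_map[locus.transcript_id]
        locus = ph.extract_phasirnas(locus, clean_tags, tr)
        score = ph.phase_score(locus, clean_tags, tr)
        for p in locus.phasirnas:
            tas_rows.append(
                {
                    "transcript": locus.transcript_id,
                    "phase_index": p.phase_index, "strand": p.strand,
                    "seq": to_rna(p.seq), "count": p.count,
                    "start": p.start + 1,
                    "phase_score": "NA" if score is None else round(score, 4),
                }
            )
    pd.DataFrame(tas_rows).to_csv(out / "tas_loci.tsv", sep="\t", index=False)
    manifest["stages"]["phasing"] = {
        "n_loci": len(loci), "flagged_multisite": flagged,
        "n_phasirnas": len(tas_rows),
    }

    # --- expression (optional) ---
    if config.ct_table:
        ct = expr.read_ct_table(config.ct_table)
        genes = sorted(set(ct.gene) - {config.reference_gene})
        report = expr.expression_report(
            ct, genes, config.reference_gene, config.control_condition
        )
        report.to_csv(out / "expression_calls.tsv", sep="\t", index=False)
        manifest["stages"]["expression"] = {
            "n_genes": len(genes),
            "n_responsive": int(
                report.groupby("gene")["call"].apply(lambda c: (c != "ns").any()).sum()
            ),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
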