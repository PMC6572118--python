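# ame-smallrna

Small-RNA sequencing analysis for plants: miRNA discovery from a reference
transcriptome, conservation classification, target prediction, TAS3
phasiRNA detection, and qRT-PCR relative quantification (2^-ΔΔCt) — plus a
fully specified synthetic-data generator with a machine-readable truth
ledger, so every stage can be validated end to end.

The package is built around the analysis design used for *Astragalus
membranaceus* (an important medicinal legume) cold-stress studies, and ships
the resulting miRNA catalogs as fixtures: 69 conserved miRNAs in 25
families, 14 non-conserved miRNAs, and the library accounting table they
were derived from. These fixtures anchor the worked examples and the
acceptance suite.

## Science overview

A plant small-RNA library is a mixture of miRNAs, phased siRNAs, ncRNA
fragments, and degradation products. The pipeline separates them with the
standard evidence chain:

1. **Preprocess** — trim the 3' sequencing adapter (reads without it are
   dropped), keep 18–25 nt inserts, remove junk reads (N's, near-homopolymers,
   poly-A), collapse to distinct tags with counts, and annotate tags matching
   rRNA/tRNA/snoRNA/snRNA references. The output is an accounting table whose
   rows exactly partition the raw reads.
2. **Discovery** — map tags exactly to the transcriptome (both strands; tags
   hitting more than 20 loci are discarded as repeats), excise candidate
   precursor windows at five flank sizes, fold them (RNAfold), and apply plant
   miRNA hairpin criteria: mature entirely in one arm, ≤ 4 unpaired mature
   positions in the miRNA/miRNA* duplex, ≤ 2 asymmetric bulges with ≤ 3 bulged
   nucleotides, minimum free energy ≤ −0.19 kcal/mol/nt, precursor 60–300 nt.
   The star sequence is read off the fold with the canonical 2-nt 3' overhang.
3. **Classification** — compare each mature against a reference set of known
   plant miRNAs under a shifted-Hamming distance (alignment shifts up to ±2,
   overhangs count as mismatches). With a hairpin and ≤ 3 mismatches →
   *conserved*; with a hairpin and no reference hit → *non-conserved* (novel);
   without a hairpin, a perfect reference match is still reported as
   *conserved (no precursor)*. Matures are named per family by descending
   abundance (`ame-miR166-1`, …; novel ones `ame-miRN-1`, …).
4. **Targets** — expectation-scored complementarity (mismatch 1, G:U wobble
   0.5, gap 2; positions 2–13 weighted 1.5×), cutoff 3.0, at most 2 seed
   mismatches and at most one gap never inside the seed. A mismatch or gap at
   positions 9–11 switches the predicted mechanism from cleavage to
   translational repression.
5. **Phasing** — TAS3-style two-hit loci: exactly two trigger-complementary
   sites ≥ 50 nt apart (transcripts with three or more sites are flagged, not
   called). The phasing register starts at the cleavage point of the
   downstream site and walks 5'-ward in 21-nt steps; minus-strand tags are in
   register with a 2-nt offset (duplex overhang). The phase score is the
   fraction of reads between the sites that fall in register.
6. **Expression** — 2^-ΔΔCt with a reference gene, per-replicate ΔCt, Welch
   t-test versus the control condition; *up* iff fold ≥ 2 and p < 0.05,
   *down* iff fold ≤ 0.5 and p < 0.05.

All internal sequence handling is DNA-alphabet, uppercase, 0-based
half-open; reports render lowercase RNA with 1-based coordinates.

## Worked example

Generate a small synthetic study with a truth ledger and run the full
pipeline on it:

```bash
ame-smallrna simulate --out bundle --seed 7 --n-hairpins 8
ame-smallrna all \
  --reads bundle/reads.fastq \
  --transcriptome bundle/transcriptome.fasta \
  --ncrna bundle/ncrna.fasta \
  --reference bundle/mature_ref.fasta \
  --ct bundle/ct_table.tsv \
  --out run
```

which prints (seed 7, 12 transcripts / 8 hairpins variant shown):

```
pipeline complete: run ({'clean': {'raw_reads': 21440, 'clean_reads': 21240,
'clean_distinct': 28}, 'discover': {'passing_matures': 15, 'overmapped_tags': 0},
'classify': {'catalog_size': 19, 'conserved_precursor': 4,
'conserved_no_precursor': 4, 'non_conserved': 11}, 'targets': {'n_hits': 50},
'phasing': {'n_loci': 1, 'flagged_multisite': [], 'n_phasirnas': 8},
'expression': {'n_genes': 28, 'n_responsive': 27}})
```

The catalog (`run/catalog.tsv`) names each mature and records its class,
family, closest reference homolog and read support:

```
name	mature_seq	length_nt	class	family	homolog	homolog_mismatches	reads	precursors
ame-miR9000-1	guguuaaccuuacuauacucc	21	conserved_precursor	MIR9000	syn-miR9000a	0.0	1551	synth_t001:215
ame-miR9001-1	cuuauuuuuugcuggugcccaa	22	conserved_precursor	MIR9001	syn-miR9001a	2.0	2393	synth_t002(-):180
ame-miR9500-1	ccaggguguaauguguaagga	21	conserved_no_precursor	MIR9500	syn-miR9500a	0.0	1762	
```

The TAS locus report (`run/tas_loci.tsv`) shows all planted phasiRNAs in
register with a perfect phase score:

```
transcript	phase_index	strand	seq	count	start	phase_score
synth_tas1	1	+	cuccguaaguggcgcuauccc	104	339	1.0
synth_tas1	2	+	gcacuagcauguaggguucuc	77	318	1.0
synth_tas1	3	+	cuugcaucuugaugacaggug	30	297	1.0
```

and `run/expression_calls.tsv` holds the per-condition 2^-ΔΔCt calls:

```
gene	condition	fold_change	log2_fold	replicate_sd	p_value	call
cons-down-1	24h	0.29152083194692185	-1.7783291134421644	0.006932284895406419	0.0013158448931921635	down
cons-down-1	3h	0.25559442759227846	-1.9680717115469788	0.019649060509272256	6.866649396795429e-05	down
```

Every planted miRNA, phasiRNA and expression effect traces back to
`bundle/truth.tsv`, so recovery can be asserted exactly.

The bundled catalogs are available programmatically:

```python
from ame_smallrna.io_formats import load_catalog_fixture
from ame_smallrna.classify import family_summaries, MirnaRecord, MirnaClass

rows = load_catalog_fixture("table2")          # 69 conserved miRNAs
records = [MirnaRecord(name=r.name, mature_seq=r.mature_seq,
                       mirna_class=MirnaClass.CONSERVED_PRECURSOR,
                       family=r.family, homolog_id=r.homolog,
                       reads=r.reads, precursor_ids=["p"]) for r in rows]
top = family_summaries(records)[0]
print(top.family, top.total_reads)             # MIR166 88223
```

## Reproduction

Run the full test suite (unit, property-based, and acceptance tests):

```bash
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Compute the headline acceptance quantities (fixture arithmetic, scoring
oracle agreement, zero-noise end-to-end recovery, expression bias/type-I,
threshold conformance) and write them as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Expected values with any seed: fixture quantities are exact (top family
MIR166 with 88,223 reads; 69 + 14 catalog records; 59.49% clean reads;
16.81% 21-mers), oracle agreement 1.0, recovery and correct-class fractions
1.0, minimum phase score 1.0, 27 of 28 panel genes responsive, |log2-fold
bias| < 0.05, null responsive rate ≤ 0.05, and the 20/21-locus,
4-mismatch, and 3-seed-mismatch thresholds behave as documented.

## Package layout

| module | contents |
| --- | --- |
| `io_formats` | FASTA/FASTQ I/O, sequence normalization, bundled catalog fixtures |
| `preprocess` | adapter trimming, filtering, collapsing, ncRNA annotation, accounting |
| `discovery` | mapping, precursor excision, folding, hairpin criteria |
| `classify` | conservation classes, families, naming, family summaries |
| `targets` | expectation-scored target scan, mechanism inference |
| `phasing` | two-hit TAS locus detection, phasiRNA extraction, phase score |
| `expression` | 2^-ΔΔCt, responsiveness calls, tissue dominance, BH correction |
| `synthetic_data` | truth-ledgered generators for every input the pipeline takes |
| `pipeline` / `cli` | end-to-end orchestration and the `ame-smallrna` command |

See `docs/methods.md` for the precise models, parameter values, and known
limitations.
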