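# Methods

This note records the exact models, parameter values, and numerical
conventions implemented by `ame_smallrna`, the scope of the synthetic-data
generator, and known limitations.

## Conventions

- Sequences are handled internally in the DNA alphabet, uppercase; `U` is
  converted to `T` on input. Reports render lowercase RNA.
- Coordinates are 0-based half-open internally; report tables are 1-based.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  generator and every sampled quantity is a pure function of its parameters
  and the seed. Re-running any stage with the same configuration is
  bit-identical.

## Preprocessing

- **3' adapter**: the leftmost full occurrence of the adapter is removed; if
  absent, a terminal adapter prefix of ≥ 6 nt is accepted. Reads with no
  adapter evidence, with an empty insert, or containing the optional 5'
  contaminant sequence are removed (counted under "3ADT & length filter").
- **Length filter**: inserts of 18–25 nt are kept.
- **Junk filter**: a read is junk if it contains any `N`, if one nucleotide
  makes up ≥ 90% of it, or if ≥ 80% is `A`.
- **Collapsing**: distinct insert sequences with read counts, sorted
  lexicographically (order-invariant).
- **ncRNA annotation**: exact substring match against labeled references
  (both strands); when several classes match, priority is
  rRNA > tRNA > snoRNA > snRNA > other. Annotated tags are excluded from
  clean reads.
- **Accounting**: every raw read is assigned to exactly one accounting row;
  the partition is asserted at runtime. Percentages are
  `round(100 * part / whole, 2)`.

## miRNA discovery

- **Mapping**: exact, ungapped, both strands. Tags mapping to more than 20
  loci are discarded as repeat-derived (20 is kept, 21 is not).
- **Precursor excision**: for each locus, windows with flanks
  {20, 50, 100, 150, 200} nt on both sides (truncated at transcript ends).
  Minus-strand hits are evaluated on the reverse complement.
- **Folding**: ViennaRNA (`RNA.fold`), default parameters, windows ≥ 40 nt.
- **Hairpin criteria** (all must hold): (a) the mature lies entirely in one
  arm and pairs only across the loop (no self-pairing); (b) ≤ 4 mature
  positions are unpaired in the miRNA/miRNA* duplex; (c) the duplex has ≤ 2
  asymmetric bulges and ≤ 3 bulged nucleotides; (d) MFE per nucleotide
  ≤ −0.19 kcal/mol/nt; (e) precursor length 60–300 nt.
- **Star**: the partner span of the mature extended to a 2-nt 3' overhang;
  star read support is the exact tag count of that sequence.
- **Precursor selection** among passing windows: lowest MFE/nt, then
  shortest, then lexicographically first transcript, then leftmost.

## Conservation classification

- **Distance**: shifted Hamming — minimum mismatches over alignment shifts
  of −2…+2, with unaligned overhanging nucleotides of either sequence
  counted as mismatches.
- **Classes**: hairpin + best reference distance ≤ 3 → `conserved_precursor`;
  hairpin + no reference within 3 → `non_conserved`; no hairpin + distance 0
  → `conserved_no_precursor` (requires a minimum read count, default 5); no
  hairpin + distance > 0 → not reported.
- **Families**: a registry maps reference ids to families; unregistered ids
  fall back to the `miR<number>` → `MIR<number>` convention.
- **Naming**: within each family, `ame-miR<fam>-k` by descending reads (ties
  by sequence); novel matures are `ame-miRN-k` globally. Naming is stable
  under input permutation.

## Target prediction

- **Penalties**: match 0, G:U wobble 0.5, mismatch 1, gap 2; positions 2–13
  (the seed) weighted 1.5×. Expectation cutoff 3.0 (inclusive); ≤ 2 seed
  mismatches (wobbles do not count); at most one gap, never in the seed — a
  bulged target nucleotide may sit between miRNA positions g and g+1 for
  g ≥ 13, an unopposed miRNA nucleotide at position 1 or ≥ 14.
- Per (start, end) span the best-scoring alignment is kept; hits are sorted
  by (expectation, transcript id, start) and capped at 200 per miRNA.
- **Mechanism**: translational repression iff a mismatch or gap involves
  miRNA positions 9–11, else cleavage. The predicted cleavage site is
  `t_end − 10` (between the nucleotides opposite positions 10 and 11).

## TAS3 phasing

- **Trigger scan**: the target scanner with relaxed parameters (expectation
  ≤ 5, seed mismatches ≤ 3); overlapping alignment variants of one site are
  merged, keeping the best-scoring one.
- **Locus call**: exactly two sites ≥ 50 nt apart (two-hit model);
  transcripts with ≥ 3 sites are flagged for manual review, not called.
- **Register**: origin at the cleavage point of the downstream site; 21-nt
  windows walk 5'-ward. A plus-strand tag is in register iff
  `(origin − start) % 21 == 0` (and > 0); minus-strand tags carry an extra
  −2 offset for the duplex overhang.
- **Phase score**: in-register reads / all reads between the two sites;
  undefined (reported `NA`) with no reads.

## Expression (2^-ΔΔCt)

- Per replicate, ΔCt = Ct(gene) − Ct(reference), matched by condition and
  replicate. ΔΔCt = mean ΔCt(condition) − mean ΔCt(control);
  fold = 2^−ΔΔCt.
- Significance: two-sided Welch t-test on the replicate ΔCt values
  (condition vs control); untestable with < 2 replicates (p = NaN → `ns`).
- Calls: `up` iff fold ≥ 2 and p < 0.05; `down` iff fold ≤ 0.5 and p < 0.05.
  Thresholds are inclusive on the fold, strict on p. No multiple-testing
  correction by default; Benjamini–Hochberg is available as an option.
- A gene is *responsive* if called up or down in ≥ 1 condition (`up` wins if
  both occur across conditions).

## Synthetic-data generator: scope

The generator emulates the statistical structure of a plant small-RNA study,
not its biology:

- Hairpins are constructed (mature + loop + reverse-complement star) and
  then validated with the production hairpin criteria *in their final
  transcript context*; rejected constructions are retried. Read counts are
  exact (not sampled), so downstream assertions can be equalities; star
  reads default to 5% of mature reads.
- Conserved matures carry a planted reference homolog at 0–3 mismatches;
  novel matures are verified to be > 3 mismatches from every reference;
  "no precursor" matures are verified absent from the transcriptome.
- The TAS transcript has a non-cleavable upstream site (one central
  mismatch) and a perfect downstream site with the phasiRNA windows laid
  between them in exact register.
- Ct tables plant log2 fold changes directly
  (`Ct = baseline − log2fold + N(0, σ)`); the reference gene's noise is
  shared across genes within a replicate unless `reference_sigma=0` is
  requested (needed when per-gene estimation errors must be independent).
- Every read traces to a ledger entry or the declared noise fraction; the
  ledger is written alongside the FASTA/FASTQ/TSV outputs.

## Numerical choices

- Percentages round half-even to 2 decimals via Python `round`.
- MFE values come from ViennaRNA as 32-bit floats; MFE/nt comparisons use
  the threshold −0.19 exactly as computed (no tolerance), which is stable
  because refolding is deterministic.
- Welch's t-test uses `scipy.stats.ttest_ind(equal_var=False)`.
- Expectation scores are sums of exact binary fractions (0.5, 0.75, 1.5, 2,
  3), so equality comparisons against the cutoff are exact.

## Limitations

- Discovery is transcriptome-based: genomic precursors absent from the
  assembly are unrecoverable by construction (hence the
  `conserved_no_precursor` class), and intron-spanning precursors are out of
  scope.
- Mapping is exact-match only; no mismatching or clipped alignment, so
  sequencing errors reduce counts rather than mislocate tags.
- Target scoring is complementarity-only (no accessibility/energy term) and
  allows at most one gap.
- Phasing implements the 21-nt two-hit TAS3 model only; 24-nt phasing and
  one-hit triggers are not modeled.
- The expression module assumes amplification efficiency 2.0 for all assays
  and a single reference gene.
- The synthetic generator plants perfect-duplex hairpins by default;
  real precursors with large internal loops are only reachable through the
  `duplex_mismatches` parameter and may fail the in-context validation more
  often.
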