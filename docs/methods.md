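# Methods

This note documents the models and procedures behind `amplistar`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic setting does and does not show about
real data.

## The problem setting

A pharmacogene locus of ~6.6 kb is amplified in full, tagged with sample
barcodes, and sequenced as single-pass long reads.  Each diploid sample
contributes reads from its two parental haplotypes (or from one, when the
other chromosome carries a whole-gene deletion), in proportion to gene copy
number.  The analysis must recover, per sample: the phased haplotype
sequences ("haplogroups"), their variants against the locus reference, the
star-allele diplotype with copy-number state, and the predicted metabolizer
group.

## Synthetic locus and read simulator

The generator defines the study conditions for every test:

- **Reference locus** — an i.i.d. random sequence of 6,600 bp (GC fraction
  0.45) with a 22-bp T-homopolymer embedded in the upstream region, the
  canonical trouble spot for long-read consensus length accuracy.
  Deterministic per seed.
- **Translation table** — 17 star alleles structured like the real CYP2D6
  families at synthetic coordinates: *1 (zero variants, the default),
  *1B, the *2/*2A, *35/*35A, *4/*4A and *6/*6A/*6B core/suballele
  families, *3A, *9, *10D, *17, *41, and the whole-gene deletion *5.
  Suballeles contain their core's diagnostic variants plus private ones,
  and the *2/*35/*41/*17 families share a four-variant backbone, so subset
  matching genuinely has to discriminate.  Variant counts follow the
  literature where it states them (*35A: 5, *4A: 7, *2A: 14, the latter
  including one insertion and one 3-bp deletion).  Activity values:
  normal-function alleles 1, reduced-function 0.5, null and deletion 0.
- **Error model** — per-base mismatch 1.5%, insertion 4%, deletion 4%
  (indel-dominant, ~9.5% total), matching the error structure of raw
  single-pass long reads.  Rates are free parameters in [0, 0.2).
- **Read layout** — padding (5-mer) + 16-mer barcode + M13 tail + gene
  primer + full-length insert + the reverse-complemented right-side
  adornments with the *same* barcode (symmetric scheme).  Reads are emitted
  full length (amplicon sequencing involves no fragmentation), on random
  strands, in random order; per-haplotype counts are multinomial with
  weights proportional to copy number, which is exactly the signal the
  copy-number caller consumes.  The direct-barcoding layout (barcode fused
  to the gene primer, no M13) is a preset of the same machinery.
- **Cohort** — the packaged 20-sample scenario spans the diplotype space:
  16 balanced heterozygotes, one 2:1 duplication carrier (*1B/*2AXN), two
  hemizygous deletions (*4A/\*5, *2A/\*5, deletion assay positive), one true
  homozygote (*10D/*10D, deletion assay negative) and one duplicated
  homozygote (*2A/*2AXN, duplication assay positive).  Default depth is
  120 reads per sample, chosen from the coverage scale of real runs
  (hundreds of subreads per sample); it keeps minority haplotype clusters
  at ~25+ reads after demultiplexing losses, comfortably above all voting
  floors below.

What the simulator does **not** model: chimeric PCR fragments (not observed
in the motivating data), pseudogene off-target reads (excluded upstream by
primer design), polymerase-pass/quality structure of the raw signal, and
read-length variation.  Passing tests therefore demonstrate the pipeline's
statistical machinery under a realistic error profile, not robustness to
pseudogene contamination or chimeras.

## Demultiplexing

The M13 anchor is located at each read end by semi-global (infix) alignment
with an edit budget of ~len/4; the barcode window sits immediately before
(after) the anchor by construction.  Each candidate barcode is scored by its
best infix edit distance within that window; a read is assigned to sample
*s* only when *s* wins at **both** ends within `max_barcode_mismatches`
(default 2) and the second-best barcode is strictly worse at both ends.
Everything else — anchor not found, strand conflict between ends, ends
naming different samples, ambiguous or over-budget barcodes — lands in the
unassigned pool with a reason.

Edit distance rather than fixed-offset Hamming comparison is essential
under the indel-dominant error model: with 8% per-base indel rates, three
quarters of reads carry an indel somewhere in a 16-mer barcode, which a
fixed-offset comparison scores as multiple mismatches.  The packaged
barcode sets keep pairwise Hamming distance ≥ 6, so a budget of 2 leaves no
room for cross-assignment (verified: 0 cross-assignments over 2,400 reads
with up to two injected barcode errors).

Orientation uses which anchor (M13 forward vs reverse) matched; the
sequence is reverse-complemented to the plus strand while the read's
`strand` field keeps the original strand as provenance.  Gene primers are
then located the same way and everything outside the insert is trimmed.
The `trim_end_bases` window (default 21) is *not* cut off: the terminal
bases remain part of the insert but are masked for variant support, because
consensus ends are ragged (each read's primer boundary estimate wobbles by
a base or two).  Reads shorter than `min_read_length` (default 6,000) after
trimming are excluded from phasing.

## Haplogroup phasing

Clustering is reference-free.  Reads above `max_subreads` (default 800) are
uniformly subsampled (seeded).  A medoid read (minimum summed edit distance
over a 20-read probe) seeds a single cluster, and the algorithm iterates
*split test → reassignment → re-polish* to a fixed point (≤ 10 rounds,
≤ `max_haplogroups` = 4 clusters).

**Consensus polishing** realigns every member to the current consensus
(edit-distance alignment with extended CIGAR), accumulates per-column votes
(A/C/G/T/deletion) plus per-junction insertion votes, and rebuilds the
sequence from the winners; iterate to a fixed point (≤ 5 rounds).  Three
numerical choices matter, all driven by the ~10% error regime:

- **Insertion placement is left-normalized before voting.**  Aligners place
  equivalent insertions in repeat context at different junctions for
  different reads; without canonicalization the votes fragment and a truly
  missing base is never restored.
- **Indel events need `max(4, 0.35·n)` votes** rather than a plain
  majority.  A true missing base gathers only ~50–60% of members (local
  errors fragment the rest), while indel noise stays below ~25%; and in
  small clusters plain majorities amplify the cluster's own noise
  (a 5-member cluster would otherwise acquire ~30 spurious deletions).
  Base substitutions, whose votes are clean, win by simple plurality with
  ties kept at the current consensus base.
- **Contested homopolymer runs are repaired post hoc.**  When the consensus
  erroneously extends a run over a true substitution (e.g. `AAAAAGAAA`
  polished to nine A's), the correcting votes spread over every equal-cost
  mismatch placement in the run and no single column can win them back.
  A final pass pools alternative-base votes per run and, above the event
  floor, substitutes that base at the run position that minimizes the
  summed member edit distance — the objective the column votes approximate.

With these rules, 30 reads at 10% error reproduce a 6.6-kb truth sequence
exactly outside homopolymer runs ≥ 8 bp; inside such runs the length may be
off by one (the known long-read artifact — the corresponding variant calls
are flagged, see below).

**Split test.**  A cluster splits when ≥ `max(4, min_support_fraction·n)`
reads co-vote the same non-consensus allele at two or more discriminating
columns whose supporter sets overlap coherently (overlap ≥ 60% of the
smaller set).  Deletion columns are excluded inside runs ≥ 3 bp and
otherwise require support from 25% of the cluster; at least one column of
the winning pair must be a substitution, because deletion-only pairs are
reachable by indel noise even in a pure cluster.  Consequence: two
haplotypes distinguished *solely* by indels fold into a single haplogroup —
a deliberate limitation; every packaged allele pair differs by ≥ 2
substitutions.  The new cluster is seeded with the full co-voting signature
(every read supporting at least half of the coherent columns) and polished
starting from the parent consensus.

**Reassignment** scores each read only at *bimodal* columns — positions
where the consensuses disagree and both alleles carry at least the support
floor in the pooled pileup.  Whole-read edit distance is deliberately not
used: a freshly split cluster's consensus is rougher than the parent's, and
that quality difference (tens of edits) would swamp a 3–15-column haplotype
signal and repel the new cluster's own reads.  Ties keep the previous
assignment.

**Filtering** then drops consensuses with support below
`min_support_fraction` (default 0.1) of the total or length outside
(1 ± `length_window` = 0.2) × the median, merges identical survivors
(supports summed), and re-indexes by descending support — automating the
manual length/coverage inspection of the original workflow.

**Coverage ratio.**  With two haplogroups, the support ratio
(larger/smaller) classifies as "duplicated" at ≥ `duplication_threshold`
(default 1.8, config-exposed) and "balanced" below; observed balanced
ratios sit near 1.0–1.3 and true duplications near 2, so 1.8 splits the
two regimes.  At 120 reads/sample the ratio estimate of a true 2:1
duplication has a standard deviation of roughly 0.4, so an occasional
duplication is classified balanced; this is a depth limitation, not a
threshold artifact.  One haplogroup classifies "single"; more than two is
an unresolved mixture and an error, matching diploid biology.

## Variant calling

Each haplogroup consensus is aligned globally to the locus reference with
affine gaps (match 2, mismatch −4, gap open −6, extend −1; a gap of length
L scores −(6+L)).  Alignment columns are atomized: runs of gap columns
merge into one indel each, multi-base mismatches split into single-base
substitutions (biallelic atomic events only, so no multiallelic VCF rows
exist by construction).  Indels are left-normalized — shifted to the
smallest coordinate producing the same edited sequence — which a
brute-force enumeration oracle and `bcftools norm` independently confirm.
Variants whose reference footprint lies within the masked terminal windows
(21 bp) are suppressed.

Edits lying wholly inside homopolymer runs ≥ 8 bp are flagged
`low_confidence`: one-base length wobble there is the dominant residual
consensus error, and the flag propagates to a VCF `FILTER` tag and excludes
the variant from star-allele matching (it is retained as an extra variant
for curation).

Zygosity is classified across the two haplogroups' variant sets: present in
both → homozygous, in one → heterozygous.  A sample with a single observed
haplogroup *and* an established deletion or homozygosity is one observed
sequence representing both (or the only) gene copies, so its variants are
all homozygous.

Output is VCF 4.2 with phased genotypes encoding haplogroup membership
(`1|0`, `0|1`, `1|1`; haploid `1` for single-haplogroup samples) plus a
per-sample variant TSV; reading the VCF back reproduces the variant sets
exactly.

## Star-allele calling and phenotype

Candidate alleles are those whose complete definition is a subset of the
observed (non-flagged) variant set; the candidate with the most defining
variants wins, ties breaking by fewest unexplained variants, then
lexicographically with a caveat.  An empty or unmatched set yields the
default allele (*1).  Observed variants outside the winning definition are
reported as `extra_variants` and never veto the match — full-locus
sequencing always reveals variants the translation table does not list.

Diplotype assembly: two balanced haplogroups get one copy each; with a
duplicated ratio the higher-support haplogroup carries `round(ratio)`
copies (capped at 3; ratios outside [1.8, 3.5] add an "ambiguous copy
number" caveat) and the XN suffix.  A single haplogroup resolves through
the orthogonal PCR evidence: deletion positive → hap/\*5; duplication
positive → hap/hapXN; deletion negative → homozygous; nothing tested →
homozygous with a "deletion not excluded" caveat.  The evidence is an input
file, not a computation — the assays are wet-lab.

The activity score sums allele activity × copy number over both
chromosomes; an XN allele in a printed diplotype string counts as two
copies.  Cut-points (config-overridable): 0 → poor, (0, 1.5] →
intermediate, (1.5, 2.5) → normal, ≥ 2.5 → ultrarapid.  The boundary
placement of 1.5 in the intermediate group is forced by the published
worked examples (*1/*41 and *9/*41XN are both printed intermediate); the
full published table of 26 diplotype rows reproduces under this mapping,
which the acceptance script recomputes.

## Pipeline and reproducibility

Stages (simulate, demux, phase, variants, call) each consume the previous
stage's on-disk artifacts, so they are independently runnable and the whole
run is idempotent.  One master seed derives per-sample phasing streams; the
simulator, subsampling, and medoid probes are all generator-seeded, and a
seeded rerun reproduces the summary TSV byte for byte.  Failures propagate
with stage and sample context and never produce partial summary rows.

Problem sizes used by the test suite and acceptance script: 20 samples ×
120 reads × 6.6 kb for the end-to-end cohort; 2-kb loci and 12–45 reads
for clustering unit tests; 2,400 reads for the demultiplexing stress test;
1,000 random indels for the normalization oracle.

## Known limitations

- Haplotypes distinguished only by indels are not split (see above).
- Homopolymer run lengths ≥ 8 bp may be off by one in consensus; the
  corresponding calls are flagged rather than resolved.
- Copy number is inferred from a single support ratio; N beyond 3 is
  capped, and ratios between ~1.4 and 1.8 are genuinely ambiguous at
  practical depths.
- More than two distinct haplotypes per sample (e.g. mosaicism, hybrid
  genes) is reported as an error, not resolved.
- The demultiplexer assumes symmetric barcodes; asymmetric dual indexing
  would need a layout extension.
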