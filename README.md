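# amplistar

Full-length pharmacogene genotyping from barcoded long-amplicon reads.

Highly polymorphic drug-metabolism genes such as *CYP2D6* resist short-read
genotyping: a homologous pseudogene sits next door, the clinically decisive
differences are combinations of variants spread over kilobases, and whole
gene copies can be deleted or duplicated.  Sequencing the entire ~6.6-kb
locus as one amplicon solves all three at once — every read covers every
variant, so the two parental haplotypes can be separated directly from the
reads — but the raw single-pass reads carry ~10% indel-dominant error and
arrive multiplexed from many barcoded samples.  `amplistar` implements the
complete desk-side analysis for this setting:

1. **Demultiplexing** — reads carry a symmetric sample barcode at both ends
   (padding + barcode + M13 tail + gene primer); a read is assigned only
   when both ends agree on the same barcode within an edit-distance budget
   and the runner-up barcode is strictly worse.
2. **Haplogroup phasing** — reference-free clustering of each sample's
   reads into one or two *haplogroup* consensus sequences (one per distinct
   chromosomal copy), by iterative realign-and-vote consensus polishing and
   a co-voting split test; spurious low-support or off-length consensuses
   are filtered automatically.
3. **Variant calling** — each consensus is globally aligned to the locus
   reference (affine gaps); differences are atomized into single-base
   substitutions and left-normalized indels, described in HGVS g. notation,
   classified heterozygous/homozygous across the two haplogroups, and
   written as phased single-sample VCF.
4. **Star-allele calling** — each haplogroup's variant set is matched
   against a translation table by subset containment, the most specific
   suballele winning (e.g. *35A over *35); observed variants absent from
   the table are reported, never fatal.
5. **Copy number and phenotype** — an unbalanced subread-support ratio
   between the two haplogroups (≥ 1.8 by default) marks a duplicated
   allele (XN); a single observed haplogroup is resolved by orthogonal
   deletion/duplication PCR evidence into hap/\*5, hap/hapXN or a
   homozygote.  The metabolizer group follows from the summed activity
   score of all gene copies (0 → poor, ≤ 1.5 → intermediate, < 2.5 →
   normal, ≥ 2.5 → ultrarapid).

A first-class synthetic module generates the entire study setting with
known truth — reference locus with a 22-bp T-homopolymer, star-allele
haplotypes, diploid samples with copy-number states, and barcoded noisy
reads — so every stage is testable end to end without external data.

## Worked example

```bash
python examples/simulate_and_genotype.py
```

simulates three samples at 100 reads each and genotypes them:

```
sample_id  n_haplogroups supports  coverage_ratio classification  n_het  n_hom  genotype  activity_score  phenotype
      S01              2    36,29           1.241       balanced      6      0   *1/*35A             2.0     normal
      S02              2    32,31           1.032       balanced     15      0    *1/*2A             2.0     normal
      S03              2    54,22           2.455     duplicated     15      1 *1B/*2AXN             3.0 ultrarapid
```

S01's reads split into two haplogroups of near-equal support; one carries
no variants (*1), the other the five-variant *35A set, giving a normal
metabolizer (score 2).  S03's support ratio of 2.5 flags a duplicated
haplogroup: the *2A copy is present twice (*2AXN), lifting the score to 3
and the call to ultrarapid.  `examples/phenotype_from_diplotype.py` and
`examples/normalize_and_describe_variants.py` demonstrate the activity-score
translation and indel left-normalization/HGVS machinery in isolation.

The same pipeline is available as a CLI:

```bash
amplistar simulate --outdir run --depth 120 --seed 1
amplistar run-all --config run/config.yaml
```

## Library surface

```python
from amplistar import (
    build_reference, apply_allele, simulate_reads,     # synthetic locus
    demultiplex, orient_and_trim,                      # demux + trim
    cluster_reads, polish_consensus, coverage_ratio,   # haplogroup phasing
    align_to_reference, extract_and_normalize,         # variant calling
    match_haplotype, call_diplotype, predict_phenotype # star alleles
)
```

See `docs/methods.md` for the models, thresholds and design decisions.

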