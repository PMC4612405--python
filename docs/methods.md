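# Methods

## The problem

When two genetically distinct plants are grafted, some mRNAs produced in one
partner (the *donor*) cross the graft junction and can be detected by RNA-Seq
in the tissues of the other partner (the *receptor*). Because the two
partners are different genotypes, a sequencing read can sometimes be
attributed to one partner's genome: at a *diagnostic SNP* — a position where
both partners are homozygous for different alleles — the base a read carries
identifies its genome of origin. `graftmrna` implements the full inference
chain from raw alignments to per-gene mRNA *transmission rates*, plus a
synthetic-data generator that makes every stage verifiable without any
external dataset.

## Pipeline model and assumptions

1. **Mapping filters.** Only uniquely mapped reads (one single best hit) are
   used. Potential PCR duplicates — records sharing (library, contig, start,
   strand) — are removed from the *genomic* libraries before pileup; the
   representative kept is the lexicographically smallest read id, for
   determinism. RNA libraries are not collapsed: the detection criteria below
   already count distinct mapping coordinates, while window counts, RPM
   denominators and RPKM use all retained mapped reads. Collapsing RNA
   coordinates would cap the reads observable at any locus at
   `2 x read_length` coordinate classes and bias every low transmission rate
   upward, so the coordinate-collapse behavior is available only as the
   `dedup_rna` switch. The alignment model is ungapped (substitutions only);
   spliced or indel-containing records are out of scope, and allele evidence
   is restricted to ungapped exonic matches.

2. **Genotyping.** From each genotype's genomic pileup, a position is called
   homozygous when the dominant base has depth >= 7 and a frequency strictly
   greater than 90% of all covering reads (ties for the dominant base are
   no-calls; the denominator is the full pileup depth). Loci called
   homozygous in both partners with different alleles are the diagnostic
   SNPs. Both bounds are read literally: 6 clean reads is a no-call, 7 is a
   call; 9-of-10 (exactly 90%) is a no-call, 10-of-11 is a call.

3. **Read classification.** A receptor-tissue read is *donor-origin* when
   (i) every diagnostic locus it covers shows the donor allele and (ii) it is
   perfectly aligned to the donor genome. "Perfect" is judged against the
   donor *haplotype* — the reference plus the donor genotype's own called
   substitutions — not against the reference, because the two partners also
   share non-diagnostic differences from the reference that a genuine donor
   (or receptor) read will display. Reads whose covered loci mix donor and
   receptor alleles are *conflicted* and discarded from evidence on both
   sides; reads covering no diagnostic locus, or carrying an unexplained
   mismatch, are *uninformative*.

4. **Transmitting-gene calls.** A gene is called graft transmitting in a
   direction when its donor-origin evidence meets any of: (a) one read
   carrying >= 2 diagnostic loci; (b) >= 2 unique reads covering the same
   locus; (c) >= 2 unique reads carrying different loci. "Unique" means
   distinct (contig, start, strand). Criterion (c) is implemented as
   ">= 2 unique reads and >= 2 distinct covered loci", which is equivalent to
   the exists-a-pair formulation (if two loci are covered and two unique
   reads exist, a pair carrying different loci can always be chosen); the
   test suite checks this against a literal pair-enumerating oracle.

5. **Transmission rates.** For each diagnostic SNP of a transmitting gene, a
   window extends one read length to each side of the locus (clipped at
   contig bounds and flagged). Donor-attributable reads fully contained in
   the window are counted separately in the receptor and donor tissues'
   libraries, each count is normalized to RPM by its own library's total
   mapped reads, and `rate = RPM_receptor / (RPM_receptor + RPM_donor)`. The
   gene rate is the unweighted mean over its loci; loci with no eligible read
   on either side are skipped. Estimates are flagged *reportable* when the
   gene produced >= 50 donor-origin reads in the donor tissue; the filter
   gates reporting and distribution summaries, not the transmitting call
   itself. By default only reads covering the SNP (hence allele-informative)
   are counted; counting every perfectly-donor-matching read in the window
   regardless of SNP coverage is exposed as the `window_rule="all_perfect"`
   switch, since reads that do not reach the SNP match both haplotypes and
   cannot be attributed.

6. **Expression.** Per-gene raw counts are reads overlapping the gene's
   exons (a read overlapping two gene models counts toward both), normalized
   to RPKM = `count x 1e9 / (exon_length x library_total)`. An optional
   read-exclusion hook stands in for an upstream rRNA pre-filter.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `min_dominant_depth` | 7 reads | homozygous-call depth floor |
| `min_dominant_fraction` | 0.9 | dominant-allele frequency bound (strict) |
| `max_edit` | 4 (reads <= 101 bp), 6 (longer) | aligner edit-distance cap |
| `min_donor_reads` | 50 reads | reportability floor for gene rates |
| `read_length` | 101 bp | read length; also the window half-width |
| `window_rule` | `informative` | which window reads count toward rates |
| `dedup_rna` | off | coordinate-collapse RNA libraries too |

## The synthetic-data generator

`simulate` builds one contig of random DNA, two fully homozygous genotypes
(`A` carried by the scion, `B` by the rootstock) differing from the reference
at planted biallelic substitutions — a configurable fraction diagnostic
(different non-reference alleles) and the rest shared — and evenly spaced
single-exon, forward-strand genes. Each gene is sourced in one genotype with
a log-normal expression weight; each tissue draws its configured library size
multinomially from its home genes, and each read is routed to the partner
tissue's library with the gene's transmission fraction. Uniform substitution
error and coordinate-level PCR duplication are applied per library; reads are
single-end with constant placeholder qualities. Defaults emulate a desk-scale
interspecific grapevine graft: 101-bp reads, 15x genomic coverage, 5 planted
SNPs/kb (interspecific *Vitis* divergence is of this order), 0.5% per-base
substitution error, 5% duplication, 30% of genes mobile with fractions drawn
log-uniformly on [1e-4, 0.6] (which puts roughly two thirds of mobile genes
below rate 0.01, matching the regime the method is meant for).

What the generator does **not** emulate: introns and spliced alignment,
indels and structural variants, paired-end inserts, base-quality variation,
strand-specific library artifacts, expression differences between tissues of
the same gene, and heterozygous sites. Passing tests therefore demonstrate
the correctness of the inference chain under its own model assumptions, not
robustness to those real-data complications; real alignments can still enter
through SAM from any mapper, subject to the ungapped-record restriction.

## Verification studies (`graftmrna.study`)

Problem sizes are chosen so each study runs in seconds to ~1 minute on one
CPU:

- **Diagnostic exactness** — error-free 100-kb genomes at 30x: recall over
  diagnostic loci with realized post-filter depth >= 7 in both genotypes, and
  precision over all calls, are both exactly 100%.
- **No-noise specificity** — all fractions 0, error 0 (40 genes, 20k reads
  per library): zero transmitting calls and zero rate records.
- **Parameter recovery** — 200 genes, one central diagnostic SNP each, exon =
  2 x read length, equal expression weights, ~3000 error-free draws per gene,
  fractions cycling {0.001, 0.01, 0.1, 0.5} assigned in pairs so both
  genotypes carry the same fraction multiset and library sizes balance
  (unequal totals would be re-weighted by RPM and shift every rate). Median
  relative error for fractions >= 0.01 is a few percent; truth-vs-estimate
  Pearson r exceeds 0.99.
- **Correlation contrast** — 150 all-mobile genes with fractions log-uniform
  on [0.01, 0.5] (the reportable regime): two replicate RNA draws of one
  graft give gene-rate Pearson r near 1; two independent grafts with
  independently drawn fractions give r near 0.
- **Default conditions** — one graft under the generator defaults, reporting
  detection scores and the rate-distribution summary (at 0.5% sequencing
  error a small number of false transmitting calls appears — single-base
  errors at a diagnostic locus can forge a donor read, the method's real
  false-positive mode).

## Numerical and design choices

- Coordinates are 1-based fully closed everywhere (SAM/VCF/GFF3 convention);
  conversion at the pysam boundary is explicit.
- The built-in aligner seeds on exact k-mers with `k = read_length //
  (max_edit + 1)` (clamped to [8, 32]), so any read within `max_edit`
  substitutions of a location retains at least one error-free seed
  (pigeonhole); candidates are verified by Hamming distance on both strands
  and ties for best score are dropped. It is test support for synthetic
  FASTQ, not a production mapper.
- Dominant-base ties, all-zero windows, empty estimate lists, constant
  correlation inputs and empty distributions are all explicit no-call /
  skip / flagged-degenerate paths, never silent zeros.
- Determinism: all randomness flows from `numpy.random.SeedSequence` spawns
  of one seed; outputs contain no timestamps, and the run manifest (config
  echo minus the output directory, input checksums, per-stage counts) makes a
  run reproducible bit-for-bit.
- SNPs not overlapping any gene model are kept in the VCF but excluded from
  gene-level detection and rates.
- Strandedness of strand-specific libraries is ignored in classification
  (allele evidence is strand-free).

## Known limitations

- Ungapped evidence only; genes whose diagnostic SNPs sit near splice
  junctions would lose evidence with real spliced reads.
- A single sequencing error at a diagnostic locus can forge donor evidence;
  criteria (a)-(c) mitigate but do not eliminate this, and the benchmark
  quantifies it.
- The treatment of mixed-allele (conflicted) reads — discarded from both
  sides — and the coordinate (rather than sequence) notion of "unique reads"
  are choices among defensible readings; both are isolated behind single
  code paths for sensitivity analysis.
- Transmission fractions are recovered accurately only when both libraries
  sample their tissues at comparable depth; RPM corrects depth, not
  composition.
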