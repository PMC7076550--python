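# Methods

## The procedure and its assumptions

The pipeline models the standard *in-silico* candidate-gene workflow for a
bi-parental rice cross: two inbred parents re-sequenced and called against
a primary reference genome (and, for validation, a second assembly),
previously mapped QTL hotspots supplied as intervals, and a curated list
of abiotic-stress genes. Its core assumptions:

- **Inbred, homozygous parents.** Both parents are inbred cultivars, so
  calls are expected homozygous; heterozygous or low-quality calls are
  treated as noise and removed by the quality filter (QUAL ≥ 100,
  genotype hom — the threshold is inclusive, reading "≥ 100" literally).
  A site called in one parent and absent in the other implies the
  reference allele in the absent parent, because both were called against
  the same assembly; parental polymorphism is therefore the symmetric
  difference of the two call sets keyed on normalized (pos, ref, alt).
- **One transcript per gene.** Each locus is treated as one coding
  sequence. When a GFF3 carries several mRNAs, the transcript with the
  longest summed CDS is used; the underlying study material does not
  record which isoform was used per locus, so this is our choice.
- **1-based inclusive coordinates everywhere** internally; VCF positions
  are kept as-is and BED converted on read/write.
- **Multi-allelic records are split** into biallelic records before any
  downstream step, since the parental comparison is per allele.

## Consequence annotation

For each gene the annotator assembles a transcript view: the spliced CDS
in coding orientation, up to 3000 nt of downstream sequence (3′UTR plus
post-gene genomic, for stop-loss read-through) and the upstream sequence
(1000-bp promoter plus 5′UTR, for start-gain scanning). The alternate
haplotype is produced by mutating the chromosome and lifting feature
boundaries over the edit, which makes plus and minus strands exactly
symmetric (a property test annotates mirrored genes and requires
identical calls).

Both alleles are translated with the standard genetic code from the
annotated start; translation stops at (and excludes) the first stop
codon. Effects are decided as:

| condition | effect |
|---|---|
| proteins identical | synonymous |
| equal length, residue substitution | missense, reported `"X pos Y"` |
| net indel ≡ 0 (mod 3), expected length reached | inframe_indel |
| net indel ≢ 0 (mod 3) | frameshift, with the first diverging residue |
| premature stop (no read-through) | stop_gain |
| translation passes the annotated stop | stop_loss (read-through ≤ 3000 nt; flagged if no stop found) |
| 5′UTR/promoter variant creating an in-frame upstream ATG with a stop-free path to the annotated start | start_gain, offset in residues |

Design choices made where the convention was genuinely open:

- A net-length ≢ 0 (mod 3) indel is always a frameshift, even when it
  also bypasses the annotated stop; stop_loss is reserved for variants
  hitting the stop codon itself or in-frame read-through. Re-sequencing
  tables in this literature label *any* length-changing coding indel
  "frame shift", so reports carry that label alongside the standard
  taxonomy.
- Indels are left-normalized (leftmost representation, one anchored base)
  before keying and comparison; printed anchored allele strings are
  parsed as-is.
- When several upstream ATGs qualify for start gain, the one closest to
  the annotated start (smallest residue offset) is reported.
- A variant spanning an exon–intron boundary is annotated as coding and
  flagged `splice_region`; splice-site effect prediction is out of scope.
- Same-length multi-residue substitutions (MNP haplotypes) are reported
  as missense at the first differing residue.

## Hotspot mining and dual-reference concordance

Gene–hotspot assignment uses ≥ 1 base of span overlap (a gene straddling
a hotspot edge counts in); an interval-tree implementation is tested
against a quadratic all-pairs oracle. Interval projection between the two
assemblies abstracts sequence matching to an anchor table (gene spans in
both references): the nearest flanking anchors supply per-end offsets,
and the per-end deviations correspond to the assembly-to-assembly shifts
such studies report. The concordance filter confirms a defining variant
iff the second-reference call set contains the identical normalized
allele change within 10 bp (default) of the anchor-projected position —
the tolerance absorbs normalization ambiguity in repeat tracts — and
drops a candidate only when *all* of its defining InDels fail; SNP-only
candidates are not subject to the InDel rule. Genes absent from the
anchor map are kept and flagged unassessable.

One discrepancy in the source material is worth recording: one printed
insertion is described as 8 bp in the text while its printed allele
strings are 9 bp; the allele strings are authoritative here. The text's
further claim that this insertion creates an upstream start codon is not
derivable from the printed alleles and is not asserted anywhere.

## The synthetic study generator

`saltmine.simulate` emulates the study design so every stage is testable
without downloads: 2 chromosomes × 500 kb, 40 non-overlapping genes (each
≥ 2 exons, ATG…stop CDS of 250–400 codons with codons drawn from a
stop-free pool, 150-bp UTRs, ≥ 1 kb promoter clearance), 4 hotspots
placed over contiguous gene runs so a configurable fraction (default
0.8) of genes falls inside, a second reference derived by padding
chromosome starts (per-chromosome shifts, default 5 and 12 kb — the
assembly-offset phenomenon scaled to desk size), and a 50-line panel.
The default planting plan is 242 variants: 22 per coding consequence
class (synonymous, missense, in-frame indel, frameshift, stop gain, stop
loss, start gain) and 22 noncoding variants in each of intron, 3′UTR,
promoter and intergenic space, carriers cycling parent 1 / parent 2 /
both. Panel allele frequencies cycle 4–75 % (the range such panel
surveys report), with named donor lines (Pokkali, Nona bokra, FL478)
forced to the alternate allele. All randomness flows from one explicit
seed; identical seed and config reproduce every output bit for bit.

Truth labels are computed **constructively**: the generator builds the
mutated codons and frames with its own hand-written codon table and its
own upstream-ATG scan, and never calls the annotator under test. The
34-candidate demonstration config plants 34 defining InDels of which two
exist only against the first reference, so the concordance filter must
confirm exactly 32.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: sequencing error and mapping artefacts,
heterozygous residual segments in the parents, structural variation
beyond short indels, transposon-rich intergenic space, alternative
isoforms, and real assembly rearrangements (the second reference differs
by clean per-chromosome offsets only). Results on real call sets depend
on upstream alignment and calling quality, which are out of scope.

## Panel calling and promoter scanning

Panel lines are treated as homozygous; a line is called by which core
haplotype (allele ± 20 bp of anchor sequence) its local slice contains,
tolerating incidental SNPs outside the core; sequences matching neither
haplotype, or too short to span the locus, are `missing`. Frequencies
are alternate calls over non-missing calls.

The motif table ships with PLACE-style consensi for the nine abiotic
stress element classes (ABRE, CAAT box, DPBF, GAGA, GBOX, IBOX, ROOT,
SEF3, SEF4) as editable convenience — element families vary by database
entry, so analyses needing exact definitions should supply their own
table; the scanner itself is exact IUPAC-consensus matching, both
strands by default, all overlapping occurrences counted once per
position (palindromic consensi are not double-counted on the reverse
strand). The promoter window is anchored at the gene-span start
(translation vs transcription start is not distinguished in the source
material); it is a parameter, as are the quality threshold, promoter
length, concordance tolerance and read-through limit, all surfaced in
the CLI with defaults printed in `--help`.

## Numerical and scale choices

The default study (500-kb chromosomes, 40 genes, 242 planted variants,
50-line panel) makes the complete pipeline — simulate, summarize, mine,
annotate, screen, panel, promoter — run in a few seconds on one CPU,
which keeps the full end-to-end truth-recovery check cheap enough to run
on every test invocation. Brute-force oracle comparisons (interval
overlap, motif scanning, ORF enumeration, set-algebra polymorphism) use
1000+ random instances. The acceptance targets use backbone sizes taken
from the published protein lengths (108–765 codons) with alanine (GCC)
filler codons, chosen so that no junction codon can form a stop; the
construction verifies this and fails loudly rather than silently
shifting an allele.

## Known limitations

- Start-gain detection requires a stop-free in-frame path from the new
  ATG to the annotated start; leaky scanning/reinitiation are not
  modelled.
- Primer design is positional only (no melting-temperature or
  specificity checks); wet-lab validation is out of scope.
- The concordance filter relies on anchor colinearity; inversions or
  translocations between assemblies would need an external liftover.
- ORF finding scans forward frames by default; the reverse strand is
  optional and reports frame indices 3–5 without coordinate remapping.
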