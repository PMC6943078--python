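# Methods

## Scope and model

`allelekit` quantifies the evidence behind an inferred (novel) germline
allele using only two inputs that any AIRR-seq analysis already has: a
germline reference set and a table of annotated rearrangements.  It assumes
annotation has already happened — every read carries V/D/J allele calls and
an IMGT-gapped alignment — and asks how the repertoire behaves *given* those
calls.  Running an annotator, or computing IMGT gaps de novo for an
ungapped V sequence, is out of scope: candidate novel V alleles must be
supplied pre-gapped on the same frame as the reference.

The genotype is defined as the set of alleles that lead to expressed
productive rearrangements, so every statistic is computed after a
productivity filter.  Non-productive reads contribute to nothing, including
the diagnostic panels.

## Coordinates

All coordinates are 1-based and inclusive.  V genes live on the IMGT-gapped
frame: positions are gapped column numbers, comparable across genes, with
gap columns shown as `.` (`-` in input FASTA is accepted and normalized).
D and J genes are numbered from the start of the coding sequence.
Substitutions are written `<ref><pos><alt>` (`G112A`); amino-acid changes
use the codon number in the same frame (`A96N`).  Codons containing a gap
or N translate to `X` and are excluded from amino-acid difference lists, so
no amino-acid change is ever fabricated at a gap column; D genes have no
fixed reading frame and their amino-acid fields stay empty.

## Assignment and exact matching

A read is *assigned* to the first allele of its (possibly comma-separated)
call string.  Reads with ambiguous calls count toward `sequences` for that
first allele but are excluded from all exact-match statistics — an
ambiguous exact match would otherwise be double-counted across the listed
alleles.  Productivity strings `T/F`, `TRUE/FALSE`, `true/false`, `1/0` are
recognized; anything else is treated as non-productive with a warning.

A read is *unmutated* for an allele when its aligned segment region equals
the germline sequence over the read's covered extent.  Concretely: columns
gapped in both sequences are skipped; a gap opposite a base counts as a
difference; N counts as a mismatch; and the comparison stops at the end of
the shorter extent — the 3′ tail for V genes (junction trimming makes the
final nucleotides uninferrable from rearranged reads) and symmetrically the
5′ end for J genes.  The V region inside `sequence_alignment` is delimited
by the optional AIRR `v_germline_end` column (1-based gapped column of the
V 3′ end); without it the whole alignment is treated as the segment region.
The comparison only covers the studied segment — junction nucleotides are
non-templated and never compared.

The exact-match comparator is shared between the genotype statistics and
the distance histogram of panel C, which is what guarantees that the
histogram's bin 0 equals `unmutated_sequences` for every allele.

Novel submitter names (no `*` designator, e.g. `IGHV_S1`) form their own
provisional single-allele gene for the `allelic_percentage` denominator
until a gene assignment exists.

Alleles called in the reads but absent from the reference set still get a
report row (their reads cannot be checked for exact match and count as
mutated); the discrepancy is logged and listed in the run manifest.

## Closest-reference annotation

`nt_diff` fields use the gapped Hamming distance over the shared extent.
`closest_reference` searches all non-novel alleles of the segment;
`closest_host` only those present in the subject's genotype, so
`nt_diff_host ≥ nt_diff` by construction.  Distance ties break to the
lexicographically smallest allele name, making reports deterministic.

## Haplotype anchoring

A heterozygous partner-segment gene (e.g. IGHJ6 with \*02/\*03) splits reads
into the two chromosomal haplotypes.  Detection: a gene qualifies as an
anchor iff exactly two of its alleles each hold ≥ `min_minor_fraction`
(default 0.2) of the gene's reads and the gene total is ≥ `min_total`
(default 100).  Detection counts only reads unmutated in the studied
segment, because hypermutation drives misassignment and distorts allele
ratios; the split itself (panel E) counts all assigned reads.  Reads
calling other alleles of the anchor gene, or other genes of the anchor
segment, are excluded from the split.

Exclusivity: an allele is flagged exclusively associated iff it has
≥ `min_reads` (default 10) reads on one haplotype and zero on the other;
the ratio min/max is reported alongside.  The defaults are deliberately
strict — a single read on the minor haplotype removes the flag — because
exclusive association is qualitative evidence, not a statistic with an
error model.  All thresholds are CLI-configurable.  When several genes
qualify, all are reported and the genotype's `haplotyping_gene` field joins
their names with commas.

## Diagnostic panels

Panel A projects each assigned read onto the allele's gap frame, masking
bases with Phred quality below `qual_threshold` (default Q20) as `-`;
positions beyond a read's covered extent render as `.`.  Panel B restricts
panel A to the last 8 non-gap columns (V) or the first 8 columns (J);
the width is configurable.  Panels are emitted both as CSV tables — which
is what the tests assert on — and as images with fixed, deterministic
layout; pixel-level styling is explicitly not a goal.

## The simulator

The generator emulates the data-generating process the statistics assume,
with exact ground truth: per-read true allele, true mutation count and
true haplotype.  Per molecule it samples a V allele by usage weight; a J
allele by usage weight, unless the V allele is linkage-mapped to one anchor
allele (emulating a novel allele resident on a single chromosome); a 3′ V
trim length (default distribution 0/1/2/3 nt with probabilities
0.4/0.3/0.2/0.1); substitutions independently per covered non-gap position
at the stated per-base rate (never in gap columns), which makes per-read
mutation counts Binomial(covered length, rate); a random CDR3/junction; a
random 12-mer UMI; and a PCR duplicate with probability `umi_dup_rate`
(default 0.2) sharing UMI and mutation pattern.  A fraction of molecules
(default 0.05) is marked non-productive to exercise the genotype filter.
Per-base qualities are Q40 with a 0.02 fraction of Q2 bases — enough to
exercise the low-confidence mask; the flat two-level model does not imitate
real quality profiles.  Emitted calls are the true alleles: the fixtures
validate the statistics, not an annotator, because the statistics
presuppose an upstream annotator anyway.

The stock study conditions are 10,000 reads at 1% per-base mutation rate
over a genotype of two alleles in each of three V genes plus one novel
allele, `IGHV_S1` = IGHV1-69\*01 + G112A at 10% usage, linked exclusively
to IGHJ6\*03 of a 50/50 heterozygous IGHJ6 anchor; a homozygous variant of
the same configuration exists for negative controls.  At a 1% rate only
about 5% of reads are unmutated (0.99^288), which is why anchor detection
on unmutated reads needs repertoires of a few thousand reads — an intended
property, since real repertoires are rarely smaller.

The synthetic germline is generated deterministically: three V genes with
two alleles each on a shared 312-column codon-aligned frame with two gap
blocks (columns 79–90 and 172–183; real IMGT gap patterns vary per gene,
but per-gene variation adds nothing to the statistics under test), IGHJ6
\*02/\*03 differing at two positions, IGHJ4, and two D genes.  What the
simulator does not model — and what passing tests therefore do not speak
to — includes annotation errors and call ambiguity, clonal lineage
structure (every molecule is independent), D/J trimming and N-region
realism, indel hypermutation, and realistic quality profiles.

## Numerical and serialization choices

Internal computation is in full precision; percentages are rounded half-up
to 2 decimals only at CSV serialization.  Undefined values (no UMI column,
zero denominators, reference alleles' difference fields) render as empty
cells, never 0.  The genotype CSV header is the standard field order,
byte-exact.  `unique_cdr3s` counts `junction_aa` strings when the column
has data, else `cdr3` nucleotides; the choice is recorded in the run
manifest.  Everything is deterministic: identical inputs (or identical
simulator seeds) give byte-identical outputs.

## Validation strategy

Counts are validated two ways on simulated repertoires: exact equality
against the generator's tallies (which use its knowledge of true mutation
counts, not sequence comparison), and equality against an independent
brute-force recount implemented separately from the library path.
Normalization (allelic percentages summing to 100 per gene, unmutated
frequencies summing to 100 overall), anchor detection on heterozygous vs
homozygous subjects, exclusivity of the linked novel allele, and
histogram/genotype consistency are asserted end to end.
`scripts/acceptance.py` reruns all of this from scratch at a given seed and
writes the measured quantities as JSON.
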