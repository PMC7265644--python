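# Methods

This note documents the models, parameters and numerical choices behind
`refcurate`, and what the synthetic-data tests do and do not demonstrate.

## Alignment primitives

**Anchor aligner.** All whole-sequence placements (contig tiling, gap-fill
flanks, site liftover, SV regions, paralog search) use a deliberately
minimal aligner: k-mers (default k = 21) that occur exactly once in the
query *and* exactly once across the whole target assembly are collected as
anchors and chained greedily — an anchor extends a chain when it is
co-linear, its diagonal moves by at most 2 kb (the indel budget) and the
positional gap is at most 5 kb. Both strands are searched via the reverse
complement. Chains report `matches` as the union of anchored bases, so
chain identity is a conservative lower bound; with `refine=True` the chain
span is re-aligned at base level and carries exact counts plus an edit
path. There is no gapped extension beyond the chain span: production users
can substitute PAF from any external aligner, and every stage accepts
alignment records rather than requiring this aligner.

**Pairwise alignment** is unit-cost edit-distance alignment (edlib),
chosen over an affine-gap scorer because every decision made on it is a
threshold on coverage, identity or net length, none of which benefits from
affine costs at the divergences involved (≤ a few percent). Identity is
defined as `(L − d)/L` with `L` the longer sequence and `d` the edit
distance. This definition is symmetric in the two sequences and invariant
under joint reverse complement; a per-column definition is neither,
because optimal alignment paths are not unique. Coverage of the first
sequence is the fraction of its bases in match/mismatch columns of the
returned path.

## Synthetic study system

The generator draws every quantity from one seeded NumPy generator, so a
(seed, config) pair is byte-reproducible. Defaults define the study
conditions; all sizes were fixed once at values that keep a full run on
one CPU in tens of seconds while leaving every rule with real work:

- **Genome**: 2 chromosomes × 500 kb of uniform-random sequence, with 2
  planted exact repeat pairs (3 kb — long enough to defeat unique anchors,
  shorter than the chaining gap budget) and 2 donor N-gap placeholders
  (800 bp) standing in for gaps in the finished donor itself.
- **Small variants**: SNVs at 1×10⁻³ per bp, indels (1–10 bp) at 1×10⁻⁴ —
  the divergence scale of two human haplotypes. 60% of SNV sites carry
  population allele frequencies drawn from a mixture with 70% of mass
  above 0.5 (sites where the population major allele differs from the
  donor) and the rest below; genotypes are drawn from the AF under
  Hardy–Weinberg, which is what makes the AF-binned match proportion rise
  with frequency. Sites reported in fewer than 200 individuals and
  multi-base rows are added as filter fodder.
- **Structural variants**: 40 insertions/deletions of 50–400 bp (1:1 mix),
  45.6% homozygous, placed clear of genes and repeats except for planted
  whole-gene deletions. Placement margins keep SV flanks alignable so the
  presence assay tests the assay, not the placement.
- **Translocation**: one reciprocal terminal-segment exchange with
  breakpoints 2.5–5 kb from the chromosome ends (the terminal ~1%),
  homozygous, with at least one gene planted inside each exchanged tail.
- **Fragmentation**: the consensus haplotype (haplotype 1 — the assembly
  records one haplotype) is cut into ~40–60 kb contigs; a configured
  number of cross-chromosome chunk pairs are concatenated as chimeras;
  withheld intervals (4–10 kb) are dropped entirely and become the gaps
  the donor fill must close, one of them deliberately straddling a donor
  N-gap so it can only be filled by the contig-fitting step.
- **Coverage**: 30× ± 3 jitter in 1-kb bins; a 4-kb window centered on each
  chimeric junction at 2× (dropout). 200 consensus errors (substitutions)
  are planted inside the benchmark regions: 10% within 30 bp of a true
  variant and 10% inside excluded regions, the rest correctable.
- **Annotation**: 20 genes, 1–3 exons of 30–90 codons with codon-aligned
  boundaries (so exon-skipping isoforms stay in frame), up to 3 isoforms.
  CDS bases are written into the reference so every source CDS translates
  cleanly. One gene is deleted from the sample but a ~98.5%-identical
  unannotated copy is planted elsewhere (the paralog case); one gene loses
  60% of its exonic bases to a deletion (the truncation case).

**What the generator does not emulate**: read-level noise, mapping bias,
segmental-duplication families beyond exact repeat pairs, tandem repeats,
complex SVs, compound heterozygotes, or assembly artifacts other than
fragmentation, chimerism and planted substitution errors. Green tests
therefore show the *rules* are implemented exactly and recover planted
truth under clean conditions; they do not certify performance on real
repeat-rich genomes.

## Stage-specific choices

**Duplicate filter.** Containment requires alignments to a single larger
partner covering ≥ 99.5% of the contig (the half-percent absorbs anchor
jitter at contig edges, which can hide up to k bases per end) with
aggregate identity strictly > 0.97. Candidate partners are prescreened
with a sparse k-mer multimap indexed every 64 bases and queried at every
query offset — sampling both sides at the same stride can miss a duplicate
whose offset is out of phase.

**Breakpoints.** Candidates are alignment ends strictly more than 5 kb
from both contig ends (alignments under 2 kb are ignored as
repeat-induced micro-hits); candidates within 1 kb merge to their median.
Confirmation scans 50 kb either side: any depth ≤ 3 confirms a weak join
and splits at the center of the first minimum-depth trough; otherwise any
depth > 35 confirms a collapsed repeat and splits at the alignment
breakpoint itself. The depth thresholds are config values and do not
auto-scale with mean coverage.

**Tiling.** A contig goes to the chromosome with the greatest summed
aligned bases (ties: lexicographic name), oriented by majority strand.
Segments order by donor midpoint; overlapping donor projections trim the
lower-identity segment. Gap sizes are donor-projection differences,
floored at 100 N because AGP requires a positive gap.

**Gap fill.** "Aligning uniquely" means the 4-kb assembly flank has
exactly one donor chain with span ≥ 2 kb at identity ≥ 0.99 (the floor
matches the harmonization stringency). Flank edges are pinned base-exactly
with an infix alignment before the donor slice is extracted, and a slice
containing N is not contiguous donor sequence (it falls through to step
2). Step 2 clips donor contigs to the gap's projected donor interval,
requires clipped fragments ≥ 200 bp, and admits a total insertion of at
most 1.1 × gap estimate + 200 bp; compatible fragments insert in donor
order, otherwise largest first. Each inserted fragment is framed by 100-N
gaps, so gap count can rise while gap length falls — monotone
non-increase of total gap length is asserted, not of count.

**Benchmarking.** Calls and benchmark records are representation-
normalized (shared-suffix trimming extended through the reference, then
shared-prefix trimming — standard left alignment) before exact
position+allele matching. A pos+allele match with discordant genotype is
an FP carrying the benchmark genotype; the FP partition applies precedence
gt > al > region so every raw FP lands in exactly one bucket. Proximity is
closest start-to-start distance ≤ 30 bp. QV uses log base 10 (Phred
convention); zero modified FPs return a configurable cap (90) with a
no-error flag instead of infinity. The built-in caller walks refined
anchor-chain alignments and suppresses events within 10 bp of an N on
either sequence; an optimal edit path may fragment a multi-base insertion
into cost-equal pieces, which is why near-variant representation artifacts
are absorbed by the proximity bucket rather than "corrected".

**Corrections** are applied right-to-left per chromosome; an edit whose
assembly span no longer matches its expected bases (overlap with an
earlier edit) is deferred with a warning rather than applied blindly.

**SV assay.** Present = best chain's region re-located by infix alignment
with ≥ 95% coverage, ≥ 99% identity, and |observed span − expected
region length| ≤ 10 bp. The length check is what distinguishes a het
deletion carried on the other haplotype (flanks align, spacing off by the
SV length) from a true presence. A region with no anchor chain at all,
whose variant-free version also fails to anchor, is reported ambiguous
(tandem-repeat context) rather than absent.

**Harmonization.** Site selection: count ≥ 200, AF strictly > 0.5,
single-base alleles, major ≠ donor reference. The 2-kb window lift keeps
chains with span ≥ 1980 and identity ≥ 0.99; best = highest identity,
then longest span, then lowest target coordinate. Sites lifting through a
minus-strand chain have alleles complemented. A site whose base falls in
a gap column of the lift has no single-base image and counts unmapped.
Heterozygosity evidence comes from a genotype VCF (the minimal contract
standing in for consulting raw read data); edits only ever install the
site's major allele and only where that genotype contains it, which is
what makes the operation idempotent. AF bins follow the selection
convention, half-open on the left: (0.5,0.6] … (0.9,1.0]; a sub-0.5 bin
appears only if selection is run with the AF filter disabled.

**Annotation QC.** Transcript status: mapped at coverage ≥ 50% of the
source mRNA, partial below, unmapped with no placement. Consequence
precedence (most consequential wins): unmapped > truncated > frameshift >
stop gained > stop lost > start lost > in-frame insertion > in-frame
deletion > missense > identical; the order beyond "a premature stop
outranks missense" is this package's fixed convention and is printed in
report headers. Frameshift is judged on net CDS length change mod 3, so a
compensating indel pair downstream reads as an in-frame event with an
altered stretch — a deliberate simplification consistent between the
classifier, the generator's truth labels, and the codon-walk oracle in
the tests. "Truncated" is tied to partial mapping status, not inferred
from alignment ends. Start-loss means the target CDS does not begin with
ATG; alternative starts are not honored. Subtelomere flagging uses the
terminal 1% of the chromosome with a 5-kb absolute floor, since real
subtelomeres do not shrink with assembly size. Gene-level disruption
requires *every* isoform to carry a disrupting category.

## Problem sizes

The default study conditions (2 × 500 kb, ~1000 small variants, ~35 SVs,
10 chimeras in the acceptance runs, 200 planted errors, ~400 qualifying
population sites, 20 genes) were chosen so that each rule is exercised
with two-digit event counts and the full pipeline, test suite and
acceptance script each complete in a few minutes on a single CPU.
Harmonization's monotone AF-bin property is checked pooled over five
seeds because single-seed bins hold only ~80 sites each.

## Known limitations

- The anchor aligner has no gapped extension; highly diverged or
  repeat-dense regions yield fragmented chains. Import external PAF for
  real genomes.
- The caller reports one haplotype (the consensus); it is a benchmarking
  device, not a variant caller.
- Translocated tails are tiled to their donor-homologous chromosome, so
  the assembled chromosomes follow the donor's layout; the translocation
  is surfaced by annotation QC, not preserved in the tiling.
- Consequence classification assumes the standard genetic code and a
  clean source CDS.
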