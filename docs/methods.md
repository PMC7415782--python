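# Methods

This note documents the models and algorithms implemented in `wgacompare`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## K-mer genome profiling

Reads are decomposed into canonical k-mers (lexicographic minimum of the
k-mer and its reverse complement; k odd so no k-mer is self-complementary;
default k = 19). Windows containing N are excluded, as are reads shorter
than k (counted and reported). Counting is an exact in-memory hash — the
package targets desk-scale data, not production sequencing runs, and gives
up disk-backed or probabilistic counting in exchange for exactness.

From the depth histogram:

* **Main peak** — the depth with the most distinct k-mers among depths
  ≥ `min_depth` (default 4, excluding the sequencing-error spike at depth
  1–3); ties break to the larger depth.
* **Genome size** — GS = total k-mer instances / peak depth, rounded to
  the nearest base. "Average k-mer depth" is read as the main-peak depth:
  the alternative (mean depth over all k-mers) is inflated by the error
  spike and by repeats and is not recoverable from a peak-style summary.
* **Repeat threshold** — 2 × peak + 1; instances deeper than this are
  attributed to repetitive sequence, and the repetitive fraction is their
  share of all instances. The threshold generalizes the one printed
  instance (115 at peak 57) and is monotone in the peak.
* **Heterozygosity** — heterozygous sites produce k-mers at roughly half
  the homozygous depth; the estimator takes the fraction of instances in
  the window [0.4×peak, 0.6×peak] and divides by 2k (each heterozygous
  site affects up to k overlapping k-mers on each haplotype). This simple
  mass estimator is validated only by recovery on simulations (homozygous
  genomes give ≈ 0); it is not calibrated against any published value.

Read simulation note: a read of length L covers L−k+1 k-mer instances, so
the expected k-mer depth is coverage × (L−k+1)/L. GS is insensitive to
this factor (it cancels between total and peak), but tests that pin the
peak near the nominal coverage use long (1 kb) reads.

## Whole-genome alignment

**Anchors.** Maximal exact matches unique in both genomes (MUMs) of length
≥ 40, found with a suffix array (numpy prefix-doubling, O(n log² n)) over
the concatenated genome pair; adjacent-suffix LCPs come from the retained
rank levels. A match is a MUM iff its two suffixes are SA-adjacent, their
LCP is the match length, both outer LCPs are shorter, and the preceding
characters differ. Uniqueness is per strand pass (forward, and reference
vs reverse-complemented query); N bases and chromosome separators are
encoded as position-unique symbols and can never match.

**Chaining.** Per (reference chromosome, query chromosome, strand), the
maximum-weight chain of anchors (weight = anchor length) is extracted
repeatedly until the best remaining chain drops below 90 bases, so
secondary collinear runs — translocated or inverted segments — become
their own blocks. Chain order requires strictly increasing starts on both
axes; anchor ends may overlap the successor by ≤ 50 bases (breakpoint
ambiguity), trimmed at emission. Instances up to 200 anchors use an exact
quadratic DP whose tie-break minimizes total diagonal drift, then prefers
the lower (ref, qry) start; larger instances use an O(n log n)
Fenwick-tree sweep that is weight-optimal with the positional tie-break.
Chains are split, never force-aligned, where the gap on either genome
exceeds `max_gap` (1000) or the two gap sizes differ by more than `band`
(200).

**Gap closing.** Inter-anchor gaps are aligned globally with edlib
(Myers bit-vector, unit-cost edit distance), giving exact `= X I D`
run-length paths at C speed. Unit costs can fragment a long indel into
equal-cost pieces interleaved with single matches; this is accepted for
block construction (indel recall on simulations remains ≥ 0.95) — the
promoter comparator, where contiguous gaps are the point, uses a true
affine-gap aligner instead (match +1, mismatch −1, gap of length g costs
4 + g).

**Filtering and one-to-one selection.** `filter_blocks` keeps blocks with
identity ≥ `min_identity` and reference span ≥ `min_len` (the 80 / 20000
defaults suit a synteny view; variant calling relaxes them). `one_to_one`
runs weighted interval scheduling (weight = reference span × identity)
on reference coordinates and then on query coordinates of the survivors,
in that fixed order. Blocks conflict only when they overlap by more than
100 bases; smaller boundary overlaps are resolved by trimming the lighter
block's edit path rather than discarding multi-kb blocks over a 1–2 bp
breakpoint ambiguity. After both passes no base of either genome is
covered twice (enforced by `check_one_to_one`).

## Variant calling

Walking each one-to-one block's edit path yields one SNP per mismatch
column and one indel per maximal gap run. Query bases and coordinates are
strand-adjusted: reverse blocks report the complement of the query base on
the reference forward strand. Indels are left-aligned in their reference
context (the VCF convention; the simulator normalizes its truth records
identically, and recovery matching still allows ±1 bp plus exact length to
absorb residual ambiguity in repeats). SNPs adjacent to gap columns are
kept by default; `mask_near_gap=N` excludes SNPs within N columns of an
indel for sensitivity analysis. Densities are count/(size/1000) at one
decimal, round half away from zero; the 12-type substitution spectrum
carries counts and fractions, with an explicit zero-total flag.

## Structural variants

* **Inversions** — a run of reverse-strand blocks whose nearest
  forward-strand blocks on both sides (same chromosome pair) both have
  identity ≥ 90% (the "well-aligned flanks" rule made quantitative);
  runs with reference gaps ≤ 50 bp merge into one record. Merged records
  whose reference and query spans disagree by more than 20% are dropped —
  a deterministic stand-in for the manual curation a human would apply.
* **Translocations / relocations** — per reference chromosome, the
  backbone is the maximum-weight collinear chain of forward blocks
  (weight = span × identity), and the dominant partner chromosome is the
  one carrying the heaviest backbone. Any off-backbone forward block with
  length > 100 bp and identity > 90% (strict) is reported: translocation
  when its query chromosome differs from the dominant partner,
  relocation when it is the same chromosome but breaks collinear order.
  The inter/intra-chromosomal split is this package's disambiguation of
  "a fragment in different locations"; records keep their support blocks
  so users can re-bin. Reverse-strand blocks consumed as inversion
  support are excluded, so no event is double-reported.

## Gene-anatomy regions

Genes decompose into exons, introns (the exon gaps), a promoter
(2 kb upstream of the 5′ UTR start, strand-aware, truncated at chromosome
ends) and a downstream region (1 kb beyond the 3′ UTR). Genes lacking a
UTR fall back to the CDS boundary and are recorded. Membership is any
overlap (≥ 1 bp); precedence mode assigns each element one category
(exon > intron > promoter > downstream > intergenic — gene-body evidence
wins), multi mode tallies every overlapped category. Paired per-gene
counts across an ortholog map are compared with an exact two-sided sign
test on non-tied pairs; the test is this package's choice where the
original comparison names none, and is reported as such in the output.

## Molecular evolution

* **Codon alignments** are built by globally aligning translated proteins
  (BLOSUM62, gap open −10 / extend −0.5) and threading codons back, so
  gaps occur only in whole-codon units; gap- or stop-containing codon
  pairs are excluded from statistics.
* **4DTv** — a site counts only when both codons share an identical
  fourfold-degenerate dinucleotide prefix (TC, CT, CC, CG, AC, GT, GC,
  GG); the statistic is the fraction of such sites whose third bases
  differ by a transversion. Zero 4D sites is reported as undefined, never
  as 0. The optional correction −½ ln(1 − 2·raw) (the transversion
  component of a Kimura-style two-parameter model) is stored alongside
  the raw value.
* **Ks** — Nei–Gojobori (1986) counting: per-codon synonymous site counts
  (normalized so S+N = 3, mutations to stop codons counted as
  nonsynonymous — the convention of widely used implementations) averaged
  over the two sequences; pathway-averaged synonymous differences for
  codons differing at 1–3 positions; Jukes–Cantor correction
  Ks = −¾ ln(1 − 4/3 ps). ps ≥ ¾ is reported as +∞ with a saturation
  flag; fewer than 30 codon pairs flags low confidence. NG86 was chosen
  over ML estimators because it is deterministic and directly checkable
  against an independent pathway-enumeration oracle.
* **Ks peaks** — Gaussian KDE (Silverman bandwidth) on values in [0, 3];
  modes need prominence ≥ 5% of the global maximum *and* height ≥ 2× the
  flat-background density over the data range. The flatness guard exists
  because a bounded-support KDE of near-uniform data always shows one
  interior bump of large relative prominence; without it a structureless
  distribution would always yield a "peak". Fewer than 50 finite values
  returns "insufficient".
* **LTR ages** — the element's two terminal repeats are globally aligned
  (affine); K is the Jukes–Cantor distance over non-gap columns and
  age = K / (2μ). μ defaults to 1.3×10⁻⁸ substitutions/site/year — a
  conventional plant neutral rate, recorded on every result since ages
  scale inversely with it. Pairs under 100 bp or below 60% identity are
  refused rather than dated.
* **Ortholog pairing** — gene midpoints are mapped through the one-to-one
  blocks (linear within a block; drift from indels is far below the
  10 kb matching radius) and paired by best-reciprocal distance.

## Synthetic data

The generator emulates a pair of diverged megabase-scale genomes: an
ancestor with i.i.d. bases at a set GC content and uniformly placed,
non-overlapping genes (2–5 exons, UTRs, valid CDS with start/stop and no
internal stop), evolved per descendant by (1) structural events planned on
ancestor coordinates — inversions, translocations (inter-chromosomal
moves), relocations (moves ≥ 10 kb within a chromosome), TE insertions
(LTR elements as 5′LTR–internal–3′LTR with the repeats identical at
insertion, then mutated independently at `ltr_divergence`) — assembled
through an explicit segment map; (2) small indels (geometric sizes,
p = 0.5, capped at 50 bp, positions spaced ≥ 60 bp); (3) SNPs with a 2:1
transition:transversion weighting. Structural events never overlap each
other — how nested rearrangements should compose is genuinely ambiguous,
so the simulator refuses to guess. Truth records carry exact coordinates
in both genomes; edits with no counterpart (inside novel insertions,
across structural breakpoints, or indels in inverted context) are flagged
unaligned and excluded from recovery denominators. Reads are uniform,
strand-symmetric, with i.i.d. substitution errors and constant quality.

Not emulated: recombination, gene duplication/loss, diploid heterozygous
genomes, sequencing-error profiles and quality models, nested/overlapping
rearrangements, and realistic repeat landscapes beyond the implanted TE
families. Passing recovery tests therefore demonstrates correctness of
the algorithms under clean divergence of the stated classes — not
performance on real assemblies with deep repeat structure.

## Problem sizes and validation scales

Recovery checks run at the scale the methods are designed for: variant
recovery on a 5 Mb pair (two 2.5 Mb chromosomes; SNP rate 0.005, indel
rate 0.0005, seed 42), SV recovery on a 5 Mb pair with 10 inversions
(2–20 kb), 5 translocations and 5 relocations over a 0.002 SNP background,
k-mer recovery on 1 Mb at 50× error-free coverage, and Ks recovery on
10,000 codons at true Ks 0.1. Combinatorial kernels (chain selection,
one-to-one selection, region classification, NG86 counting) are checked
for exact equality against exhaustive or brute-force oracles on small
fuzzed instances.

## Published-value check

All derived numbers the source study prints alongside their inputs
(repeat-class percentages, the genome-size and repeat-threshold k-mer
figures, variant densities, GO fractions, the attribution of the
genome-size difference to repeat content) are recomputed from a bundled,
SHA-256-checksummed constants table and compared at printed rounding
(two decimals half-away-from-zero for percentages, one decimal for
densities). One value — the genome-wide TE fraction printed as 43.36% —
is not exactly reproducible from the printed inputs (they give 43.37%;
the original likely divided by the exact assembly length rather than the
rounded 270.3 Mb) and is reported informationally rather than as a hard
check. The bundled table's class-row lengths are never summed: only
printed totals are used.

## Known limitations

* The aligner's suffix array is in-memory numpy; practical up to tens of
  megabases per genome pair, far from the 100 Mb+ scale of real plant
  chromosomes.
* Unit-cost gap closing can split long indels inside blocks (see above).
* One transcript per gene (longest CDS); multi-isoform region definitions
  are out of scope.
* The heterozygosity estimator is deliberately simple and validated only
  on simulations.
* SV classification trusts the one-to-one block geometry; read-level
  evidence, copy-number changes and nested events are out of scope.
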