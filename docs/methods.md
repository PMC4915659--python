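# Methods

## The problem

A long-read cDNA library is a mixture of genuine full-length molecules and
5'-truncated ones (RNA degradation, mechanical shearing, incomplete
first-strand synthesis). Because truncation removes the 5' cap,
cap-dependent adapter ligation captures predominantly 5'-intact molecules,
whereas template-switch chemistry captures whatever 5' end the reverse
transcriptase reaches. `flreads` quantifies this contrast from spliced
read alignments against an annotation, and ships a generative simulator of
both chemistries so every statistic can be validated against per-read
ground truth.

## Coordinate conventions

All internal coordinates are 0-based half-open on the forward strand.
GFF3 (1-based inclusive) is converted on read; PAF is taken as-is. The 5'
and 3' ends of genes and reads are strand-aware: on the minus strand the
5' end is the rightmost genomic coordinate. Spliced block structure
travels in the standard `cg:Z` CIGAR tag of PAF lines (M/D/N consume
reference; N opens a new block); a line without a CIGAR is one gap-free
block. PAF is the reference input format; a SAM/BAM adapter
(`read_bam`) CIGAR-walks alignments into the same records, deriving
matches from the NM tag.

## Read classification

* **Identity filter.** `identity = matches / alignment_block_length` (PAF
  columns 10/11); the threshold 0.90 is inclusive — a read at exactly 90%
  survives.
* **Multiplicity.** Counted per read across alignment lines *after* the
  identity filter: one surviving line ⇒ unique, several ⇒ multi (excluded
  from FL/offset analyses), none ⇒ filtered; manifest reads never seen ⇒
  unaligned.
* **Target assignment.** Candidates are same-chromosome, same-strand gene
  models with ≥ 1 bp of exonic overlap with the alignment blocks; the
  maximal exonic overlap wins. Ties break to the lexicographically
  smaller gene id and are flagged. Strand agreement is required because
  orientation-resolved cDNA reads aligning antisense to a gene are not
  evidence for that gene; they surface as unassigned.
* **Offsets.** Measured from alignment ends (not clipped read ends), in
  transcript orientation: negative 5' offset = read starts upstream of
  the TSS; positive 3' offset = read ends downstream of the TES.
* **Full length.** `read_length ≥ spliced_length` of the assigned mRNA
  (inclusive at equality). The comparison uses spliced (mRNA) length, not
  genomic span — cDNA reads are spliced, so a genomic-span criterion
  could never be met for intron-containing genes. When a gene has several
  mRNAs, the mRNA whose exons the read was assigned to is the target.
* **Size fractions.** Half-open, low-inclusive bins: `[1000,2000)` →
  1–2 kb, `[2000,3000)` → 2–3 kb, `[3000,6000]` → 3–6 kb, plus `sub1k`
  and `over6k` edge labels for data that was not gel-fractionated.

## End-offset profiling and the protocol test

Offsets are histogrammed in half-open bins (default 50 bp) with one bin
edge exactly at 0, within a ±10 kb window; offsets outside the window are
tallied separately. The Mann-Whitney statistic is `U = min(U_a, U_b)`
with `U_a = #{(a,b): a < b} + ½·#ties`. The exact two-sided p-value is
defined by permutation: `P(min(U_a, U_b) ≤ U_obs)` over all `C(n+m, n)`
equally likely labelings of the pooled sample.

* Full enumeration is used whenever `C(n+m, n) ≤ 1e5` (ties handled
  exactly).
* For larger tie-free samples, `exact` mode uses the classical
  U-distribution counting recurrence `f(i,j,u) = f(i−1,j,u−j) +
  f(i,j−1,u)`, which is mathematically identical to enumeration.
* Otherwise a normal approximation with tie-corrected variance and a
  continuity correction of ½ toward the mean is used (`auto` picks
  enumeration or the approximation).

The test is two-sided; the tested quantity is the offset sample itself
(5' and 3' separately), over all assigned unique reads — the ±10 kb
window restricts plots and histograms only. No multiple-testing
correction is applied across the 3 fractions × 2 anchors by default; an
optional Bonferroni flag scales the per-fraction p-values.

## Redundancy clustering

Within each (gene, strand) group — unassigned reads are grouped by
overlap of their alignment spans per (chromosome, strand) — two reads are
linked when their 5' ends differ by ≤ 100 bp *and* their 3' ends by
≤ 5 bp (both inclusive; ends compared in transcript orientation).
Clusters are the connected components of this graph, i.e. true single
linkage. Consequence of chaining: a cluster's extreme members can differ
by more than the tolerance; this is the standard transcript-collapse
behaviour and is deliberate. The implementation uses a sorted sweep with
union-find and is order-independent; tests verify equivalence with a
brute-force pairwise-graph oracle. Redundancy is
`100·(n_reads − n_clusters)/n_reads`; the representative of a cluster is
its longest member.

## Homeolog resolution

A read is homeolog-ambiguous when its alignments (primary plus secondary)
hit ≥ 2 members of the same declared homeolog group. Resolution applies
the inclusive 90% identity filter, then keeps the candidate(s) minimizing
`d = read_length − alignment_length`. By default `d` uses the read-side
aligned length (PAF column 11), which penalizes the aligned-base loss
caused by homeolog sequence divergence; a target-side variant (sum of
genomic block lengths) is available via `side="target"`. A unique minimum
resolves the read; ties remain ambiguous — the resolver never guesses.
Resolved reads are reported separately and not promoted into the unique
set by default, since the main FL/offset analyses discard multi-mapped
reads; `promote_resolved` opts in to re-classifying them against their
resolved gene.

## Isoform classes

The intron chain of a read is the ordered list of gaps between its
alignment blocks. Classification, in order of precedence:

1. `known` — multi-exon read whose chain equals a same-strand overlapping
   transcript's chain. Junction coordinates must match exactly by default
   (`junction_fuzz = 0`); a configurable fuzz exists because long-read
   aligners wobble at junctions.
2. `novel_isoform` — shares ≥ 1 exact junction with such a transcript but
   the chains differ. A chain that is a contiguous sub-chain of the
   annotated chain (typical 5'-truncated read) is additionally flagged
   `contained` for transparency, but still counts as novel rather than
   known.
3. `mono_exon_contained` — single-exon read fully inside one annotated
   exon (any strand).
4. `other` — exonic overlap with an annotated gene (any strand, which
   covers antisense reads) without a shared junction.
5. `novel_locus` — no exonic overlap with any gene; purely intronic
   mono-exon reads also land here. Novel loci are counted as connected
   overlap clusters of such reads.

The classes are exhaustive and mutually exclusive; a 46-case
hand-enumerated truth battery (each case also strand-mirrored) pins the
semantics.

## The simulator

The generator emulates, per molecule:

1. **Source.** Gene drawn with log-normal abundance weights
   (σ = 1) from a toy annotation: `n_genes = 30` non-overlapping genes,
   2–8 exons, spliced lengths uniform in 800–6500 bp, introns 60–500 bp,
   intergenic gaps 2–8 kb, on 3 chromosomes, both strands.
2. **Truncation.** With `p_truncated = 0.4` the molecule loses a uniform
   (0, 0.8] share of its 5' spliced length (≥ 1 base, so cap state and 5'
   intactness coincide exactly) and is uncapped.
3. **Capture.** `cap_dependent`: capped molecules kept with
   `cap_capture = 0.95`, uncapped with `cap_leakage = 0.02`.
   `template_switch`: everything kept, plus an extra truncation-like 5'
   loss with `p_incomplete_synthesis = 0.3`.
4. **3' end.** Gaussian jitter (σ = 2 bp), rounded, clamped to ±10 bp;
   negative jitter shortens the read, positive extends the last block
   past the annotated TES (the poly-A boundary).
5. **Size selection.** Only cDNAs of 1000–6000 bp (the three gel bands)
   are sequenced (`size_selection = True`). `n_reads_per_protocol = 1000`
   is the number of molecules sampled per protocol; the library yield is
   the captured, size-selected subset.
6. **Alignment.** The read is emitted as a spliced PAF alignment computed
   by walking the exon chain from the truncated transcript interval;
   identity is `1 − error_rate` (default 0, so identity-threshold
   behaviour is exercised explicitly, not stochastically). Reads from
   homeolog triplet genes (structure-identical copies on distinct
   chromosomes, divergence `homeolog_identity = 0.97`) additionally
   receive, with probability `p_homeolog_multimap = 0.5`, secondary
   alignments to each sister locus with aligned length reduced by
   `(1 − homeolog_identity)·read_length` and identity equal to
   `homeolog_identity` — the same signal, in kind, that a real aligner
   produces for a diverged paralog.

All randomness flows from one integer seed; an identical config is
guaranteed byte-identical in its GFF3/PAF/truth outputs.

**What the simulator does not model:** base-level sequences (and hence
real alignment noise, microhomology, junction wobble), poly-A tails,
chimeras, expression-dependent degradation, internal oligo-dT mispriming,
and reference/annotation errors. Passing tests therefore demonstrate the
correctness and calibration of the *evaluation machinery* under a clean
generative model, not protocol performance on real tissue.

## Validation experiments and problem sizes

The test suite and `scripts/acceptance.py` run, at sizes chosen to keep
the whole suite in seconds on one CPU:

* Chemistry contrast at defaults, 1000 molecules per protocol: FL%
  (cap-dependent) > FL% (template-switch) and 5' Mann-Whitney p < 1e-6 in
  every size fraction with ≥ 50 reads per arm.
* Truncation recovery: with cap-blind capture and every other 5'/3'
  channel silenced (`p_incomplete_synthesis = 0`, jitter 0, size
  selection off — size selection preferentially discards short truncated
  reads and would bias the estimate by construction), the non-FL fraction
  estimates `p_truncated ∈ {0.1, 0.3, 0.5}` within 3 binomial standard
  errors at n = 2000.
* Mann-Whitney: 200 random small-sample draws (with ties) against
  independent full enumeration, to machine precision; exact vs normal
  agreement within 0.02 at n = m = 30; cross-check against
  `scipy.stats.mannwhitneyu` on tie-free data.
* Clustering: 200 random ≤ 50-read instances against pairwise-graph
  connected components (networkx); inclusive boundaries 100/101 and 5/6;
  exact duplicate arithmetic `100·(k−1)/n`.
* Homeolog resolution: ≥ 500 flagged triplet reads, 100% resolved to the
  ground-truth locus (the true locus always has strictly minimal d by
  construction); constructed ties stay ambiguous.
* Determinism: byte-identical run directories for identical config+seed.

## Known limitations

* Identity is computed from PAF columns 10/11 as provided by the aligner;
  different aligners define the block length slightly differently.
* The FL criterion compares total read length with target spliced length;
  a read with long non-genomic adapter/poly-A tails could reach FL
  without covering the 5' end. On simulator output this cannot happen
  (read length equals aligned length); on real data, upstream primer
  trimming is assumed.
* Single-linkage chaining can merge end clusters wider than the
  tolerances (documented above).
* The per-gene sampling depth of the toy simulation makes redundancy
  percentages much higher than in a diverse real library; redundancy
  tests therefore assert exact arithmetic on constructed fixtures, not
  realistic magnitudes.
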