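# flreads

Evaluation of full-length transcript enrichment in long-read cDNA
libraries.

Single-molecule long-read sequencing of cDNA (e.g. PacBio Iso-Seq) can read
entire mRNA molecules, but real libraries are contaminated by 5'-truncated
molecules from RNA degradation, shearing and incomplete cDNA synthesis.
Cap-dependent chemistry (an adapter ligated to the 5' cap, the TeloPrime
principle) captures only 5'-intact molecules, while template-switch
chemistry (SMARTer principle) is cap-blind. `flreads` implements the read
evaluation used to quantify this contrast, for people benchmarking library
protocols or curating gene annotations with long reads — including in
polyploids, where reads must additionally be assigned to the correct
homeologous gene copy.

## What it computes

Given a gene annotation (GFF3), spliced read alignments (PAF) and
optionally a homeolog-group table (TSV):

* **Full-length (FL) classification** — after an inclusive ≥ 90%
  nucleotide-identity filter and a mapping-multiplicity partition
  (unique / multi / unaligned / filtered), each unique read is assigned to
  the same-strand gene with maximal exonic overlap and called FL when
  `read_length ≥ spliced_length` of its target.
* **End-offset profiling** — signed offsets of read 5'/3' alignment ends
  from the annotated TSS/TES, histogrammed within ±10 kb; protocols are
  compared per size fraction (1–2 / 2–3 / 3–6 kb) with a two-sided
  Mann-Whitney test, `U = min(U_a, U_b)`,
  `U_a = #{(a,b): a < b} + ½·#ties`, exact permutation p
  (`P(min(U_a,U_b) ≤ U_obs)` over all C(n+m, n) labelings) for small
  samples and a tie-corrected normal approximation otherwise.
* **Redundancy estimation** — single-linkage clustering of same-locus
  reads whose ends agree within 100 bp (5') and 5 bp (3'), both
  inclusive; redundancy = 100·(n_reads − n_clusters)/n_reads.
* **Homeolog resolution** — reads hitting ≥ 2 members of one homeolog
  group are resolved by best alignment match: minimal
  `d = read_length − alignment_length`; ties stay ambiguous.
* **Isoform comparison** — intron-chain classification of each unique
  read: `known`, `novel_isoform`, `mono_exon_contained`, `other`,
  `novel_locus`.
* **Library simulation** — a seeded generative model of the two
  chemistries (truncation ⇒ uncapped; cap capture vs cap-blind capture
  with extra incomplete-synthesis loss; oligo-dT 3' priming jitter; 1–6 kb
  gel size selection; homeolog triplets at ~97% identity emitting
  secondary alignments) with per-read ground truth.

## Worked example

```python
from flreads import (AnnotationIndex, SimConfig, simulate_run,
                     classify_alignments, full_length_percentage, compare_protocols)

result = simulate_run(SimConfig(seed=7))          # both chemistries, 1000 molecules each
index = AnnotationIndex(result.genes)
asg = {p: classify_alignments(recs, index, manifest=[t.read_id for t in truths])
       for p, (recs, truths) in result.libraries.items()}
print({p: round(full_length_percentage(a), 1) for p, a in asg.items()})
table = compare_protocols(asg["cap_dependent"], asg["template_switch"])
```

prints

```
{'cap_dependent': 60.1, 'template_switch': 30.1}
```

— 60.1% of the cap-selected library's uniquely assigned reads reach their
target's full spliced length versus 30.1% for the cap-blind library, and
the comparison table shows the 5' offset contrast per size fraction
(median offset 0 = reads start exactly at the annotated TSS):

```
size_fraction  n_cap_dependent  n_template_switch  median_cap_dependent  median_template_switch      p_value
        1-2kb               54                302                   0.0                   539.0 5.075866e-13
        2-3kb               93                164                   0.0                   484.0 7.200521e-16
        3-6kb              234                279                   0.0                     0.0 3.677983e-19
```

The `examples/` directory has one short script per capability; the
`flreads` console command exposes the same stages
(`simulate`, `classify`, `profile`, `redundancy`, `homeologs`,
`isoforms`, `run`) for shell use, e.g.

```sh
flreads run --config config.yaml --out-dir runs/demo --seed 7
```

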