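"""Resolve reads that align to several homeologous loci.

Homeolog triplets (~97% identical copies on three chromosomes) attract
secondary alignments. A read hitting >= 2 members of one group is flagged,
then resolved by the best alignment match: minimal d = read length minus
aligned length. The resolution is checked against the simulator's truth.
"""

from flreads import AnnotationIndex, SimConfig, resolve_homeologs, simulate_run

config = SimConfig(seed=41, n_genes=30, n_homeolog_triplets=10,
                   p_homeolog_multimap=1.0, n_reads_per_protocol=1500)
result = simulate_run(config)
index = AnnotationIndex(result.genes)
records, truths = result.libraries["template_switch"]
truth = {t.read_id: t.gene_id for t in truths}

table, summary = resolve_homeologs(records, result.groups, index)
resolved = table[table.status == "resolved"]
correct = sum(r.resolved_gene == truth[r.read_id] for r in resolved.itertuples())
print(summary)
print(f"correctly resolved: {correct}/{len(resolved)}")

print(
    "\nThe true locus aligns the full read (d=0) while sister loci lose ~3% of"
    "\naligned bases, so best-match resolution recovers the source gene exactly."
)
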