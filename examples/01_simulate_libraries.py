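"""Simulate cap-dependent and template-switch cDNA libraries.

Builds a toy multi-exon annotation with homeolog triplets, draws mRNA
molecules (some 5'-truncated, hence uncapped), and captures them with the
two chemistries. Prints the library yields and the mean 5' loss per
protocol — the core contrast: cap selection keeps 5'-intact molecules.
"""

import numpy as np

from flreads import SimConfig, simulate_run

result = simulate_run(SimConfig(seed=7))

print(f"genes: {len(result.genes)}  homeolog triplets: {len(result.groups)}")
for protocol, (records, truths) in result.libraries.items():
    lost5 = np.mean([t.bases_lost_5p for t in truths])
    capped = np.mean([t.capped for t in truths])
    print(
        f"{protocol:16s}  reads={len(truths):4d}  capped={100 * capped:5.1f}%  "
        f"mean 5' bases lost={lost5:7.1f}"
    )

print(
    "\nCap-dependent capture keeps mostly capped (5'-intact) molecules, so its"
    "\nreads lose far fewer 5' bases than the cap-blind template-switch library."
)
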