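"""Comparative summaries: Z-scores, library PCA and target-set overlaps.

Builds an antisense-rpkm matrix over six simulated libraries (three
archetypes x two stages), standardizes features, runs the deterministic
library PCA (log2(rpkm+1), top-500 variable features, SVD) and prints the
M6 target-set Venn counts for the three mRNA-targeting Argonautes.
"""

import pandas as pd

from wagoseq import (
    SimConfig,
    antisense_gene_rpkm,
    build_index,
    build_transcript_index,
    call_targets,
    generate_genome,
    pca_libraries,
    place_reads,
    simulate_library,
    venn_counts,
    zscore_rows,
)
from wagoseq.simulate import default_archetypes

sim = generate_genome(SimConfig(seed=1))
table = default_archetypes()
index = build_index(sim.genome)
tindex = build_transcript_index(sim.annotations.genes, sim.genome)

cols = {}
for arch in ("CSR1_like", "NRDE3_like", "ALG4_like"):
    for stage in ("M3", "M6"):
        sl = simulate_library(sim, table[arch], stage)
        pl = place_reads(sl.library, index, tindex)
        cols[sl.library.library_id] = antisense_gene_rpkm(
            pl, sl.library, sim.annotations.genes)
rpkm = pd.DataFrame(cols)

z, flat = zscore_rows(rpkm)
print(f"z-score matrix: {z.shape[0]} genes x {z.shape[1]} libraries "
      f"({len(flat)} flat rows set to 0)")

pca = pca_libraries(rpkm)
print("\nlibrary PCA coordinates (PC1 separates mRNA-target repertoires):")
print(pca.coordinates.round(1))
print(f"variance explained: PC1 {pca.variance_explained[0]:.1f}%, "
      f"PC2 {pca.variance_explained[1]:.1f}%")

targets = call_targets(rpkm)
m6 = {a: targets[f"M6_{a}"] for a in ("CSR1_like", "NRDE3_like", "ALG4_like")}
print("\nM6 target-set Venn region counts:")
for region, n in venn_counts(m6).items():
    print(f"  {region}: {n}")
# Late-meiosis target sets of the three mRNA-targeting Argonautes overlap
# heavily, as in the germline stage where all three are active.
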