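"""Simulate an Argonaute-IP input library and classify its reads.

Builds a reduced synthetic study (400 kb genome), simulates the total
small-RNA ("input") library for the early mitotic germline stage, places
every read on the genome and spliced transcriptome, and prints the
nine-category breakdown and the size/first-nucleotide profile summary.
"""

from wagoseq import (
    SimConfig,
    build_index,
    build_transcript_index,
    category_profile,
    classify_library,
    generate_genome,
    place_reads,
    simulate_library,
    size_profile,
)
from wagoseq.simulate import default_archetypes

cfg = SimConfig(
    seed=1,
    contig_lengths={"chr1": 200_000, "chr2": 200_000},
    mito_length=5_000,
    n_genes=40, n_dispersed_planted=10, n_dispersed_cold=10, n_tandem=10,
    n_mirna=8, n_rrna=2, n_trna=6, depth=50_000,
)
sim = generate_genome(cfg)
sl = simulate_library(sim, default_archetypes()["input"], "M1")

index = build_index(sim.genome)
tindex = build_transcript_index(sim.annotations.genes, sim.genome)
placements = place_reads(sl.library, index, tindex)
categories = classify_library(sl.library, placements, sim.annotations)

prof = category_profile(sl.library, categories)
print("category fractions (input library, stage M1):")
print((100 * prof["fraction"]).round(1).to_string())
# The repeat-antisense class dominates the total small-RNA pool (~85 %),
# the signature of WAGO-bound 22G secondary siRNAs silencing repeats.

sp = size_profile(sl.library)
print(f"\nmodal read length: {sp.modal_length} nt "
      f"(G-start fraction at mode: {sp.first_nt_fraction('G', sp.modal_length):.2f})")
# 22 nt with a strong 5'-G bias: the 22G-RNA signature.
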