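"""Find mismatched knockout genes between paired genomes.

A mismatched gene is completely inactive (two copies lost) in one genome
of a pair but still active in the other — the situation of interest when
comparing donor vs recipient after transplantation, or maternal vs fetal
genomes.  Direction A->B lists genes knocked out in B but active in A.
"""

import lofcall as lc

cfg = lc.SimulationConfig(n_samples=30, n_genes=40, seed=12,
                          hom_rate=0.03, ch_rate=0.03)
vcf, _ = lc.generate_cohort(cfg, "scratch/example_pairs")
hc = lc.filter_hc(lc.read_annotated_vcf(vcf))
gene_matrix = lc.build_gene_matrix(hc)

pairs = [("S0001", "S0002"), ("S0003", "S0004")]
for pair, directions in lc.mismatch_genes(gene_matrix, pairs).items():
    for direction, genes in directions.items():
        print(f"{direction}: {len(genes)} mismatched genes"
              + (f" e.g. {genes[0]}" if genes else ""))
# Each listed gene would be a functional difference between the two
# genomes: one partner produces the protein, the other cannot.
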