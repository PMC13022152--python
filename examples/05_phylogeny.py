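"""NJ phylogeny with TN93 distances, bootstrap support, and 60% collapse.

One representative per haplotype class is taken from a simulated cohort;
the SNP matrix (heterozygotes as IUPAC codes) feeds pairwise-deletion
distances, neighbor joining, and a column-resampling bootstrap.
"""

import sd1hap as s
from sd1hap.phylo import nj_tree, tn93_distance_matrix, vcf_to_seq_matrix

cohort = s.simulate_cohort(s.SimConfig(seed=7), n_per_class=1)
samples = cohort.accessions  # one accession per haplotype class

matrix = vcf_to_seq_matrix([r for r in cohort.variants if r.is_snp], samples)
print(f"SNP matrix: {matrix.n} taxa x {matrix.L} sites")

# sparse SNP-only matrices can saturate TN93; p-distance keeps all pairs estimable
builder = lambda m: nj_tree(tn93_distance_matrix(m, model="p"))  # noqa: E731
tree = s.bootstrap_support(matrix, builder=builder, replicates=500, seed=7,
                           collapse_below=60.0)

print(f"bootstrap replicates dropped: {tree.dropped_replicates}")
print("newick (support values label internal nodes; edges under 60% collapsed):")
print(tree.to_newick())
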