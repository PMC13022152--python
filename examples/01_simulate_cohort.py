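"""Simulate a rice accession panel over the SD1 locus with known truth.

Builds a 25-kb reference carrying the three-exon GA20ox-2 gene, edits
accessions to carry each of the 12 published haplotypes (plus GR/EQ
heterozygotes), and writes FASTA/VCF/TSV inputs for the pipeline.
"""

import sd1hap as s

cohort = s.simulate_cohort(s.SimConfig(seed=7), n_per_class=3, n_heterozygous=3)
paths = cohort.write("scratch_example_cohort")

print(f"accessions: {len(cohort.accessions)}  variant sites: {len(cohort.variants)}")
print(f"reference length: {len(cohort.reference)} bp")
print(f"gene span: {cohort.gene_model.gene_start}-{cohort.gene_model.gene_end} "
      f"(CDS {cohort.gene_model.cds_length} bp = {cohort.gene_model.cds_length // 3} codons)")
for name, path in paths.items():
    print(f"  wrote {name}: {path}")

# every accession's true haplotype is recorded, so downstream calls are checkable
labels = sorted({str(l) for l in cohort.truth.haplotypes.values()})
print(f"haplotype classes present: {', '.join(labels)}")
print("The truth set is what classifier accuracy is scored against.")
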