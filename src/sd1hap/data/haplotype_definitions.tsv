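# SD1 haplotype definitions (Nipponbare IRGSP-1.0 chromosome 1 coordinates, 1-based)
# kind: combo = residue-100/340 amino-acid state pair; point_snp = single diagnostic SNP;
#       indel = short frameshifting indel; long_deletion = multi-feature deletion.
# expected: for combo rows, the nucleotide expected at each listed site (comma-separated,
#       ref allele = G at both sites -> Gly100 / Arg340); for point rows, the alt allele.
# precedence: 1 = structural, 2 = point LOF/frameshift, 3 = residue-100/340 combination.
type_id	allele_name	kind	precedence	chrom	positions	ref	alt	expected	length	aa_detail	note
1	GR	combo	3	chr01	38382764,38385057	G,G	A,A	G,G	.	Gly100+Arg340	wild type
2	EQ	combo	3	chr01	38382764,38385057	G,G	A,A	A,A	.	Glu100+Gln340	japonica predominant
3	Jikkoku	point_snp	2	chr01	38382746	G	T	T	.	Gly94Val	.
4	Calrose76	point_snp	2	chr01	38383363	C	T	T	.	Leu266Phe	gamma-ray induced
5	Reimei	point_snp	2	chr01	38385083	G	C	C	.	Asp349His	gamma-ray induced
6	new_allele	long_deletion	1	chr01	38381879-38383157	.	.	.	1279	promoter+exon1+intron1 deletion	.
7	DGWG	long_deletion	1	chr01	38382762-38383144	.	.	.	383	exon1/intron1/exon2 deletion	linked marker C38383221T
8	9311	point_snp	2	chr01	38385064	C	A	A	.	Tyr342*	early stop
9	Aijiao-Nante	indel	2	chr01	38382846-38382847	.	.	.	2	Arg130fs	2-bp indel; encoded as deletion (text); table wording says insertion
10	Zhayeqing8	point_snp	2	chr01	38383286	C	T	T	.	Pro240Leu	.
11	ER	combo	3	chr01	38382764,38385057	G,G	A,A	A,G	.	Glu100+Arg340	reduced-function combo
12	bm	point_snp	2	chr01	38384938	C	A	A	.	Tyr300*	absent from 3K panel
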