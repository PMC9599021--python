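# Published per-locus genetic variation statistics for the 7 polymorphic SSR
# loci scored across 24 diploid red raspberry genotypes: allele count,
# expected heterozygosity (He), observed heterozygosity (Ho), and polymorphic
# information content (PIC).
locus,n_alleles,He,Ho,PIC
RcFH01,2,0.117,0.125,0.110
FaFH01,3,0.190,0.208,0.178
FaFS01,2,0.395,0.292,0.317
RiAS01,2,0.187,0.125,0.169
RhUF01,3,0.156,0.167,0.150
RiMY01,7,0.813,0.583,0.787
RiG001,2,0.153,0.167,0.141
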