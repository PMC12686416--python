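# Synthetic stand-in for the RPS24 exon-4..exon-6 microexon region.
#
# The genomic coordinates below are placeholders (NOT hg38): the reference
# annotation is not redistributed with this package.  Everything that the
# quantification pipeline depends on is faithful to the published RPS24
# architecture: three microexons of exactly 3, 18 and 22 nt between the two
# constitutive flanking exons, an in-frame stop codon inside the 22-nt exon,
# and the ex4F/ex6R primer pair anchored in the flanking exons.  Matching
# synthetic exon sequences are in rps24_exons_synthetic.fa.
gene_id: RPS24
chrom: chr10
strand: "+"
cds_frame_offset: 0
donor_exon: ex4
terminal_exon: ex6
exons:
  - {id: ex4, start: 78030001, end: 78030060}
  - {id: m3,  start: 78031001, end: 78031003, microexon: true}
  - {id: m18, start: 78032001, end: 78032018, microexon: true}
  - {id: m22, start: 78033001, end: 78033022, microexon: true}
  - {id: ex6, start: 78034001, end: 78034100}
primers:
  forward: {sequence: ATGGCCTGTATGAGAAGAAA, exon: ex4, offset: 0}
  reverse: {sequence: CACAGCTAACATCATTGCAG, exon: ex6, offset: 80}
# Experimentally resolved exon content of the three junction-named isoforms:
# transcripts with the ex4:3bp junction always also carry the 22-nt exon and
# never the 18-nt exon.
canonical_structures:
  "ex4:3bp": [m3, m22]
  "ex4:22bp": [m22]
  "ex4:ex6": []
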