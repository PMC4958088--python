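# The 33 long-core-motif SSR markers (tri- to hexa-nucleotide repeat units)
# drawn from the 15 linkage groups of the tea plant genetic map. core=1 flags
# the six fingerprinting panel markers. Primer sequences are transcribed only
# for the core markers; the source text fuses forward and reverse primers for
# the remaining rows into a single undelimited string whose split point is not
# recoverable, so those fields are left empty rather than guessed.
linkage_group,marker,motif,forward_primer,reverse_primer,tm,dye,core
LG01,TM447,(AAAAG)5,,,52,TAMRA,0
LG02,TM514,(TCA)5,,,52,FAM,0
LG02,TM480,(GTA)5,,,52,FAM,0
LG03,TM337,(CCAATT)6,,,60,FAM,0
LG03,TM453,(TTC)6,,,52,TAMRA,0
LG04,TM343,(TGTTGA)3,,,56,FAM,0
LG04,TM445,(GTA)5,,,52,TAMRA,0
LG04,TM502,(AGAT)4,,,50,FAM,0
LG04,TM422,(TTC)7,,,52,TAMRA,0
LG04,TM369,(GAA)8,,,52,FAM,0
LG04,TM523,(AAAAGA)3,,,52,FAM,0
LG05,TM589,(CTCCT)3,,,52,TAMRA,0
LG05,TM428,(CAC)7,,,52,FAM,0
LG06,TM341,(TCGAA)5,,,52,FAM,0
LG07,TM415,(CCTTC)3,,,52,TAMRA,0
LG07,TM426,(AGA)11,,,52,FAM,0
LG07,TM324,(TTTTTG)5,CATCGTTTCATTGCTTATT,ATTTTCGGCATTGTCTT,54,FAM,1
LG08,TM352,(GAGGTG)4,,,52,TAMRA,0
LG08,TM395,(TCTTTT)4,,,52,FAM,0
LG08,TM493,(AGG)6,,,52,FAM,0
LG09,TM442,(ATACAC)3,CAAGCCAAACCTTGCTGAAT,CTGTCCTGTGTCTGGTGGTG,52,FAM,1
LG09,TM440,(TTTGC)3,,,52,FAM,0
LG10,TM407,(CAAGAT)3,,,52,TAMRA,0
LG10,TM569,(GTGA)5,GCAAATTCGTAAGGCGAGAG,CTGACGTTTACCCTCGTTCC,52,FAM,1
LG11,TM461,(ATTTTT)6,GGCTAGGGTTTCTCCCACTT,GAAGGTCGAAGCGATGTTGT,52,TAMRA,1
LG11,TM581,(AAAAAC)3,AAGGATCACTGGTAAAAAGCCA,CTTCTGAGCCGTTCTTGAGC,52,FAM,1
LG12,TM241,(GAGAA)3,,,58,FAM,0
LG12,TM499,(AGA)5,,,54,FAM,0
LG13,TM425,(TTATT)3,,,52,FAM,0
LG13,TM576,(TTTTC)3,,,52,FAM,0
LG14,TM348,(TATC)7,,,52,FAM,0
LG14,TM351,(GGAGAA)3,GGGTGAGAGTAAAGGGGGAG,AAACACAAAATCAAATTTGTCAGAA,52,FAM,1
LG15,TM601,(GGA)5,,,52,FAM,0
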