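# Common type II restriction enzymes with unambiguous recognition sites.
# name	site
AatII	GACGTC
AgeI	ACCGGT
ApaI	GGGCCC
AscI	GGCGCGCC
AvrII	CCTAGG
BamHI	GGATCC
BclI	TGATCA
BglII	AGATCT
BmtI	GCTAGC
BsiWI	CGTACG
BspEI	TCCGGA
BspHI	TCATGA
BsrGI	TGTACA
BssHII	GCGCGC
ClaI	ATCGAT
DpnI	GATC
DraI	TTTAAA
EagI	CGGCCG
EcoRI	GAATTC
EcoRV	GATATC
FseI	GGCCGGCC
FspI	TGCGCA
HindIII	AAGCTT
HpaI	GTTAAC
KasI	GGCGCC
KpnI	GGTACC
MfeI	CAATTG
MluI	ACGCGT
MscI	TGGCCA
NaeI	GCCGGC
NcoI	CCATGG
NdeI	CATATG
NheI	GCTAGC
NotI	GCGGCCGC
NruI	TCGCGA
NsiI	ATGCAT
PacI	TTAATTAA
PciI	ACATGT
PmeI	GTTTAAAC
PmlI	CACGTG
PstI	CTGCAG
PvuI	CGATCG
PvuII	CAGCTG
SacI	GAGCTC
SacII	CCGCGG
SalI	GTCGAC
SbfI	CCTGCAGG
ScaI	AGTACT
SmaI	CCCGGG
SnaBI	TACGTA
SpeI	ACTAGT
SphI	GCATGC
SspI	AATATT
StuI	AGGCCT
SwaI	ATTTAAAT
XbaI	TCTAGA
XhoI	CTCGAG
XmaI	CCCGGG
ZraI	GACGTC
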