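# Potential intron cryptic splice-site motifs (exact-match consensus forms):
# 5' donor consensus variants (exon|GT intron start) and 3' acceptor forms.
GGTAAG
GGTGAG
AGGTAAGT
CAGGTAAG
AGGTGAGT
TACTAAC
TTTCAG
CTAAC
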