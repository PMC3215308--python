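# Polyadenylation signal hexamers (canonical AATAAA and common variants).
AATAAA
ATTAAA
AGTAAA
TATAAA
AATACA
AATATA
CATAAA
GATAAA
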