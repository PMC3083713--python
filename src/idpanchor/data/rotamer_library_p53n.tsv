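# Empirical backbone-dependent rotamer-library populations (%) of the bound
# conformation of each p53-segment anchor residue, per complex.  Consumed as
# a reference table; not recomputed here.  "qualifier" marks upper bounds.
residue	complex	library_pct	qualifier
Phe19	p53N-MDM2	31.71
Leu22	p53N-MDM2	3.65
Trp23	p53N-MDM2	16.21
Leu26	p53N-MDM2	62.52
Phe19	p53N-Taz2	47.08
Leu22	p53N-Taz2	62.52
Trp23	p53N-Taz2	5.32
Leu26	p53N-Taz2	1.0	<
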