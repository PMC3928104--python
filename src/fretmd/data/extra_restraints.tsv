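# Four additional literature FRET distances (two per Ca2+ state) used alongside
# the 45 measured pairs: the TnC 13-51 pocket distance and the TnI 5-192 distance.
# Their half-widths were not printed; a nominal 10 A is recorded here so the
# restraint stiffness mapping stays defined (see docs/methods.md).
subunit_d	res_d	subunit_a	res_a	state	rbar_A	hw_A
cTnC	13	cTnC	51	ca_saturated	31	10.0
cTnC	13	cTnC	51	ca_free	25.8	10.0
cTnI	5	cTnI	192	ca_saturated	51.5	10.0
cTnI	5	cTnI	192	ca_free	46.8	10.0
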