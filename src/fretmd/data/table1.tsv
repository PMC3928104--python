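# Measured FRET distance distributions within the reconstituted cardiac troponin
# complex: 45 donor-acceptor pairs per Ca2+ state.  rbar_A is the distance at the
# peak of the Gaussian P(r) and hw_A its full width at half maximum, in Angstrom.
subunit_d	res_d	subunit_a	res_a	state	rbar_A	hw_A
cTnI	131	cTnT	240	ca_saturated	48.1	10.2
cTnI	145	cTnT	240	ca_saturated	55.6	14.3
cTnI	151	cTnT	240	ca_saturated	66.9	12.8
cTnI	160	cTnT	240	ca_saturated	73.3	18.1
cTnI	167	cTnT	240	ca_saturated	78.4	19.9
cTnI	131	cTnT	276	ca_saturated	20.4	1.2
cTnI	145	cTnT	276	ca_saturated	34.3	11.2
cTnI	151	cTnT	276	ca_saturated	53.6	14.3
cTnI	160	cTnT	276	ca_saturated	51.8	10.7
cTnI	167	cTnT	276	ca_saturated	61.3	20.5
cTnI	17	cTnT	276	ca_saturated	54.6	16.0
cTnI	27	cTnT	276	ca_saturated	45.1	9.1
cTnI	40	cTnT	276	ca_saturated	38.0	13.6
cTnI	131	cTnT	288	ca_saturated	25.9	4.1
cTnI	145	cTnT	288	ca_saturated	39.5	17.8
cTnI	151	cTnT	288	ca_saturated	51.4	16.9
cTnI	160	cTnT	288	ca_saturated	55	21.3
cTnI	167	cTnT	288	ca_saturated	65.4	29.2
cTnI	5	cTnT	288	ca_saturated	54.9	5.6
cTnI	17	cTnT	288	ca_saturated	57.6	21.9
cTnI	40	cTnT	288	ca_saturated	46.9	14.2
cTnI	5	cTnC	12	ca_saturated	42.6	4.7
cTnI	15	cTnC	12	ca_saturated	39.9	3.3
cTnI	30	cTnC	12	ca_saturated	41.3	16.6
cTnI	43	cTnC	12	ca_saturated	38.8	16.3
cTnI	5	cTnC	35	ca_saturated	39.6	16.4
cTnI	15	cTnC	35	ca_saturated	24.9	11
cTnI	30	cTnC	35	ca_saturated	16	6.5
cTnI	43	cTnC	35	ca_saturated	35.5	4.1
cTnI	5	cTnC	89	ca_saturated	34.1	15.5
cTnI	15	cTnC	89	ca_saturated	41.9	16.4
cTnI	30	cTnC	89	ca_saturated	45.2	16.8
cTnI	43	cTnC	89	ca_saturated	33.1	15.3
cTnI	5	cTnC	93	ca_saturated	47.8	13.9
cTnI	15	cTnC	93	ca_saturated	33.8	15.4
cTnI	30	cTnC	93	ca_saturated	39.3	16.2
cTnI	43	cTnC	93	ca_saturated	28.9	3.6
cTnI	129	cTnI	5	ca_saturated	24.62	8.165
cTnI	129	cTnI	15	ca_saturated	31.0	13.8
cTnI	129	cTnI	30	ca_saturated	27.9	2.5
cTnI	129	cTnI	43	ca_saturated	26.2	11.6
cTnI	150	cTnI	5	ca_saturated	31.2	1.2
cTnI	150	cTnI	15	ca_saturated	31.8	1.2
cTnI	150	cTnI	30	ca_saturated	29.7	10.5
cTnI	150	cTnI	43	ca_saturated	26.9	3.1
cTnI	131	cTnT	240	ca_free	47	11.7
cTnI	145	cTnT	240	ca_free	58.1	14.4
cTnI	151	cTnT	240	ca_free	63.9	18.0
cTnI	160	cTnT	240	ca_free	70.7	21.8
cTnI	167	cTnT	240	ca_free	76.7	35.5
cTnI	131	cTnT	276	ca_free	19.1	3.6
cTnI	145	cTnT	276	ca_free	28.2	10.7
cTnI	151	cTnT	276	ca_free	44.7	21.9
cTnI	160	cTnT	276	ca_free	54.2	20.7
cTnI	167	cTnT	276	ca_free	62.3	29.2
cTnI	17	cTnT	276	ca_free	50.0	15.4
cTnI	27	cTnT	276	ca_free	47.4	11.0
cTnI	40	cTnT	276	ca_free	39.4	19.3
cTnI	131	cTnT	288	ca_free	26.1	8.8
cTnI	145	cTnT	288	ca_free	39.6	18.3
cTnI	151	cTnT	288	ca_free	50.1	22.2
cTnI	160	cTnT	288	ca_free	57.8	22.9
cTnI	167	cTnT	288	ca_free	63.2	26.3
cTnI	5	cTnT	288	ca_free	56.8	7.6
cTnI	17	cTnT	288	ca_free	55.6	20.1
cTnI	40	cTnT	288	ca_free	47.5	13.4
cTnI	5	cTnC	12	ca_free	45	7.5
cTnI	15	cTnC	12	ca_free	43.4	11.6
cTnI	30	cTnC	12	ca_free	42.1	16.5
cTnI	43	cTnC	12	ca_free	36.3	6.9
cTnI	5	cTnC	35	ca_free	33.7	2.8
cTnI	15	cTnC	35	ca_free	24.5	5.9
cTnI	30	cTnC	35	ca_free	19.2	7.3
cTnI	43	cTnC	35	ca_free	36.2	4.4
cTnI	5	cTnC	89	ca_free	36.6	16
cTnI	15	cTnC	89	ca_free	34.5	2.3
cTnI	30	cTnC	89	ca_free	39.3	9.9
cTnI	43	cTnC	89	ca_free	37.8	16.2
cTnI	5	cTnC	93	ca_free	38.7	16.3
cTnI	15	cTnC	93	ca_free	34.8	14.2
cTnI	30	cTnC	93	ca_free	39.8	16.5
cTnI	43	cTnC	93	ca_free	39.1	14.4
cTnI	129	cTnI	5	ca_free	41.2	20.4
cTnI	129	cTnI	15	ca_free	32.1	2.5
cTnI	129	cTnI	30	ca_free	30.4	12.1
cTnI	129	cTnI	43	ca_free	35.2	14.6
cTnI	150	cTnI	5	ca_free	34.9	2.0
cTnI	150	cTnI	15	ca_free	32.2	5.6
cTnI	150	cTnI	30	ca_free	20.5	2.5
cTnI	150	cTnI	43	ca_free	29.1	10.9
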