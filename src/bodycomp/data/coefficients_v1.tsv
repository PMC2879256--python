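# bodycomp coefficient registry format=v1
variant	race	sex	term	value
printed	AA	M	1	-69.0
printed	AA	M	F	3.6
printed	AA	M	A	-0.04
printed	AA	M	H	0.7
printed	AA	M	FA	-0.002
printed	AA	M	FH	-0.010002
printed	AA	M	F2	-0.07
printed	AA	M	F2A	3e-05
printed	AA	M	F3	0.0007
printed	AA	M	F4	-2e-06
printed	AA	M	F2H	0.0003
printed	AA	M	F3H	0.0
printed	AA	F	1	-69.0
printed	AA	F	F	2.5
printed	AA	F	A	-0.04
printed	AA	F	H	0.3
printed	AA	F	FA	-0.002
printed	AA	F	FH	-0.01
printed	AA	F	F2	-0.047
printed	AA	F	F2A	3e-05
printed	AA	F	F3	0.0002
printed	AA	F	F4	4e-07
printed	AA	F	F2H	0.0003
printed	AA	F	F3H	-2e-06
printed	NAA	M	1	-71.7
printed	NAA	M	F	3.6
printed	NAA	M	A	-0.04
printed	NAA	M	H	0.7
printed	NAA	M	FA	-0.002
printed	NAA	M	FH	-0.01
printed	NAA	M	F2	-0.07
printed	NAA	M	F2A	3e-05
printed	NAA	M	F3	0.0006
printed	NAA	M	F4	-2e-06
printed	NAA	M	F2H	0.0003
printed	NAA	M	F3H	-2e-06
printed	NAA	F	1	-72.1
printed	NAA	F	F	2.5
printed	NAA	F	A	-0.042
printed	NAA	F	H	0.7
printed	NAA	F	FA	0.0
printed	NAA	F	FH	-0.01
printed	NAA	F	F2	-0.04
printed	NAA	F	F2A	3e-05
printed	NAA	F	F3	0.0002
printed	NAA	F	F4	4e-07
printed	NAA	F	F2H	0.0003
printed	NAA	F	F3H	-2e-06
normalized	AA	M	1	-69.0
normalized	AA	M	F	3.6
normalized	AA	M	A	-0.04
normalized	AA	M	H	0.7
normalized	AA	M	FA	-0.002
normalized	AA	M	FH	-0.01
normalized	AA	M	F2	-0.07
normalized	AA	M	F2A	3e-05
normalized	AA	M	F3	0.0007
normalized	AA	M	F4	-2e-06
normalized	AA	M	F2H	0.0003
normalized	AA	M	F3H	-2e-06
normalized	AA	F	1	-69.0
normalized	AA	F	F	2.5
normalized	AA	F	A	-0.04
normalized	AA	F	H	0.3
normalized	AA	F	FA	-0.002
normalized	AA	F	FH	-0.01
normalized	AA	F	F2	-0.047
normalized	AA	F	F2A	3e-05
normalized	AA	F	F3	0.0002
normalized	AA	F	F4	4e-07
normalized	AA	F	F2H	0.0003
normalized	AA	F	F3H	-2e-06
normalized	NAA	M	1	-71.7
normalized	NAA	M	F	3.6
normalized	NAA	M	A	-0.04
normalized	NAA	M	H	0.7
normalized	NAA	M	FA	-0.002
normalized	NAA	M	FH	-0.01
normalized	NAA	M	F2	-0.07
normalized	NAA	M	F2A	3e-05
normalized	NAA	M	F3	0.0006
normalized	NAA	M	F4	-2e-06
normalized	NAA	M	F2H	0.0003
normalized	NAA	M	F3H	-2e-06
normalized	NAA	F	1	-72.1
normalized	NAA	F	F	2.5
normalized	NAA	F	A	-0.04
normalized	NAA	F	H	0.7
normalized	NAA	F	FA	-0.002
normalized	NAA	F	FH	-0.01
normalized	NAA	F	F2	-0.04
normalized	NAA	F	F2A	3e-05
normalized	NAA	F	F3	0.0002
normalized	NAA	F	F4	4e-07
normalized	NAA	F	F2H	0.0003
normalized	NAA	F	F3H	-2e-06
corrected	AA	M	1	-69.0
corrected	AA	M	F	3.6
corrected	AA	M	A	-0.04
corrected	AA	M	H	0.7
corrected	AA	M	FA	-0.002
corrected	AA	M	FH	-0.01
corrected	AA	M	F2	-0.07
corrected	AA	M	F2A	3e-05
corrected	AA	M	F3	0.0007
corrected	AA	M	F4	-2e-06
corrected	AA	M	F2H	0.0003
corrected	AA	M	F3H	-2e-06
corrected	AA	F	1	-69.0
corrected	AA	F	F	1.6529944418252542
corrected	AA	F	A	-0.04
corrected	AA	F	H	0.7
corrected	AA	F	FA	-0.0020184308409458827
corrected	AA	F	FH	-0.012236094673581329
corrected	AA	F	F2	-0.03888469941687331
corrected	AA	F	F2A	3.0112416567606916e-05
corrected	AA	F	F3	0.00021024547454001537
corrected	AA	F	F4	4.0164891331766295e-07
corrected	AA	F	F2H	0.000354555098985709
corrected	AA	F	F3H	-1.8309496700897466e-06
corrected	NAA	M	1	-71.7
corrected	NAA	M	F	3.6
corrected	NAA	M	A	-0.04
corrected	NAA	M	H	0.7
corrected	NAA	M	FA	-0.002
corrected	NAA	M	FH	-0.01
corrected	NAA	M	F2	-0.07
corrected	NAA	M	F2A	3e-05
corrected	NAA	M	F3	0.0006
corrected	NAA	M	F4	-2e-06
corrected	NAA	M	F2H	0.0003
corrected	NAA	M	F3H	-2e-06
corrected	NAA	F	1	-72.1
corrected	NAA	F	F	2.5
corrected	NAA	F	A	-0.04
corrected	NAA	F	H	0.7
corrected	NAA	F	FA	-0.002
corrected	NAA	F	FH	-0.01
corrected	NAA	F	F2	-0.04
corrected	NAA	F	F2A	3e-05
corrected	NAA	F	F3	0.0002
corrected	NAA	F	F4	4e-07
corrected	NAA	F	F2H	0.0003
corrected	NAA	F	F3H	-2e-06
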