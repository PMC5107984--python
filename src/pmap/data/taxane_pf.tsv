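gene	pf_sum	expected_category	expected_restricted_to
FOXP1	-48	inconsistent	
NME7	-41	inconsistent	
EPS8	-87	inconsistent	
IL1R1	-9	inconsistent	
DDX17	-7	inconsistent	
CNR1	-2	inconsistent	
UBC	274	inconsistent	
ELAVL1	7	weak	
HMOX1	17	moderate	
HCK	50	moderate	
TXN	1	weak	
HSP90AA1	138	strong	
NOTCH2	3	weak	
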