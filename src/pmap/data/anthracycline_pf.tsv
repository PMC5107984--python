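gene	pf_sum	expected_category	expected_restricted_to
NOTCH2	-21	moderate	MDA-MB-231
CAV1	-331	strong	MDA-MB-231
BCL2L11	-238	strong	MDA-MB-231
CXCL9	-8	weak	MDA-MB-231
AKAP7	-2	inconsistent	
IRF5	-32	moderate	
CD244	-1	weak	
LAPTM4B	-46	moderate	
MXRA7	-2	weak	
GNA15	-204	strong	
RHOBTB3	-1	weak	
UBC	-1101	strong	
EP300	-308	inconsistent	
ELAVL1	-73	moderate	MDA-MB-231
HDAC2	-146	inconsistent	
HSP90AA1	-756	inconsistent	
GRB2	-495	strong	
ZAP70	-322	strong	
FOXP1	-2	weak	
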