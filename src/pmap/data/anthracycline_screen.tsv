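gene	cell_line	drug	observation
NOTCH2	BT549	doxorubicin	non_responsive
NOTCH2	BT549	epirubicin	non_responsive
NOTCH2	MDA-MB-231	doxorubicin	decreased_sensitivity
NOTCH2	MDA-MB-231	epirubicin	decreased_sensitivity
CAV1	BT549	doxorubicin	non_responsive
CAV1	BT549	epirubicin	non_responsive
CAV1	MDA-MB-231	doxorubicin	decreased_sensitivity
CAV1	MDA-MB-231	epirubicin	decreased_sensitivity
BCL2L11	BT549	doxorubicin	non_responsive
BCL2L11	BT549	epirubicin	non_responsive
BCL2L11	MDA-MB-231	doxorubicin	decreased_sensitivity
BCL2L11	MDA-MB-231	epirubicin	decreased_sensitivity
CXCL9	BT549	doxorubicin	non_responsive
CXCL9	BT549	epirubicin	non_responsive
CXCL9	MDA-MB-231	doxorubicin	non_responsive
CXCL9	MDA-MB-231	epirubicin	decreased_sensitivity
AKAP7	BT549	doxorubicin	non_responsive
AKAP7	BT549	epirubicin	non_responsive
AKAP7	MDA-MB-231	doxorubicin	non_responsive
AKAP7	MDA-MB-231	epirubicin	non_responsive
IRF5	BT549	doxorubicin	decreased_sensitivity
IRF5	BT549	epirubicin	decreased_sensitivity
IRF5	MDA-MB-231	doxorubicin	decreased_sensitivity
IRF5	MDA-MB-231	epirubicin	decreased_sensitivity
CD244	BT549	doxorubicin	decreased_sensitivity
CD244	BT549	epirubicin	decreased_sensitivity
CD244	MDA-MB-231	doxorubicin	decreased_sensitivity
CD244	MDA-MB-231	epirubicin	decreased_sensitivity
LAPTM4B	BT549	doxorubicin	decreased_sensitivity
LAPTM4B	BT549	epirubicin	decreased_sensitivity
LAPTM4B	MDA-MB-231	doxorubicin	decreased_sensitivity
LAPTM4B	MDA-MB-231	epirubicin	decreased_sensitivity
MXRA7	BT549	doxorubicin	decreased_sensitivity
MXRA7	BT549	epirubicin	decreased_sensitivity
MXRA7	MDA-MB-231	doxorubicin	decreased_sensitivity
MXRA7	MDA-MB-231	epirubicin	decreased_sensitivity
GNA15	BT549	doxorubicin	decreased_sensitivity
GNA15	BT549	epirubicin	decreased_sensitivity
GNA15	MDA-MB-231	doxorubicin	decreased_sensitivity
GNA15	MDA-MB-231	epirubicin	decreased_sensitivity
RHOBTB3	BT549	doxorubicin	decreased_sensitivity
RHOBTB3	BT549	epirubicin	decreased_sensitivity
RHOBTB3	MDA-MB-231	doxorubicin	decreased_sensitivity
RHOBTB3	MDA-MB-231	epirubicin	decreased_sensitivity
UBC	BT549	doxorubicin	decreased_sensitivity
UBC	BT549	epirubicin	decreased_sensitivity
UBC	MDA-MB-231	doxorubicin	decreased_sensitivity
UBC	MDA-MB-231	epirubicin	decreased_sensitivity
EP300	BT549	doxorubicin	non_responsive
EP300	BT549	epirubicin	non_responsive
EP300	MDA-MB-231	doxorubicin	non_responsive
EP300	MDA-MB-231	epirubicin	non_responsive
ELAVL1	BT549	doxorubicin	non_responsive
ELAVL1	BT549	epirubicin	non_responsive
ELAVL1	MDA-MB-231	doxorubicin	non_responsive
ELAVL1	MDA-MB-231	epirubicin	decreased_sensitivity
HDAC2	BT549	doxorubicin	non_responsive
HDAC2	BT549	epirubicin	non_responsive
HDAC2	MDA-MB-231	doxorubicin	non_responsive
HDAC2	MDA-MB-231	epirubicin	non_responsive
HSP90AA1	BT549	doxorubicin	non_responsive
HSP90AA1	BT549	epirubicin	non_responsive
HSP90AA1	MDA-MB-231	doxorubicin	non_responsive
HSP90AA1	MDA-MB-231	epirubicin	non_responsive
GRB2	BT549	doxorubicin	decreased_sensitivity
GRB2	BT549	epirubicin	decreased_sensitivity
GRB2	MDA-MB-231	doxorubicin	decreased_sensitivity
GRB2	MDA-MB-231	epirubicin	decreased_sensitivity
ZAP70	BT549	doxorubicin	decreased_sensitivity
ZAP70	BT549	epirubicin	decreased_sensitivity
ZAP70	MDA-MB-231	doxorubicin	decreased_sensitivity
ZAP70	MDA-MB-231	epirubicin	decreased_sensitivity
FOXP1	BT549	doxorubicin	decreased_sensitivity
FOXP1	BT549	epirubicin	decreased_sensitivity
FOXP1	MDA-MB-231	doxorubicin	decreased_sensitivity
FOXP1	MDA-MB-231	epirubicin	decreased_sensitivity
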