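gene	cell_line	drug	observation
FOXP1	BT549	docetaxel	non_responsive
FOXP1	BT549	paclitaxel	non_responsive
FOXP1	MDA-MB-231	docetaxel	non_responsive
FOXP1	MDA-MB-231	paclitaxel	non_responsive
NME7	BT549	docetaxel	increased_sensitivity
NME7	BT549	paclitaxel	increased_sensitivity
NME7	MDA-MB-231	docetaxel	increased_sensitivity
NME7	MDA-MB-231	paclitaxel	increased_sensitivity
EPS8	BT549	docetaxel	increased_sensitivity
EPS8	BT549	paclitaxel	increased_sensitivity
EPS8	MDA-MB-231	docetaxel	increased_sensitivity
EPS8	MDA-MB-231	paclitaxel	increased_sensitivity
IL1R1	BT549	docetaxel	increased_sensitivity
IL1R1	BT549	paclitaxel	increased_sensitivity
IL1R1	MDA-MB-231	docetaxel	increased_sensitivity
IL1R1	MDA-MB-231	paclitaxel	increased_sensitivity
DDX17	BT549	docetaxel	increased_sensitivity
DDX17	BT549	paclitaxel	increased_sensitivity
DDX17	MDA-MB-231	docetaxel	increased_sensitivity
DDX17	MDA-MB-231	paclitaxel	increased_sensitivity
CNR1	BT549	docetaxel	increased_sensitivity
CNR1	BT549	paclitaxel	increased_sensitivity
CNR1	MDA-MB-231	docetaxel	increased_sensitivity
CNR1	MDA-MB-231	paclitaxel	increased_sensitivity
UBC	BT549	docetaxel	decreased_sensitivity
UBC	BT549	paclitaxel	decreased_sensitivity
UBC	MDA-MB-231	docetaxel	decreased_sensitivity
UBC	MDA-MB-231	paclitaxel	decreased_sensitivity
ELAVL1	BT549	docetaxel	increased_sensitivity
ELAVL1	BT549	paclitaxel	increased_sensitivity
ELAVL1	MDA-MB-231	docetaxel	increased_sensitivity
ELAVL1	MDA-MB-231	paclitaxel	increased_sensitivity
HMOX1	BT549	docetaxel	increased_sensitivity
HMOX1	BT549	paclitaxel	increased_sensitivity
HMOX1	MDA-MB-231	docetaxel	increased_sensitivity
HMOX1	MDA-MB-231	paclitaxel	increased_sensitivity
HCK	BT549	docetaxel	increased_sensitivity
HCK	BT549	paclitaxel	increased_sensitivity
HCK	MDA-MB-231	docetaxel	increased_sensitivity
HCK	MDA-MB-231	paclitaxel	increased_sensitivity
TXN	BT549	docetaxel	increased_sensitivity
TXN	BT549	paclitaxel	increased_sensitivity
TXN	MDA-MB-231	docetaxel	increased_sensitivity
TXN	MDA-MB-231	paclitaxel	increased_sensitivity
HSP90AA1	BT549	docetaxel	increased_sensitivity
HSP90AA1	BT549	paclitaxel	increased_sensitivity
HSP90AA1	MDA-MB-231	docetaxel	increased_sensitivity
HSP90AA1	MDA-MB-231	paclitaxel	increased_sensitivity
NOTCH2	BT549	docetaxel	increased_sensitivity
NOTCH2	BT549	paclitaxel	increased_sensitivity
NOTCH2	MDA-MB-231	docetaxel	increased_sensitivity
NOTCH2	MDA-MB-231	paclitaxel	increased_sensitivity
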