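gene	disease	species	alteration	relationship	evidence_ref
COL4A1	VaD	h	mutation	causes VaD	CR61
MTHFR	VaD	h	polymorphism	causes VaD	CR62-CR64
NOTCH3	CADASIL	h	abnormal folding; absence; decreased processing; mutation	causes VaD	CR65-CR70
HTRA1	CADASIL	h	mutation	causes VaD	CR71
HTR1A	VaD	h	activation	may prevent VaD	CR72
ACHE	VaD	h	inhibition	may prevent VaD	CR73
ADRA1A	VaD	h	inhibition	may prevent VaD	CR74
BDNF	VaD	r	up expression	may prevent VaD	CR75
BCHE	Subcortical VaD	h	inhibition	may prevent VaD	CR73
GABBR2	VaD	r	activation	may prevent VaD	CR76
IDO1	VaD	r, m	inhibition	may prevent VaD	CR56
IDO2	VaD	r, m	inhibition	may prevent VaD	CR56
KYNU	VaD	r, m	inhibition	may prevent VaD	CR56
AADAT	VaD	r, m	inhibition	may prevent VaD	CR56
KMO	VaD	r, m	inhibition	may prevent VaD	CR56
PPARG	VaD	h	activation	may prevent VaD	CR77,CR78
TACR1	VaD	r	inhibition	may prevent VaD	CR78
TDO2	VaD	r, m	inhibition	may prevent VaD	CR56
AGTR2	VaD	m	activation	may prevent VaD	CR79
SLC6A2	VaD	m	inhibition	may prevent VaD	CR80
AHR	VaD	r, m	inhibition	may prevent VaD	CR56,CR81
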