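mechanism	uniprot_id	rank	drug
Nitric oxide synthase, brain inhibitor	P29475	9	Ketamine; Methylene blue
Glycogen synthase kinase-3 alpha inhibitor	P49840	13	Fostamatinib
Bradykinin B2 receptor antagonist	P30411	15	Icatibant
Extracellular calcium sensing receptor antagonist	P41180	36	—
Alpha 2 A adrenergic receptor antagonists	P08913	49	Phentolamine; Mirtazapine; Yohimbine; Phenoxybenzamine; Propericiazine
Cystic fibrosis transmembrane conductance regulator agonist	P13569	104	Bumetanide; Crofelemer; Ibuprofen; Dexibuprofen
Insulin-like growth factor 1 receptor agonist	P08069	109	Mecasermin
Androgen receptor agonist	P10275	289	Oxandrolone; Testosterone; Nandrolone phenpropionate; Fluoxymesterone; Danazol; Nandrolone decanoate; Methyltestosterone; Oxymetholone
Glycogen synthase kinase-3 beta inhibitor	P49841	296	Fostamatinib
Protein phosphatase 1B inhibitor	P18031	507	Tiludronic acid
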