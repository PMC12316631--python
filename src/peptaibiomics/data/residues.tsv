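token	class	formula	mono_mass	ambiguity
Gly	internal	C2H3NO	57.02146
Ala	internal	C3H5NO	71.03711
Ser	internal	C3H5NO2	87.03203
Pro	internal	C5H7NO	97.05276
Val	internal	C5H9NO	99.06841
Iva	internal	C5H9NO	99.06841
Vxx	internal	C5H9NO	99.06841	Val,Iva
Aib	internal	C4H7NO	85.05276
Thr	internal	C4H7NO2	101.04768
Leu	internal	C6H11NO	113.08406
Ile	internal	C6H11NO	113.08406
Lxx	internal	C6H11NO	113.08406	Leu,Ile
Asn	internal	C4H6N2O2	114.04293
Asp	internal	C4H5NO3	115.02694
Gln	internal	C5H8N2O2	128.05858
Glu	internal	C5H7NO3	129.04259
Phe	internal	C9H9NO	147.06841
Tyr	internal	C9H9NO2	163.06333
Trp	internal	C11H10N2O	186.07931
Glyol	amino_alcohol	C2H7NO	61.05276
Alaol	amino_alcohol	C3H9NO	75.06841
Valol	amino_alcohol	C5H13NO	103.09971
Ivaol	amino_alcohol	C5H13NO	103.09971
Vxxol	amino_alcohol	C5H13NO	103.09971	Valol,Ivaol
Leuol	amino_alcohol	C6H15NO	117.11536
Ileol	amino_alcohol	C6H15NO	117.11536
Lxxol	amino_alcohol	C6H15NO	117.11536	Leuol,Ileol
Pheol	amino_alcohol	C9H13NO	151.09971
Trpol	amino_alcohol	C11H14N2O	190.11061
Ac	acyl_cap	C2H2O	42.01057
Oc	acyl_cap	C8H14O	126.10446
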