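metal	pattern	note
Co	cobalt	element name
Co	cobalamin	vitamin B12 cofactor
Co	corrin(oid)?	corrin ring cofactors
Co	\bB-?12\b	vitamin B12 shorthand
Fe	\biron\b	element name
Fe	ferric|ferrous	oxidation-state adjectives
Fe	\bheme\b|\bhaem\b	heme cofactor
Fe	iron[- ]?sulfur|iron[- ]?sulphur|\b[0-9]?Fe[- ]?[0-9]?S\b	Fe-S clusters
Fe	ferredoxin|rubredoxin|rubrerythrin	Fe-S / mononuclear Fe proteins
Fe	siderophore	Fe scavenging
Mn	manganese	element name
Mo	molybdenum|molybdate	element name / oxyanion
Mo	molybdopterin|\bMoCo\b|molybdenum cofactor	Mo-pterin cofactor
Ni	\bnickel\b	element name
Ni	urease	canonical Ni enzyme
Ni	\[NiFe\]|NiFe[- ]?hydrogenase	Ni-Fe hydrogenases
Pb	\blead\(II\)|\blead ion|plumb(ous|ic)	avoid the common verb "lead"
U	uranium|uranyl	element name / oxycation
V	vanadium|vanadate|vanadyl	element name / oxyanions
W	tungsten|tungstate	element name / oxyanion
W	tungstopterin|tungsten cofactor	W-pterin cofactor
Zn	\bzinc\b	element name
Zn	zinc[- ]?finger	structural Zn motif
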