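surface	entity_id	kind	canonical_name	group_names
metoprolol	D_METO	generic	metoprolol	
Selokeen	D_METO	trade	metoprolol	
hydrochloorthiazide	D_HCTZ	generic	hydrochloorthiazide	
hydrochlorothiazide	D_HCTZ	synonym	hydrochloorthiazide	
morfine	D_MORF	generic	morfine	opiaten
morphine	D_MORF	synonym	morfine	opiaten
oxycodon	D_OXY	generic	oxycodon	opiaten
oxycodone	D_OXY	synonym	oxycodon	opiaten
OxyContin	D_OXY	trade	oxycodon	opiaten
paracetamol	D_PCM	generic	paracetamol	
acetaminophen	D_PCM	synonym	paracetamol	
penicilline	D_PEN	generic	penicilline	antibiotica
penicillin	D_PEN	synonym	penicilline	antibiotica
amoxicilline	D_AMOX	generic	amoxicilline	antibiotica
amoxicillin	D_AMOX	synonym	amoxicilline	antibiotica
haloperidol	D_HAL	generic	haloperidol	
Haldol	D_HAL	trade	haloperidol	
furosemide	D_FURO	generic	furosemide	
Lasix	D_FURO	trade	furosemide	
apixaban	D_APIX	generic	apixaban	
Eliquis	D_APIX	trade	apixaban	
simvastatine	D_SIMVA	generic	simvastatine	
simvastatin	D_SIMVA	synonym	simvastatine	
ibuprofen	D_IBU	generic	ibuprofen	
Brufen	D_IBU	trade	ibuprofen	
opiaten	G_OPI	group	opiaten	
opiates	G_OPI	synonym	opiaten	
opioiden	G_OPI	synonym	opiaten	
antibiotica	G_AB	group	antibiotica	
antibioticum	G_AB	synonym	antibiotica	
antibiotic	G_AB	synonym	antibiotica	
antibiotics	G_AB	synonym	antibiotica	
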