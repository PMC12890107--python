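surface	term_code	preferred_label	organ_class
nausea	T_NAUSEA	nausea	gastrointestinal disorders
misselijkheid	T_NAUSEA	nausea	gastrointestinal disorders
misselijk	T_NAUSEA	nausea	gastrointestinal disorders
nauseous	T_NAUSEA	nausea	gastrointestinal disorders
constipation	T_CONSTIP	constipation	gastrointestinal disorders
obstipatie	T_CONSTIP	constipation	gastrointestinal disorders
constipatie	T_CONSTIP	constipation	gastrointestinal disorders
diarrhoea	T_DIARR	diarrhoea	gastrointestinal disorders
diarrhea	T_DIARR	diarrhoea	gastrointestinal disorders
diarree	T_DIARR	diarrhoea	gastrointestinal disorders
vomiting	T_VOMIT	vomiting	gastrointestinal disorders
braken	T_VOMIT	vomiting	gastrointestinal disorders
urticaria	T_URTIC	urticaria	skin and subcutaneous tissue disorders
hives	T_URTIC	urticaria	skin and subcutaneous tissue disorders
netelroos	T_URTIC	urticaria	skin and subcutaneous tissue disorders
galbulten	T_URTIC	urticaria	skin and subcutaneous tissue disorders
rash	T_RASH	rash	skin and subcutaneous tissue disorders
huiduitslag	T_RASH	rash	skin and subcutaneous tissue disorders
hypotension	T_HYPOTENS	hypotension	vascular disorders
hypotensie	T_HYPOTENS	hypotension	vascular disorders
lage bloeddruk	T_HYPOTENS	hypotension	vascular disorders
low blood pressure	T_HYPOTENS	hypotension	vascular disorders
bradycardia	T_BRADY	bradycardia	cardiac disorders
bradycardie	T_BRADY	bradycardia	cardiac disorders
dizziness	T_DIZZ	dizziness	nervous system disorders
duizeligheid	T_DIZZ	dizziness	nervous system disorders
duizelig	T_DIZZ	dizziness	nervous system disorders
somnolence	T_SOMNOL	somnolence	nervous system disorders
sufheid	T_SOMNOL	somnolence	nervous system disorders
slaperigheid	T_SOMNOL	somnolence	nervous system disorders
hyponatraemia	T_HYPONAT	hyponatraemia	metabolism and nutrition disorders
hyponatremia	T_HYPONAT	hyponatraemia	metabolism and nutrition disorders
hyponatriëmie	T_HYPONAT	hyponatraemia	metabolism and nutrition disorders
haemorrhage	T_HAEMORR	haemorrhage	vascular disorders
hemorrhage	T_HAEMORR	haemorrhage	vascular disorders
bloeding	T_HAEMORR	haemorrhage	vascular disorders
hemorragie	T_HAEMORR	haemorrhage	vascular disorders
cardiac failure	T_CARDFAIL	cardiac failure	cardiac disorders
heart failure	T_CARDFAIL	cardiac failure	cardiac disorders
hartfalen	T_CARDFAIL	cardiac failure	cardiac disorders
decompensatio cordis	T_CARDFAIL	cardiac failure	cardiac disorders
retinopathy	T_RETINO	retinopathy	eye disorders
retinopathie	T_RETINO	retinopathy	eye disorders
acute kidney injury	T_AKI	acute kidney injury	renal and urinary disorders
nierinsufficiëntie	T_AKI	acute kidney injury	renal and urinary disorders
acute nierschade	T_AKI	acute kidney injury	renal and urinary disorders
delirium	T_DELIR	delirium	psychiatric disorders
delier	T_DELIR	delirium	psychiatric disorders
hypersensitivity	T_HYPERSENS	hypersensitivity	immune system disorders
overgevoeligheid	T_HYPERSENS	hypersensitivity	immune system disorders
allergische reactie	T_HYPERSENS	hypersensitivity	immune system disorders
hypertension	T_HYPERTENS	hypertension	vascular disorders
hypertensie	T_HYPERTENS	hypertension	vascular disorders
hoge bloeddruk	T_HYPERTENS	hypertension	vascular disorders
pain	T_PAIN	pain	general disorders
pijn	T_PAIN	pain	general disorders
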