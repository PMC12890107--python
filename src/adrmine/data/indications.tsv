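ingredient_id	term_code
D_METO	T_HYPERTENS
D_HCTZ	T_HYPERTENS
D_MORF	T_PAIN
D_OXY	T_PAIN
D_PCM	T_PAIN
D_IBU	T_PAIN
D_HAL	T_DELIR
D_FURO	T_CARDFAIL
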