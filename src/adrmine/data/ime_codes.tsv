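term_code
T_HYPONAT
T_HAEMORR
T_CARDFAIL
T_RETINO
T_AKI
T_DELIR
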