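surface	kind
door	causal_link
vanwege	causal_link
wegens	causal_link
ten gevolge van	causal_link
bij gebruik van	causal_link
allergie	allergy_label
allergisch	allergy_label
gestaakt	discontinuation
gestopt	discontinuation
weigert	refusal
geweigerd	refusal
weigering	refusal
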