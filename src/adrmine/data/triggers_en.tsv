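surface	kind
due to	causal_link
because of	causal_link
caused by	causal_link
after	causal_link
attributed to	causal_link
allergy	allergy_label
allergic	allergy_label
discontinued	discontinuation
stopped	discontinuation
refuses	refusal
refused	refusal
declined	refusal
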