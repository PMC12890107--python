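item	question	yes	no	unknown
1	Are there previous conclusive reports on this reaction?	1	0	0
2	Did the adverse event appear after the suspected drug was administered?	2	-1	0
3	Did the adverse reaction improve when the drug was discontinued or a specific antagonist was administered?	1	0	0
4	Did the adverse reaction reappear when the drug was readministered?	2	-1	0
5	Are there alternative causes that could on their own have caused the reaction?	-1	2	0
6	Did the reaction reappear when a placebo was given?	-1	1	0
7	Was the drug detected in the blood in concentrations known to be toxic?	1	0	0
8	Was the reaction more severe when the dose was increased or less severe when the dose was decreased?	1	0	0
9	Did the patient have a similar reaction to the same or similar drugs in any previous exposure?	1	0	0
10	Was the adverse event confirmed by any objective evidence?	1	0	0
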