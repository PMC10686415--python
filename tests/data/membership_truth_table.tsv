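vs_control	vs_type_b	vs_type_c	expected_status	expected_criterion
enriched	enriched	enriched	enriched	II
enriched	enriched	de-enriched	enriched	II
enriched	enriched	not significant	enriched	II
enriched	de-enriched	enriched	enriched	III
enriched	de-enriched	de-enriched	not significant	none
enriched	de-enriched	not significant	not significant	none
enriched	not significant	enriched	enriched	I
enriched	not significant	de-enriched	enriched	I
enriched	not significant	not significant	enriched	I
de-enriched	enriched	enriched	de-enriched	none
de-enriched	enriched	de-enriched	de-enriched	none
de-enriched	enriched	not significant	de-enriched	none
de-enriched	de-enriched	enriched	de-enriched	none
de-enriched	de-enriched	de-enriched	de-enriched	none
de-enriched	de-enriched	not significant	de-enriched	none
de-enriched	not significant	enriched	de-enriched	none
de-enriched	not significant	de-enriched	de-enriched	none
de-enriched	not significant	not significant	de-enriched	none
not significant	enriched	enriched	enriched	II
not significant	enriched	de-enriched	enriched	II
not significant	enriched	not significant	enriched	II
not significant	de-enriched	enriched	enriched	III
not significant	de-enriched	de-enriched	not significant	none
not significant	de-enriched	not significant	not significant	none
not significant	not significant	enriched	enriched	III
not significant	not significant	de-enriched	not significant	none
not significant	not significant	not significant	not significant	none
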