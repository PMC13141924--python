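characteristic	count	total
female	31	40
male	9	40
smoker	10	40
non_smoker	30	40
hypertension	13	40
diabetes	8	40
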