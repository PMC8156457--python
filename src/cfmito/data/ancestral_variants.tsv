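pos	ref	alt	variant_type
750	A	G	SNV
2706	A	G	SNV
263	A	G	SNV
15326	A	G	SNV
9769	T		del
12272	A		del
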