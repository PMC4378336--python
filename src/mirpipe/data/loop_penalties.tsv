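kind	size	energy
hairpin	3	5.40
hairpin	4	5.60
hairpin	5	5.70
hairpin	6	5.80
hairpin	7	5.90
hairpin	8	6.00
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
internal	2	1.50
internal	3	1.60
internal	4	1.70
internal	5	2.00
internal	6	2.20
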