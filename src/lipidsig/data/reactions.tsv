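substrate	product	kind
12:0	14:0	elongation
14:0	16:0	elongation
15:0	17:0	elongation
16:0	18:0	elongation
18:0	20:0	elongation
20:0	22:0	elongation
22:0	24:0	elongation
24:0	26:0	elongation
16:0	16:1n-7	desaturation
18:0	18:1n-9	desaturation
16:1n-7	18:1n-7	elongation
18:1n-9	20:1n-9	elongation
20:1n-9	22:1n-9	elongation
22:1n-9	24:1n-9	elongation
18:1n-9	16:1n-9	chain_shortening
18:2n-6	18:3n-6	desaturation
18:2n-6	20:2n-6	elongation
20:2n-6	22:2n-6	elongation
18:3n-6	20:3n-6	elongation
20:2n-6	20:3n-6	desaturation
20:3n-6	20:4n-6	desaturation
20:4n-6	22:4n-6	elongation
22:4n-6	24:4n-6	elongation
24:4n-6	24:5n-6	desaturation
24:5n-6	22:5n-6	chain_shortening
18:3n-3	18:4n-3	desaturation
18:3n-3	20:3n-3	elongation
18:4n-3	20:4n-3	elongation
20:3n-3	20:4n-3	desaturation
20:4n-3	20:5n-3	desaturation
20:5n-3	22:5n-3	elongation
22:5n-3	24:5n-3	elongation
24:5n-3	24:6n-3	desaturation
24:6n-3	22:6n-3	chain_shortening
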