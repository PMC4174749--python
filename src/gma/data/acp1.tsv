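acp1	frequency	activity	inhibition
A/A	0.1242	122.4	41.2
A/B	0.4139	153.9	37.9
B/B	0.3349	188.3	34.4
A/C	0.0445	183.6	58.7
B/C	0.0799	212.3	53.1
C/C	0.0025	240.0	76.0
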