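factor	threshold
SRSF1	6.2
SRSF2	5.8
SRSF5	6.1
SRSF6	5.0
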