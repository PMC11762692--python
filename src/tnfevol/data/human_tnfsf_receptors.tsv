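gene	receptor
TNFSF6	TNFRSF6B
TNFSF14	TNFRSF6B
TNFSF15	TNFRSF6B
TNFSF1	TNFRSF1A
TNFSF2	TNFRSF1A
TNFSF1	TNFRSF3
TNFSF3	TNFRSF3
TNFSF14	TNFRSF3
TNFSF13	TNFRSF13B
TNFSF13B	TNFRSF13B
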