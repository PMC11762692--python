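gene	feature
TNFSF1	BINDS_DD_RECEPTOR
TNFSF2	BINDS_DD_RECEPTOR
TNFSF6	BINDS_DD_RECEPTOR
TNFSF15	BINDS_DD_RECEPTOR
TNFSF10	BINDS_DD_RECEPTOR
EDA	BINDS_DD_RECEPTOR
TNFSF1	ACTIVATES_NFKB
TNFSF2	ACTIVATES_NFKB
TNFSF3	ACTIVATES_NFKB
TNFSF6	ACTIVATES_NFKB
TNFSF14	ACTIVATES_NFKB
TNFSF15	ACTIVATES_NFKB
EDA	ACTIVATES_NFKB
TNFSF13	ACTIVATES_NFKB
TNFSF13B	ACTIVATES_NFKB
TNFSF11	ACTIVATES_NFKB
TNFSF12	ACTIVATES_NFKB
TNFSF4	ACTIVATES_NFKB
TNFSF9	ACTIVATES_NFKB
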