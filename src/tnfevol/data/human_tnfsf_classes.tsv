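gene	ancestral_class
EDA	V22
TNFSF1	V11
TNFSF10	V12
TNFSF11	V12
TNFSF12	V12
TNFSF13	V22
TNFSF13B	V22
TNFSF14	V11
TNFSF15	V11
TNFSF18	V21
TNFSF2	V11
TNFSF3	V11
TNFSF4	V21
TNFSF5	V12
TNFSF6	V11
TNFSF7	V21
TNFSF8	V21
TNFSF9	V21
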