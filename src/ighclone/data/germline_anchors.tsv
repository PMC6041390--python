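V1-26	V	97
V1-7	V	97
V1-81	V	97
V1-82	V	97
V1-9	V	97
V2-2	V	97
V5-17	V	97
V5-9-1	V	97
V7-3	V	97
V9-4	V	97
J1	J	6
J2	J	4
J3	J	4
J4	J	6
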