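name	kind	anchor_nt
V01	V	271
V02	V	271
V03	V	271
V04	V	271
V05	V	271
V06	V	271
V07	V	271
V08	V	271
J01	J	9
J02	J	9
J03	J	9
J04	J	9
J05	J	9
J06	J	9
C01	C	
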