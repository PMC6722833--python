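family	members
MIR156	13
MIR396	7
MIR166	5
MIR172	5
MIR403	5
MIR168	4
MIR398	4
MIR167_1	3
MIR397	3
MIR160	2
MIR162_1	2
MIR398_2	2
MIR159	1
MIR169_1	1
MIR2111	1
MIR2592	1
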