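# Haplogroup frequency table of a 214-sample Southeast Asian control-region survey
# (64 distinct labels; trailing * marks paragroup assignments).
Haplogroup	N
A5b	1
B4*	1
B4a'g*	3
B4a1*	3
B4a1b	1
B4b1*	1
B4b1a1'2*	1
B4b1a2a	2
B4c1b	1
B4c2	6
B4e	2
B4g	7
B5a	26
B5b	1
B6	1
C7	13
D*	1
D4b1b	1
D4b2b	2
D4e1'3	1
D4g2a	1
preD5a2a1	1
D5b	2
F*	2
F1a'c*	1
F1a*	9
F1a1*	11
F1a1a	16
F1a2	1
F1a2'3*	1
F1b'd'e*	2
F1d	1
F2a	1
F3a	1
F4a	2
G2a	1
M*	17
M7b*	10
M7b1	13
M7c*	1
M7c3b	4
M7e	3
M8a2a	1
M9a'b*	1
M9a	1
M9b	1
M12a	2
M12b	4
M21d	1
preM23	1
M51	1
preM61	2
M71	5
M73	1
N*	2
N9a*	1
N9a2'4'5	1
N9a6	1
preN21	2
N22	1
R9b1*	2
R9b1b	3
R9b2	3
R9c	1
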