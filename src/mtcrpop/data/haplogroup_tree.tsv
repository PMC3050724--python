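# Curated haplogroup motif tree -- TEST RESOURCE.
# Rooted at the reference sequence; one row per node: Name, Parent, Motif.
# Motif tokens use the difference-codec grammar plus @NNN back-mutations.
# Motifs are plausible control-region diagnostics for a Southeast Asian
# sample (hallmark sites used where well attested, e.g. B5a
# 210/16140/16183C/16189/16266A); this is not a phylotree redistribution.
Name	Parent	Motif
ROOT
L3	ROOT	73 263 16223
M	L3	489
N	L3	150
R	N	@16223 16519
A	N	235 16290 16319
A5	A	16187
A5b	A5	16126
N9	N	16257A
N9a	N9	16261
N9a2'4'5	N9a	16311
N9a6	N9a	16219
preN21	N	207
N22	N	16145
R9	R	16304
F	R9	249del
F1	F	16129
F1a'c	F1	16162
F1a	F1a'c	16172
F1a1	F1a	16399
F1a1a	F1a1	152
F1a2'3	F1a	16291
F1a2	F1a2'3	146
F1b'd'e	F1	16232A
F1d	F1b'd'e	16324
F2	F	16203
F2a	F2	16167
F3	F	16298
F3a	F3	16355
F4	F	16300
F4a	F4	195
R9b	R9	16192
R9b1	R9b	16335
R9b1b	R9b1	16111
R9b2	R9b	16242
R9c	R9	103
B	R	16189 523del 524del
B4	B	16217
B4a'g	B4	16234
B4a	B4a'g	16261T
B4a1	B4a	16235
B4a1b	B4a1	16309
B4g	B4a'g	16181C
B4b'd'e	B4	499
B4b1	B4b'd'e	16136
B4b1a1'2	B4b1	204
B4b1a2	B4b1a1'2	64
B4b1a2a	B4b1a2	16148
B4c	B4	16169
B4c1	B4c	16327
B4c1b	B4c1	198
B4c2	B4c	16274
B4e	B4	16227
B5	B	16140
B5a	B5	210 16183C 16266A
B5b	B5	16243
B6	B	16179
M7	M	16209
M7b	M7	16297
M7b1	M7b	199
M7c	M7	16295
M7c3	M7c	16294
M7c3b	M7c3	16104
M7e	M7	16390
M8	M	16184
M8a	M8	16320
M8a2	M8a	143
M8a2a	M8a2	16260
CZ	M8	16185
C	CZ	16357
C7	C	16356
D	M	16362
D4	D	195
D4b	D4	16358
D4b1	D4b	16236
D4b1b	D4b1	16092
D4b2	D4b	16296
D4b2b	D4b2	194
D4e	D4	16231
D4e1'3	D4e	16263
D4g	D4	16278
D4g2	D4g	16215
D4g2a	D4g2	@195 16174
D5	D	16164
preD5a2a1	D5	16160
D5b	D5	16302
G	M	16222
G2	G	16226
G2a	G2	16325
M9	M	153
M9a'b	M9	16316
M9a	M9a'b	16254
M9b	M9a'b	16195
M12	M	125
M12a	M12	318
M12b	M12	16241
M21	M	16122
M21d	M21	16131
preM23	M	16201
M51	M	16205
preM61	M	16220C
M71	M	16239
M73	M	16248
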