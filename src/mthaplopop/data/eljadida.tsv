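# El Jadida (Morocco) control-region haplotypes, n=81.
# Variant strings are rCRS-relative; HVRI positions are printed minus 16000.
# OTHER holds coding-region polymorphisms typed in possible-H samples.
sample_id	population	HVRI	HVRII	OTHER	haplogroup
J1	El Jadida	0	263 309.1 315.1		H*
J2	El Jadida	129 184	146 263 309.2 315.1		H*
J3	El Jadida	304	263 309.1 315.1		H*
J4	El Jadida	0	263 315.1	3010	H1
J5	El Jadida	0	263 309.1 315.1	3010	H1
J6	El Jadida	0	263 309.2 315.1	3010	H1
J7	El Jadida	0	263 309.1 315.1	3010	H1
J8	El Jadida	0	263 309.2 315.1	3010	H1
J9	El Jadida	209	114 146 263 309.1 315.1	3010	H1
J10	El Jadida	212	263 309.1 315.1	3010	H1
J11	El Jadida	218	263 309.2 315.1	3010	H1
J12	El Jadida	318A/C	114 263 309.2 315.1	3010	H1
J13	El Jadida	355	263 315.1	3010	H1
J14	El Jadida	0	263 309.1 315.1	4793	H7
J15	El Jadida	67	263 309.1 315.1		HV1
J16	El Jadida	93 298 311	72 263 315.1		V
J17	El Jadida	153 193 298	72 195 263 309.1 315.1		V
J18	El Jadida	153 298	72 195 263 315.1		V
J19	El Jadida	193	72 93 263 309.1 315.1		V
J20	El Jadida	298	72 195 263 309.1 315.1		V
J21	El Jadida	298	72 263 309.1 315.1		V
J22	El Jadida	298	72 263 309.1 315.1		V
J23	El Jadida	298	72 195 263 309.2 315.1		V
J24	El Jadida	126 291 362	58 64 152 263 315.1	7028	R0a
J25	El Jadida	126 291 362	58 64 152 263 315.1	7028	R0a
J26	El Jadida	126 362	58 64 263 315.1		R0a
J27	El Jadida	93 224 311	73 263 309.1 315.1		K
J28	El Jadida	224 287 311	73 146 263 309.1 315.1		K
J29	El Jadida	224 287 311	73 146 263 309.1 315.1		K
J30	El Jadida	224 287 311	73 146 263 309.1 315.1		K
J31	El Jadida	224 287 311	73 146 263 309.1 315.1		K
J32	El Jadida	224 287 311	73 146 263 309.1 315.1		K
J33	El Jadida	224 311	73 263 280G/C 315.1		K
J34	El Jadida	224 311	73 263 280C/G 315.1		K
J35	El Jadida	69 126	73 185 228 263 295 315.1		J
J36	El Jadida	69 126	73 185 225 228 263 295 315.1		J
J37	El Jadida	69 126 193 300 309	73 263 309.1 315.1		J
J38	El Jadida	69 126 193 265A/T	73 146 150 152 263 295 315.1		J2
J39	El Jadida	69 126 193 278 291	73 150 152 263 295 309.1 315.1		J2
J40	El Jadida	69 126 193 195 278	73 150 152 196insT 263 295 309.1 315.1		J2
J41	El Jadida	126 220 292 294	73 146 152 195 263 279 315.1		T
J42	El Jadida	126 163 186 189 193del 294	73 263 309.1 315.1		T1
J43	El Jadida	173 183A/C 189 223 278	73 146 153 195 225 226 263 309.1 315.1		X
J44	El Jadida	145 176C/G 223 311 390	73 152 204 263 315.1		N1b
J45	El Jadida	0	73 195 263 315.1	7028	U
J46	El Jadida	0	73 195 263 315.1	7028	U
J47	El Jadida	311	263 309.1 315.1	7028	U
J48	El Jadida	287 356	73 195 263 309.1 315.1		U4
J49	El Jadida	189 270	73 146 195 263 315.1		U5b
J50	El Jadida	172 189 219 261 278	73 263 309.1 315.1		U6a
J51	El Jadida	172 219 278 300	73 242 263 309.1 315.1		U6a
J52	El Jadida	129 183A/C 189 223 235 249 311	73 152 195 263 315.3		M1
J53	El Jadida	183A/C 189 249 265A/C 280 311	73 146 195 263 315.1		M1
J54	El Jadida	183A/C 189 249 265A/C 280 311	73 146 195 263 315.1		M1
J55	El Jadida	129 189 223 249 311 359	263 309.1 309.2 315.1		M1a
J56	El Jadida	129 189 223 249 311 359	73 195 198 263 315.1		M1a
J57	El Jadida	126 187 189 215A/T 223 264 270 278 293 311	73 152 182 185G/C 195 247 263 309.1 315.1 357		L1b1
J58	El Jadida	126 187 189 223 264 270 278 293 311	73 152 182 185G/T 189 195 207 247 263 309.1 315.1 357		L1b1
J59	El Jadida	126 187 189 223 264 270 278 293 311	73 152 182 185G/C 195 247 263 315.1 357		L1b1
J60	El Jadida	126 187 189 223 264 270 278 293 311 355	73 152 182 185G/T 195 247 263 315.1 357		L1b1
J61	El Jadida	126 187 189 223 264 270 278 293 311 355	73 152 182 185G/T 195 247 263 315.1 357		L1b1
J62	El Jadida	17 148 163 187 189 223 278 293 294 311 360	73 89 93 151 182 186C/A 189A/C 247 263 315.1 316		L1c4
J63	El Jadida	86 223 278 294 309 390	73 143 146 152 195 198 263 315.1		L2a1
J64	El Jadida	167 192 223 278 294 309 390	73 143 146 152 195 263 309.1 315.1		L2a1
J65	El Jadida	145 213 223 278 294 390	73 146 152 195 263 315.1		L2a1
J66	El Jadida	189 192 223 278 294 309 357 390	73 143 146 152 195 263 315.1		L2a1
J67	El Jadida	189 192 223 278 294 309	73 143 146 152 195 263 315.1		L2a1
J68	El Jadida	51 172 223 266 278 362	73 263 315.1		L2c1
J69	El Jadida	129 183A/C 189 278 300 354 357 390	73 146 150 195 263 309.2 315.1		L2d1
J70	El Jadida	209 223	73 152 235 263 309.1 315.1		L3f1a
J71	El Jadida	124 223 278 362	73 263 309.1 315.1		L3b1
J72	El Jadida	124 223 336	73 152 242 263 315.1		L3d
J73	El Jadida	124 223 256	73 152 189 195 263 315.1		L3d1'2'3'
J74	El Jadida	124 192 223 256	73 152 189 195 263 309.1 315.1		L3d1'2'3'
J75	El Jadida	223 320 399	73 152 195 198 263 315.1		L3e2a
J76	El Jadida	223 311 320	73 150 195 198 263 315.1		L3e2a
J77	El Jadida	172 183A/C 187 189 223 320	73 150 195 236 263 309.1 315.1 316		L3e2b
J78	El Jadida	172 209 223 292 311	73 189 200 263 315.1		L3f1b
J79	El Jadida	188 223 292 295 311	73 189 200 263 309.1 315.1		L3f1
J80	El Jadida	209 223 292 311 390	73 189 200 263 315.1		L3f1b
J81	El Jadida	129 223 256C/A 278 311 362	73 151 152 189A/C 195 263 294 309.1 315.1		L3h1b
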