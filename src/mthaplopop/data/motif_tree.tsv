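# Minimal haplogroup motif tree for North African control-region data.
# Rooted at H* because the rCRS itself is an H2 lineage: a haplotype with no
# scored differences is reference-like and stays at the root.  Each row gives
# the motif variants ADDED at that node (cumulative along the path); tokens
# use the same dialect as the population tables (HVRI printed minus 16000).
# Motifs are minimally diagnostic for the haplogroups observed in the El
# Jadida sample, transcribed from published control-region phylogenies; the
# file is data and can be replaced by a richer user-supplied tree.
name	parent	HVRI	HVRII	CODING
H*
H1	H*			3010
H7	H*			4793
HV1	H*	67
V	H*	298	72
R0a	H*	126 362	58 64
J	H*	69 126	73 295
J2	J		150 152
T	H*	126 294	73
T1	T	163 186 189
X	H*	189 223 278	73 153 225 226
N1b	H*	145 176G 223	73 204
U	H*			7028
K	U	224 311	73
U4	U	356
U5b	U	189 270	73
U6a	U	172 219 278	73
M1	H*	129 189 223 249 311	73 195
M1a	M1	359
L1b1	H*	126 187 189 223 264 270 278 293 311	73 152 182 195 247
L1c4	H*	148 187 189 223 278 293 294 311 360	73 151 182 247 316
L2a1	H*	223 278 294 309 390	73 143 146 152 195
L2c1	H*	51 223 266 278 362	73
L2d1	H*	129 189 278 354 390	73 146 150 195
L3b1	H*	124 223 278 362	73
L3d	H*	124 223	73 152
L3d1'2'3'	L3d	256	189 195
L3e2	H*	223 320	73 195
L3e2a	L3e2		198
L3e2b	L3e2	172 189	236 316
L3f1	H*	223 292 311	73 189 200
L3f1b	L3f1	209
L3f1a	H*	209 223	73 152 235
L3h1b	H*	129 223 256A 278 311 362	73 151 152 195
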