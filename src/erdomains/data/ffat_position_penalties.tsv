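# FFAT-like motif position-penalty matrix (13-mer window).
# Positions 1-6: acidic tract upstream of the core.  Per-residue acidity
#   penalties (D/E = 0, phosphorylatable S/T = half penalty, basic K/R = 1.5x)
#   multiplied by position weights 0.25, 0.25, 0.5, 0.5, 0.75, 0.75 that
#   increase toward the core; a fully non-acidic neutral tract scores 3.0.
# Positions 7-13: motif core, consensus E-F-F-D-A-x-E ("two phenylalanines
#   in an acidic tract").  Consensus residues score 0; penalties grow with
#   biochemical distance, the second phenylalanine (position 9) being the
#   least substitutable.  Position 12 is the consensus wildcard (only
#   proline is penalized).
# Scores are additive over the window; lower = better; total < 3 = "strong".
position	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	0.25	0.25	0	0	0.25	0.25	0.25	0.25	0.375	0.25	0.25	0.25	0.25	0.25	0.375	0.125	0.125	0.25	0.25	0.25
2	0.25	0.25	0	0	0.25	0.25	0.25	0.25	0.375	0.25	0.25	0.25	0.25	0.25	0.375	0.125	0.125	0.25	0.25	0.25
3	0.5	0.5	0	0	0.5	0.5	0.5	0.5	0.75	0.5	0.5	0.5	0.5	0.5	0.75	0.25	0.25	0.5	0.5	0.5
4	0.5	0.5	0	0	0.5	0.5	0.5	0.5	0.75	0.5	0.5	0.5	0.5	0.5	0.75	0.25	0.25	0.5	0.5	0.5
5	0.75	0.75	0	0	0.75	0.75	0.75	0.75	1.125	0.75	0.75	0.75	0.75	0.75	1.125	0.375	0.375	0.75	0.75	0.75
6	0.75	0.75	0	0	0.75	0.75	0.75	0.75	1.125	0.75	0.75	0.75	0.75	0.75	1.125	0.375	0.375	0.75	0.75	0.75
7	2	2	0.5	0	2	2	2	2	2.5	2	2	1.5	2	1.5	2.5	1	1	2	2	2
8	2.5	2.5	3	3	0	3	2.5	1.5	3	1.5	1.5	2.5	3	2.5	3	2.5	2.5	2	1	0.5
9	3	3	3.5	3.5	0	3.5	3	2	3.5	2	2	3	3.5	3	3.5	3	3	2	1.5	1
10	2.5	2.5	0	0.5	2.5	2.5	2.5	2.5	3	2.5	2.5	1.5	2.5	2.5	3	1	1	2.5	2.5	2.5
11	0	0.5	1.5	1.5	1.5	1	1.5	1.5	2	1.5	1.5	1.5	2	1.5	2	0.5	1	1	1.5	1.5
12	0	0	0	0	0	0	0	0	0	0	0	0	0.5	0	0	0	0	0	0	0
13	1.5	1.5	0	0	1.5	1.5	1.5	1.5	2	1.5	1.5	1	1.5	1	2	0.5	0.5	1.5	1.5	1.5
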