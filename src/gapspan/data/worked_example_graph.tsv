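# Demonstration graph: a linear backbone with a two-branch bubble
# (B1-B3 vs B2) and a repeat contig R flanked by two contexts
# (C5..C8). Format: edge rows are
# node_a<TAB>side_a<TAB>node_b<TAB>side_b<TAB>support<TAB>gap
#node	B1	3000
#node	B2	4000
#node	B3	4000
#node	C1	10000
#node	C2	10000
#node	C3	10000
#node	C4	10000
#node	C5	10000
#node	C6	10000
#node	C7	10000
#node	C8	10000
#node	R	8000
C1	end	C2	begin	4	300
C2	end	B1	begin	3	250
C2	end	B2	begin	3	250
B1	end	B3	begin	3	200
B3	end	C3	begin	3	220
B2	end	C3	begin	3	240
C3	end	C4	begin	4	310
C5	end	R	begin	3	150
C6	end	R	begin	3	180
R	end	C7	begin	3	160
R	end	C8	begin	3	170
C5	end	C8	begin	2	8400
C6	end	C7	begin	2	8500
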