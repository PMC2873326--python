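index	name	family	repeat_class	side	window	subfamily	fl_only	stat	domain_type	trunc	measure
1	gene_size	intrinsic	.	.	.	.	.	.	.	.	gene_size
2	intron_size	intrinsic	.	.	.	.	.	.	.	.	intron_size
3	transgene_distance	transgene_distance	.	.	.	.	.	.	.	.	.
4	ll1_overlap	domain	.	.	.	.	.	overlap	LL1	.	.
5	hl1_overlap	domain	.	.	.	.	.	overlap	HL1	.	.
6	L1_upstream_10kb_density	local_density	L1	upstream	10000.0	.	.	.	.	.	.
7	SINE_upstream_10kb_density	local_density	SINE	upstream	10000.0	.	.	.	.	.	.
8	LTR_upstream_10kb_density	local_density	LTR	upstream	10000.0	.	.	.	.	.	.
9	L1_downstream_10kb_density	local_density	L1	downstream	10000.0	.	.	.	.	.	.
10	SINE_downstream_10kb_density	local_density	SINE	downstream	10000.0	.	.	.	.	.	.
11	LTR_downstream_10kb_density	local_density	LTR	downstream	10000.0	.	.	.	.	.	.
12	L1_downstream_100kb_density	local_density	L1	downstream	100000.0	.	.	.	.	.	.
13	SINE_downstream_100kb_density	local_density	SINE	downstream	100000.0	.	.	.	.	.	.
14	LTR_downstream_100kb_density	local_density	LTR	downstream	100000.0	.	.	.	.	.	.
15	L1_upstream_500kb_density	local_density	L1	upstream	500000.0	.	.	.	.	.	.
16	SINE_upstream_500kb_density	local_density	SINE	upstream	500000.0	.	.	.	.	.	.
17	LTR_upstream_500kb_density	local_density	LTR	upstream	500000.0	.	.	.	.	.	.
18	L1_downstream_500kb_density	local_density	L1	downstream	500000.0	.	.	.	.	.	.
19	SINE_downstream_500kb_density	local_density	SINE	downstream	500000.0	.	.	.	.	.	.
20	LTR_downstream_500kb_density	local_density	LTR	downstream	500000.0	.	.	.	.	.	.
21	L1_upstream_1000kb_density	local_density	L1	upstream	1000000.0	.	.	.	.	.	.
22	SINE_upstream_1000kb_density	local_density	SINE	upstream	1000000.0	.	.	.	.	.	.
23	LTR_upstream_1000kb_density	local_density	LTR	upstream	1000000.0	.	.	.	.	.	.
24	L1_downstream_1000kb_density	local_density	L1	downstream	1000000.0	.	.	.	.	.	.
25	L1_upstream_100kb_density	local_density	L1	upstream	100000.0	.	.	.	.	.	.
26	SINE_upstream_100kb_density	local_density	SINE	upstream	100000.0	.	.	.	.	.	.
27	LTR_upstream_100kb_density	local_density	LTR	upstream	100000.0	.	.	.	.	.	.
28	SINE_downstream_1000kb_density	local_density	SINE	downstream	1000000.0	.	.	.	.	.	.
29	LTR_downstream_1000kb_density	local_density	LTR	downstream	1000000.0	.	.	.	.	.	.
30	ll1_size_mb	domain	.	.	.	.	.	size	LL1	.	.
31	hl1_size_mb	domain	.	.	.	.	.	size	HL1	.	.
32	hl1_distance	domain	.	.	.	.	.	distance	HL1	.	.
33	core_ll1_250kb_overlap	domain	.	.	.	.	.	core_overlap	LL1	250000.0	.
34	core_ll1_500kb_overlap	domain	.	.	.	.	.	core_overlap	LL1	500000.0	.
35	ll1_distance	domain	.	.	.	.	.	distance	LL1	.	.
36	core_hl1_250kb_overlap	domain	.	.	.	.	.	core_overlap	HL1	250000.0	.
37	core_hl1_500kb_overlap	domain	.	.	.	.	.	core_overlap	HL1	500000.0	.
38	boundary_distance	domain	.	.	.	.	.	boundary_distance	.	.	.
39	L1_body_density	local_density	L1	body	.	.	.	.	.	.	.
40	SINE_body_density	local_density	SINE	body	.	.	.	.	.	.	.
41	LTR_body_density	local_density	LTR	body	.	.	.	.	.	.	.
42	fl_L1_Mus1_distance	fl_subfamily	.	.	.	L1_Mus1	True	distance	.	.	.
43	fl_L1_Mus1_orientation	fl_subfamily	.	.	.	L1_Mus1	True	orientation	.	.	.
44	fl_L1_Mus2_distance	fl_subfamily	.	.	.	L1_Mus2	True	distance	.	.	.
45	fl_L1_Mus2_orientation	fl_subfamily	.	.	.	L1_Mus2	True	orientation	.	.	.
46	fl_L1_Mus3_distance	fl_subfamily	.	.	.	L1_Mus3	True	distance	.	.	.
47	fl_L1_Mus3_orientation	fl_subfamily	.	.	.	L1_Mus3	True	orientation	.	.	.
48	fl_L1Md_A_distance	fl_subfamily	.	.	.	L1Md_A	True	distance	.	.	.
49	fl_L1Md_A_orientation	fl_subfamily	.	.	.	L1Md_A	True	orientation	.	.	.
50	fl_L1Md_T_distance	fl_subfamily	.	.	.	L1Md_T	True	distance	.	.	.
51	fl_L1Md_T_orientation	fl_subfamily	.	.	.	L1Md_T	True	orientation	.	.	.
52	fl_L1Md_F2_distance	fl_subfamily	.	.	.	L1Md_F2	True	distance	.	.	.
53	fl_L1Md_F2_orientation	fl_subfamily	.	.	.	L1Md_F2	True	orientation	.	.	.
54	fl_L1Md_F_distance	fl_subfamily	.	.	.	L1Md_F	True	distance	.	.	.
55	fl_L1Md_F_orientation	fl_subfamily	.	.	.	L1Md_F	True	orientation	.	.	.
56	fl_L1Md_F3_distance	fl_subfamily	.	.	.	L1Md_F3	True	distance	.	.	.
57	fl_L1Md_F3_orientation	fl_subfamily	.	.	.	L1Md_F3	True	orientation	.	.	.
58	fl_L1Md_Gf_distance	fl_subfamily	.	.	.	L1Md_Gf	True	distance	.	.	.
59	fl_L1Md_Gf_orientation	fl_subfamily	.	.	.	L1Md_Gf	True	orientation	.	.	.
60	fl_L1VL4_distance	fl_subfamily	.	.	.	L1VL4	True	distance	.	.	.
61	fl_L1VL4_orientation	fl_subfamily	.	.	.	L1VL4	True	orientation	.	.	.
62	fl_L1VL1_distance	fl_subfamily	.	.	.	L1VL1	True	distance	.	.	.
63	fl_L1VL1_orientation	fl_subfamily	.	.	.	L1VL1	True	orientation	.	.	.
64	fl_Lx_distance	fl_subfamily	.	.	.	Lx	True	distance	.	.	.
65	fl_Lx_orientation	fl_subfamily	.	.	.	Lx	True	orientation	.	.	.
66	fl_Lx2_distance	fl_subfamily	.	.	.	Lx2	True	distance	.	.	.
67	fl_Lx2_orientation	fl_subfamily	.	.	.	Lx2	True	orientation	.	.	.
68	fl_Lx3_distance	fl_subfamily	.	.	.	Lx3	True	distance	.	.	.
69	fl_Lx3_orientation	fl_subfamily	.	.	.	Lx3	True	orientation	.	.	.
70	fl_Lx3_Mus_distance	fl_subfamily	.	.	.	Lx3_Mus	True	distance	.	.	.
71	fl_Lx3_Mus_orientation	fl_subfamily	.	.	.	Lx3_Mus	True	orientation	.	.	.
72	fl_Lx4A_distance	fl_subfamily	.	.	.	Lx4A	True	distance	.	.	.
73	fl_Lx4A_orientation	fl_subfamily	.	.	.	Lx4A	True	orientation	.	.	.
74	fl_Lx6_distance	fl_subfamily	.	.	.	Lx6	True	distance	.	.	.
75	fl_Lx6_orientation	fl_subfamily	.	.	.	Lx6	True	orientation	.	.	.
76	fl_Lx7_distance	fl_subfamily	.	.	.	Lx7	True	distance	.	.	.
77	fl_Lx7_orientation	fl_subfamily	.	.	.	Lx7	True	orientation	.	.	.
78	fl_Lx8_distance	fl_subfamily	.	.	.	Lx8	True	distance	.	.	.
79	fl_Lx8_orientation	fl_subfamily	.	.	.	Lx8	True	orientation	.	.	.
80	fl_Lx4B_distance	fl_subfamily	.	.	.	Lx4B	True	distance	.	.	.
81	fl_Lx4B_orientation	fl_subfamily	.	.	.	Lx4B	True	orientation	.	.	.
82	fl_Lx5_distance	fl_subfamily	.	.	.	Lx5	True	distance	.	.	.
83	fl_Lx5_orientation	fl_subfamily	.	.	.	Lx5	True	orientation	.	.	.
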