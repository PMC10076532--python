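index	name	abbreviation	hemisphere	x	y	z
1	Left superior frontal gyrus, medial	SFGmed.L	left	-6	49	31
2	Left superior frontal gyrus, medial orbital	ORBsupmed.L	left	-6	54	-7
3	Left posterior cingulate gyrus	PCG.L	left	-6	-43	25
4	Left hippocampus	HIP.L	left	-26	-21	-10
5	Left inferior parietal gyrus	IPL.L	left	-44	-46	47
6	Left angular gyrus	ANG.L	left	-45	-61	36
7	Left precuneus	PCUN.L	left	-8	-56	48
8	Right superior frontal gyrus, medial	SFGmed.R	right	8	51	30
9	Right superior frontal gyrus, medial orbital	ORBsupmed.R	right	7	52	-7
10	Right posterior cingulate gyrus	PCG.R	right	6	-42	22
11	Right hippocampus	HIP.R	right	28	-20	-10
12	Right inferior parietal gyrus	IPL.R	right	45	-46	50
13	Right angular gyrus	ANG.R	right	45	-60	39
14	Right precuneus	PCUN.R	right	9	-56	44
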