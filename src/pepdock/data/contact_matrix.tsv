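#	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-0.9800	-1.0889	-0.1556	-0.1556	-1.1356	-0.6378	-0.2022	-1.4000	-0.0933	-1.2911	-0.9956	-0.1556	-0.4511	-0.1556	-0.0000	-0.5756	-0.5911	-1.3533	-0.5600	-0.4978
C	-1.0889	-1.2099	-0.1728	-0.1728	-1.2617	-0.7086	-0.2247	-1.5556	-0.1037	-1.4346	-1.1062	-0.1728	-0.5012	-0.1728	-0.0000	-0.6395	-0.6568	-1.5037	-0.6222	-0.5531
D	-0.1556	-0.1728	-0.0247	-0.0247	-0.1802	-0.1012	-0.0321	-0.2222	-0.0148	-0.2049	-0.1580	-0.0247	-0.0716	-0.0247	-0.0000	-0.0914	-0.0938	-0.2148	-0.0889	-0.0790
E	-0.1556	-0.1728	-0.0247	-0.0247	-0.1802	-0.1012	-0.0321	-0.2222	-0.0148	-0.2049	-0.1580	-0.0247	-0.0716	-0.0247	-0.0000	-0.0914	-0.0938	-0.2148	-0.0889	-0.0790
F	-1.1356	-1.2617	-0.1802	-0.1802	-1.3158	-0.7390	-0.2343	-1.6222	-0.1081	-1.4960	-1.1536	-0.1802	-0.5227	-0.1802	-0.0000	-0.6669	-0.6849	-1.5681	-0.6489	-0.5768
G	-0.6378	-0.7086	-0.1012	-0.1012	-0.7390	-0.4151	-0.1316	-0.9111	-0.0607	-0.8402	-0.6479	-0.1012	-0.2936	-0.1012	-0.0000	-0.3746	-0.3847	-0.8807	-0.3644	-0.3240
H	-0.2022	-0.2247	-0.0321	-0.0321	-0.2343	-0.1316	-0.0417	-0.2889	-0.0193	-0.2664	-0.2054	-0.0321	-0.0931	-0.0321	-0.0000	-0.1188	-0.1220	-0.2793	-0.1156	-0.1027
I	-1.4000	-1.5556	-0.2222	-0.2222	-1.6222	-0.9111	-0.2889	-2.0000	-0.1333	-1.8444	-1.4222	-0.2222	-0.6444	-0.2222	-0.0000	-0.8222	-0.8444	-1.9333	-0.8000	-0.7111
K	-0.0933	-0.1037	-0.0148	-0.0148	-0.1081	-0.0607	-0.0193	-0.1333	-0.0089	-0.1230	-0.0948	-0.0148	-0.0430	-0.0148	-0.0000	-0.0548	-0.0563	-0.1289	-0.0533	-0.0474
L	-1.2911	-1.4346	-0.2049	-0.2049	-1.4960	-0.8402	-0.2664	-1.8444	-0.1230	-1.7010	-1.3116	-0.2049	-0.5943	-0.2049	-0.0000	-0.7583	-0.7788	-1.7830	-0.7378	-0.6558
M	-0.9956	-1.1062	-0.1580	-0.1580	-1.1536	-0.6479	-0.2054	-1.4222	-0.0948	-1.3116	-1.0114	-0.1580	-0.4583	-0.1580	-0.0000	-0.5847	-0.6005	-1.3748	-0.5689	-0.5057
N	-0.1556	-0.1728	-0.0247	-0.0247	-0.1802	-0.1012	-0.0321	-0.2222	-0.0148	-0.2049	-0.1580	-0.0247	-0.0716	-0.0247	-0.0000	-0.0914	-0.0938	-0.2148	-0.0889	-0.0790
P	-0.4511	-0.5012	-0.0716	-0.0716	-0.5227	-0.2936	-0.0931	-0.6444	-0.0430	-0.5943	-0.4583	-0.0716	-0.2077	-0.0716	-0.0000	-0.2649	-0.2721	-0.6230	-0.2578	-0.2291
Q	-0.1556	-0.1728	-0.0247	-0.0247	-0.1802	-0.1012	-0.0321	-0.2222	-0.0148	-0.2049	-0.1580	-0.0247	-0.0716	-0.0247	-0.0000	-0.0914	-0.0938	-0.2148	-0.0889	-0.0790
R	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000	-0.0000
S	-0.5756	-0.6395	-0.0914	-0.0914	-0.6669	-0.3746	-0.1188	-0.8222	-0.0548	-0.7583	-0.5847	-0.0914	-0.2649	-0.0914	-0.0000	-0.3380	-0.3472	-0.7948	-0.3289	-0.2923
T	-0.5911	-0.6568	-0.0938	-0.0938	-0.6849	-0.3847	-0.1220	-0.8444	-0.0563	-0.7788	-0.6005	-0.0938	-0.2721	-0.0938	-0.0000	-0.3472	-0.3565	-0.8163	-0.3378	-0.3002
V	-1.3533	-1.5037	-0.2148	-0.2148	-1.5681	-0.8807	-0.2793	-1.9333	-0.1289	-1.7830	-1.3748	-0.2148	-0.6230	-0.2148	-0.0000	-0.7948	-0.8163	-1.8689	-0.7733	-0.6874
W	-0.5600	-0.6222	-0.0889	-0.0889	-0.6489	-0.3644	-0.1156	-0.8000	-0.0533	-0.7378	-0.5689	-0.0889	-0.2578	-0.0889	-0.0000	-0.3289	-0.3378	-0.7733	-0.3200	-0.2844
Y	-0.4978	-0.5531	-0.0790	-0.0790	-0.5768	-0.3240	-0.1027	-0.7111	-0.0474	-0.6558	-0.5057	-0.0790	-0.2291	-0.0790	-0.0000	-0.2923	-0.3002	-0.6874	-0.2844	-0.2528
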