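aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	-1.278	-1.185	-2.706	-3.059	-2.590	-1.997	-2.070	-1.764	-3.648	-2.468	-3.165	-3.055	-2.656	-2.680	-2.894	-2.584	-3.060	-2.194	-3.102	-2.600
C	-1.185	-2.212	-2.434	-2.732	-2.525	-2.383	-3.831	-2.842	-1.873	-3.734	-3.239	-3.096	-4.529	-1.382	-2.662	-2.810	-3.344	-2.824	-2.595	-3.911
D	-2.706	-2.434	-3.607	-3.879	-3.172	-2.193	-3.086	-2.342	-2.970	-3.534	-2.777	-1.290	-2.326	-1.314	-0.992	-1.743	-2.440	-1.719	-2.647	-3.507
E	-3.059	-2.732	-3.879	-2.361	-2.410	-1.961	-2.988	-2.227	-2.257	-2.137	-2.959	-2.167	-2.862	-0.743	-3.000	-2.050	-2.587	-3.190	-2.480	-1.904
F	-2.590	-2.525	-3.172	-2.410	-3.057	-1.830	-2.124	-2.510	-3.588	-0.755	-3.203	-2.654	-2.233	-2.112	-2.766	-0.826	-2.263	-2.553	-2.286	-1.947
G	-1.997	-2.383	-2.193	-1.961	-1.830	-4.538	-1.461	-2.918	-1.321	-1.590	-2.444	-0.973	-3.729	-2.029	-3.965	-2.899	-3.093	-2.751	-2.238	-3.364
H	-2.070	-3.831	-3.086	-2.988	-2.124	-1.461	-1.218	-3.139	-2.951	-1.609	-4.067	-4.045	-4.557	-2.631	-2.312	-3.223	-3.787	-1.933	-3.553	-3.133
I	-1.764	-2.842	-2.342	-2.227	-2.510	-2.918	-3.139	-2.582	-4.419	-0.683	-2.724	-3.119	-0.820	-2.324	-2.086	-4.208	-1.844	-2.283	-2.016	-1.775
K	-3.648	-1.873	-2.970	-2.257	-3.588	-1.321	-2.951	-4.419	-1.600	-4.915	-1.885	-3.666	-3.369	-3.457	-2.361	-2.791	-2.110	-4.678	-1.834	-1.417
L	-2.468	-3.734	-3.534	-2.137	-0.755	-1.590	-1.609	-0.683	-4.915	-4.091	-1.583	-3.035	-1.027	-2.080	-1.216	-2.581	-1.564	-1.933	-2.629	-1.338
M	-3.165	-3.239	-2.777	-2.959	-3.203	-2.444	-4.067	-2.724	-1.885	-1.583	-1.943	-1.161	-3.654	-1.752	-2.547	-4.052	-2.269	-1.824	-3.682	-1.532
N	-3.055	-3.096	-1.290	-2.167	-2.654	-0.973	-4.045	-3.119	-3.666	-3.035	-1.161	-0.938	-1.638	-2.704	-3.055	-4.805	-3.033	-2.629	-2.492	-2.697
P	-2.656	-4.529	-2.326	-2.862	-2.233	-3.729	-4.557	-0.820	-3.369	-1.027	-3.654	-1.638	-2.305	-2.119	-3.721	-3.256	-1.886	-2.723	-2.093	-3.288
Q	-2.680	-1.382	-1.314	-0.743	-2.112	-2.029	-2.631	-2.324	-3.457	-2.080	-1.752	-2.704	-2.119	-3.692	-2.454	-1.946	-1.931	-1.314	-2.518	-2.783
R	-2.894	-2.662	-0.992	-3.000	-2.766	-3.965	-2.312	-2.086	-2.361	-1.216	-2.547	-3.055	-3.721	-2.454	-1.521	-3.781	-3.010	-2.928	-1.319	-1.859
S	-2.584	-2.810	-1.743	-2.050	-0.826	-2.899	-3.223	-4.208	-2.791	-2.581	-4.052	-4.805	-3.256	-1.946	-3.781	-5.077	-0.767	-2.845	-0.492	-2.290
T	-3.060	-3.344	-2.440	-2.587	-2.263	-3.093	-3.787	-1.844	-2.110	-1.564	-2.269	-3.033	-1.886	-1.931	-3.010	-0.767	-3.673	-2.481	-1.232	-0.615
V	-2.194	-2.824	-1.719	-3.190	-2.553	-2.751	-1.933	-2.283	-4.678	-1.933	-1.824	-2.629	-2.723	-1.314	-2.928	-2.845	-2.481	-2.679	-2.922	-1.701
W	-3.102	-2.595	-2.647	-2.480	-2.286	-2.238	-3.553	-2.016	-1.834	-2.629	-3.682	-2.492	-2.093	-2.518	-1.319	-0.492	-1.232	-2.922	-3.540	-2.029
Y	-2.600	-3.911	-3.507	-1.904	-1.947	-3.364	-3.133	-1.775	-1.417	-1.338	-1.532	-2.697	-3.288	-2.783	-1.859	-2.290	-0.615	-1.701	-2.029	-2.218
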