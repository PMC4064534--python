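# Heptad positional propensities for coiled-coil scoring (Lupas-style
# sliding-window method).  Columns: residue, positions a b c d e f g.
# Values adapted from the classical coiled-coil residue frequency
# statistics; entries of zero in the source table are floored at 0.01 so
# geometric-mean window scores remain strictly positive.  Editable.
A	1.297	1.551	1.084	2.612	0.377	1.248	0.877
C	0.824	0.022	0.308	0.152	0.180	0.156	0.044
D	0.030	2.352	2.268	0.237	0.663	1.620	1.448
E	0.262	3.496	3.108	0.998	5.685	2.494	3.048
F	0.531	0.076	0.403	0.662	0.189	0.106	0.013
G	0.045	0.275	0.578	0.216	0.211	0.426	0.156
H	0.347	0.275	0.679	0.395	0.294	0.579	0.213
I	2.597	0.098	0.345	0.894	0.514	0.471	0.431
K	1.375	2.639	1.763	0.191	1.815	1.961	2.795
L	3.167	0.297	0.398	3.902	0.585	0.501	0.483
M	2.240	0.370	0.480	1.409	0.541	0.772	0.663
N	0.835	1.475	1.534	0.039	1.722	2.456	2.280
P	0.010	0.010	0.010	0.013	0.010	0.010	0.010
Q	0.179	2.114	1.778	0.631	2.550	1.578	2.526
R	0.659	1.163	1.210	0.031	1.358	1.937	1.798
S	0.382	0.583	1.052	0.419	0.525	0.916	0.628
T	0.169	0.702	0.955	0.654	0.791	0.843	0.647
V	1.665	0.403	0.386	0.949	0.211	0.342	0.360
W	0.240	0.010	0.010	0.456	0.019	0.010	0.010
Y	1.417	0.090	0.122	1.659	0.190	0.130	0.155
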