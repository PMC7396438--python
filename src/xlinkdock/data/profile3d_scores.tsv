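# 3D-1D environment score table (regenerate with scripts/make_profile_table.py)
aa	exposed-nonpolar-helix	exposed-nonpolar-sheet	exposed-nonpolar-other	exposed-polar-helix	exposed-polar-sheet	exposed-polar-other	partial-nonpolar-helix	partial-nonpolar-sheet	partial-nonpolar-other	partial-polar-helix	partial-polar-sheet	partial-polar-other	buried-nonpolar-helix	buried-nonpolar-sheet	buried-nonpolar-other	buried-polar-helix	buried-polar-sheet	buried-polar-other
ALA	-0.160	-0.210	-0.210	-0.280	-0.330	-0.330	0.390	0.340	0.340	0.270	0.220	0.220	0.280	0.230	0.230	0.160	0.110	0.110
ARG	0.400	0.350	0.350	0.700	0.650	0.650	-0.150	-0.200	-0.200	0.150	0.100	0.100	-0.700	-0.750	-0.750	-0.400	-0.450	-0.450
ASN	0.261	0.261	0.261	0.494	0.494	0.494	-0.044	-0.044	-0.044	0.189	0.189	0.189	-0.594	-0.594	-0.594	-0.361	-0.361	-0.361
ASP	0.261	0.261	0.261	0.494	0.494	0.494	-0.044	-0.044	-0.044	0.189	0.189	0.189	-0.594	-0.594	-0.594	-0.361	-0.361	-0.361
CYS	-0.272	-0.272	-0.272	-0.439	-0.439	-0.439	0.278	0.278	0.278	0.111	0.111	0.111	0.339	0.339	0.339	0.172	0.172	0.172
GLN	0.311	0.261	0.261	0.544	0.494	0.494	0.006	-0.044	-0.044	0.239	0.189	0.189	-0.544	-0.594	-0.594	-0.311	-0.361	-0.361
GLU	0.311	0.261	0.261	0.544	0.494	0.494	0.006	-0.044	-0.044	0.239	0.189	0.189	-0.544	-0.594	-0.594	-0.311	-0.361	-0.361
GLY	-0.014	-0.014	-0.014	0.012	0.012	0.012	0.438	0.438	0.438	0.464	0.464	0.464	-0.112	-0.112	-0.112	-0.086	-0.086	-0.086
HIS	0.284	0.234	0.234	0.498	0.448	0.448	0.052	0.002	0.002	0.266	0.216	0.216	-0.498	-0.548	-0.548	-0.284	-0.334	-0.334
ILE	-0.450	-0.450	-0.450	-0.750	-0.750	-0.750	0.100	0.100	0.100	-0.200	-0.200	-0.200	0.650	0.650	0.650	0.350	0.350	0.350
LEU	-0.338	-0.388	-0.388	-0.591	-0.641	-0.641	0.212	0.162	0.162	-0.041	-0.091	-0.091	0.591	0.541	0.541	0.338	0.288	0.288
LYS	0.347	0.297	0.297	0.607	0.557	0.557	-0.057	-0.107	-0.107	0.203	0.153	0.153	-0.607	-0.657	-0.657	-0.347	-0.397	-0.397
MET	-0.169	-0.219	-0.219	-0.296	-0.346	-0.346	0.381	0.331	0.331	0.254	0.204	0.204	0.296	0.246	0.246	0.169	0.119	0.119
PHE	-0.299	-0.299	-0.299	-0.486	-0.486	-0.486	0.251	0.251	0.251	0.064	0.064	0.064	0.386	0.386	0.386	0.199	0.199	0.199
PRO	0.092	0.092	0.092	0.199	0.199	0.199	0.251	0.251	0.251	0.358	0.358	0.358	-0.299	-0.299	-0.299	-0.192	-0.192	-0.192
SER	0.021	0.021	0.021	0.074	0.074	0.074	0.376	0.376	0.376	0.429	0.429	0.429	-0.174	-0.174	-0.174	-0.121	-0.121	-0.121
THR	0.012	0.012	0.012	0.059	0.059	0.059	0.391	0.391	0.391	0.438	0.438	0.438	-0.159	-0.159	-0.159	-0.112	-0.112	-0.112
TRP	0.030	0.030	0.030	0.090	0.090	0.090	0.360	0.360	0.360	0.420	0.420	0.420	-0.190	-0.190	-0.190	-0.130	-0.130	-0.130
TYR	0.066	0.066	0.066	0.152	0.152	0.152	0.298	0.298	0.298	0.384	0.384	0.384	-0.252	-0.252	-0.252	-0.166	-0.166	-0.166
VAL	-0.423	-0.423	-0.423	-0.703	-0.703	-0.703	0.127	0.127	0.127	-0.153	-0.153	-0.153	0.603	0.603	0.603	0.323	0.323	0.323
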