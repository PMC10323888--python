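gene_id	S1	S2	S3	S4	S5	S6
ANTXR1	6.163	5.658	5.301	6.931	4.758	6.751
CASC15	6.818	5.621	3.66	8.683	5.54	5.538
COL11A1	7.494	6.832	3.919	6.589	6.837	5.992
COL1A1	3.695	3.987	6.632	5.987	5.014	7.575
COL5A2	6.656	6.121	5.691	7.301	6.378	6.859
COL8A1	5.545	5.046	7.546	6.336	4.028	4.754
DCBLD1	5.279	4.93	5.643	5.562	7.632	6.978
DLG4	6.886	7.832	6.82	4.923	5.451	8.201
ITGA11	6.307	6.62	5.681	6.093	6.131	7.131
KANK4	4.555	6.072	6.378	4.608	6.389	5.869
LRRC15	3.589	5.212	5.874	5.844	5.899	6.524
MEIS3	6.196	6.073	6.354	6.779	6.184	5.208
MMP11	5.613	6.586	6.008	5.269	5.473	4.935
MMP14	5.545	6.432	6.096	4.939	6.643	6.061
NOTCH3	6.786	5.728	4.306	5.211	5.507	7.245
NOX4	5.081	6.385	5.35	6.419	5.979	4.927
NUAK1	7.648	6.584	6.016	6.025	5.776	5.868
PPEF1	6.612	4.506	5.929	5.157	5.774	6.491
PPFIBP1	6.081	6.17	6.467	4.928	5.147	6.613
PTK7	5.33	5.816	4.898	5.023	6.987	6.886
SERPINH1	8.158	3.061	5.928	6.485	4.554	5.553
SOX11	6.278	7.023	7.992	6.104	6.481	5.556
SPOCD1	4.62	5.943	5.71	6.135	6.542	5.605
UNC5B	5.927	7.377	5.336	7.098	7.205	4.827
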