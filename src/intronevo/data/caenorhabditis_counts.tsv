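species	losses	lost_genes	gains	gained_genes	both_genes	precise_losses	genes_ge2_lost	adjacent_pairs
C_angaria	2981	1534	130	118	80	2866	757	643
C_japonica	918	672	16	15	7	882	166	119
C_elegans	329	274	13	13	3	314	43	26
C_tropicalis	279	246	0	0	0	269	25	14
C_brenneri	256	225	7	6	4	245	28	11
C_latens	41	38	0	0	0	37	3	2
C_remanei	31	27	0	0	0	30	2	2
C_sinica	166	142	0	0	0	158	17	7
C_nigoni	39	35	0	0	0	36	3	3
C_briggsae	7	6	2	2	0	7	1	1
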