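# Reference binned count table: drug withdrawals/precautions per drug-AUC bin
# (10 equal-width AUC bins over 1041 study drugs; rows are withdrawal/precaution sources)
label	~0.1	~0.2	~0.3	~0.4	~0.5	~0.6	~0.7	~0.8	~0.9	~1.0
withdrawn_total	1	4	7	13	30	34	39	16	6	4
withdrawn_un_or_ema	1	3	7	11	26	31	34	15	4	2
withdrawn_un_or_drugbank	1	3	5	5	25	26	28	12	5	3
withdrawn_ema_or_drugbank	1	4	3	11	16	14	26	8	5	3
withdrawn_un	1	2	5	3	21	23	23	11	3	1
withdrawn_ema	0	1	2	8	6	8	12	4	1	1
withdrawn_drugbank	1	3	1	3	10	6	14	4	4	2
precaution_beers	0	1	6	7	16	25	25	6	3	1
precaution_fda	0	0	6	11	17	32	19	7	3	1
total_study_drugs	5	14	34	68	144	217	234	167	88	70
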