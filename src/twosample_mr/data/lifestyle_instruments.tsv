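trait	snp_id	ancestry	chrom	pos	gene	effect_allele	eaf	beta	se	n	pvalue	source
sedentary	rs26579	Europeans	5	87985295	MEF2C-AS2	G	0.415	0.028	0.005	91105	2.60e-09	UK Biobank (Doherty 2018)
sedentary	rs25966	Europeans	5	106822908	EFNA5	G	0.531	0.028	0.005	91105	3.00e-09	UK Biobank (Doherty 2018)
sedentary	rs6801032	Europeans	3	68527135	LOC105377146	A	0.259	0.031	0.005	91105	3.10e-09	UK Biobank (Doherty 2018)
sedentary	rs7779206	Europeans	7	71723883	CALN1	A	0.558	0.028	0.005	91105	4.20e-09	UK Biobank (Doherty 2018)
MVPA	rs429358	Europeans	19	45411941	APOE	T	0.850	-0.019	0.003	377234	7.30e-11	UK Biobank (Klimentidis 2018)
MVPA	rs7804463	Europeans	7	133447651	EXOC4	T	0.530	0.013	0.002	377234	4.10e-10	UK Biobank (Klimentidis 2018)
MVPA	rs2854277	Europeans	6	32628084	HLA-DQB1	C	0.920	0.027	0.005	377234	1.40e-08	UK Biobank (Klimentidis 2018)
MVPA	rs1379183	Europeans	7	50237784	C7orf72/SPATA48	C	0.410	-0.012	0.002	377234	1.70e-08	UK Biobank (Klimentidis 2018)
MVPA	rs3094622	Europeans	6	30327952	RPP21	A	0.860	0.018	0.003	377234	1.00e-08	UK Biobank (Klimentidis 2018)
MVPA	rs149943	Europeans	6	28002388	ZNF165	G	0.850	0.016	0.003	377234	5.60e-08	UK Biobank (Klimentidis 2018)
MVPA	rs2035562	Europeans	3	85056521	CADM2	A	0.330	-0.014	0.002	377234	1.00e-09	UK Biobank (Klimentidis 2018)
MVPA	rs7854466	Europeans	9	37044388	PAX5	T	0.560	-0.014	0.002	377234	2.40e-11	UK Biobank (Klimentidis 2018)
MVPA	rs1043595	Europeans	7	128410012	CALU	G	0.720	0.013	0.002	377234	4.20e-08	UK Biobank (Klimentidis 2018)
VPA	rs1248860	Europeans	3	85015779	CADM2	G	0.480	-0.051	0.007	261055	5.30e-15	UK Biobank (Klimentidis 2018)
VPA	rs2764261	Europeans	6	108927842	FOXO3	A	0.370	0.030	0.005	261055	5.30e-08	UK Biobank (Klimentidis 2018)
VPA	rs13243553	Europeans	7	133506955	EXOC4	G	0.610	0.039	0.007	261055	2.40e-09	UK Biobank (Klimentidis 2018)
VPA	rs3781411	Europeans	10	126715436	CTBP2	C	0.880	0.058	0.009	261055	1.00e-10	UK Biobank (Klimentidis 2018)
VPA	rs328902	Europeans	7	35020843	DPY19L1	C	0.690	-0.041	0.006	261055	1.30e-10	UK Biobank (Klimentidis 2018)
sleep_duration	rs1191685	Europeans	2	113811454	PAX8	C	0.370	2.870	0.470	44563	1.06e-09	CHARGE (Gottlieb 2015)
sleep_duration	rs1823125	Europeans	2	113806882	PAX8	G	0.260	3.010	0.500	45281	1.71e-08	CHARGE (Gottlieb 2015)
sleep_duration	rs1807282	Europeans	2	113826506	PAX8	T	0.260	2.890	0.490	46805	3.91e-09	CHARGE (Gottlieb 2015)
sleep_duration	rs1964463	Europeans	2	113785491	PAX8	G	0.250	2.840	0.500	45281	1.07e-08	CHARGE (Gottlieb 2015)
sleep_duration	rs4587207	Europeans	6	30874924	IER3	G	0.800	-3.140	0.560	46807	2.02e-08	CHARGE (Gottlieb 2015)
sleep_duration	rs4248149	Europeans	6	30875606	IER3	C	0.800	-3.080	0.560	46810	3.95e-08	CHARGE (Gottlieb 2015)
sleep_duration	rs2394403	Europeans	6	30875848	IER3	T	0.800	-3.070	0.560	46811	4.39e-08	CHARGE (Gottlieb 2015)
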