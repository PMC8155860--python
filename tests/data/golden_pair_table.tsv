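miRNA	mRNA	Cor	Adj.pval	FC.miRNA	FC.mRNA	Dat.Sum
mir0015	gene000040	-1.00	9.17e-06	-7.26	6.61	1
mir0016	gene000052	-1.00	9.17e-06	-12.01	13.91	2
mir0010	gene000102	-1.00	9.51e-06	7.73	-8.04	2
mir0002	gene000094	-1.00	1.10e-05	14.43	-11.25	3
mir0002	gene000099	-1.00	1.23e-05	14.43	-14.51	1
mir0015	gene000108	-1.00	1.57e-05	-7.26	10.81	1
mir0016	gene000091	-1.00	1.63e-05	-12.01	8.88	1
mir0020	gene000046	-1.00	1.63e-05	7.09	-7.15	3
mir0016	gene000048	-1.00	1.63e-05	-12.01	18.91	1
mir0016	gene000108	-1.00	2.11e-05	-12.01	10.81	1
mir0016	gene000026	-0.99	2.31e-05	-12.01	10.63	1
mir0015	gene000088	-0.99	2.40e-05	-7.26	13.27	1
mir0022	gene000098	-0.99	2.40e-05	8.71	-11.67	1
mir0014	gene000017	-0.99	2.40e-05	-16.18	14.73	2
mir0002	gene000095	-0.99	2.54e-05	14.43	-14.17	1
mir0015	gene000104	-0.99	2.54e-05	-7.26	14.52	1
mir0022	gene000078	-0.99	2.54e-05	8.71	-8.07	3
mir0015	gene000053	-0.99	2.54e-05	-7.26	6.16	2
mir0022	gene000046	-0.99	2.81e-05	8.71	-7.15	1
mir0021	gene000029	-0.99	2.81e-05	-10.27	12.53	3
mir0014	gene000040	-0.99	2.82e-05	-16.18	6.61	1
mir0020	gene000111	-0.99	3.01e-05	7.09	-7.04	2
mir0002	gene000103	-0.99	3.01e-05	14.43	-5.66	1
mir0015	gene000100	-0.99	3.28e-05	-7.26	6.91	2
mir0020	gene000075	-0.99	3.66e-05	7.09	-10.32	1
mir0007	gene000069	-0.99	3.74e-05	8.31	-8.77	2
mir0002	gene000098	-0.99	4.13e-05	14.43	-11.67	1
mir0021	gene000088	-0.99	4.16e-05	-10.27	13.27	1
mir0016	gene000059	-0.99	4.67e-05	-12.01	6.50	1
mir0016	gene000038	-0.99	4.97e-05	-12.01	13.93	3
mir0020	gene000078	-0.99	5.06e-05	7.09	-8.07	2
mir0023	gene000103	-0.99	5.20e-05	4.76	-5.66	2
mir0002	gene000024	-0.99	5.20e-05	14.43	-13.57	1
mir0023	gene000062	-0.99	5.20e-05	4.76	-15.20	1
mir0015	gene000091	-0.99	5.65e-05	-7.26	8.88	2
mir0007	gene000049	-0.99	5.78e-05	8.31	-8.92	2
mir0014	gene000048	-0.99	5.98e-05	-16.18	18.91	2
mir0010	gene000075	-0.99	6.29e-05	7.73	-10.32	1
mir0023	gene000054	-0.99	6.29e-05	4.76	-9.61	1
mir0010	gene000049	-0.99	6.57e-05	7.73	-8.92	1
mir0023	gene000067	-0.99	6.97e-05	4.76	-5.16	2
mir0010	gene000044	-0.99	7.30e-05	7.73	-6.71	3
mir0002	gene000078	-0.99	8.14e-05	14.43	-8.07	1
mir0021	gene000053	-0.98	8.64e-05	-10.27	6.16	2
mir0010	gene000054	-0.98	1.20e-04	7.73	-9.61	1
mir0007	gene000078	-0.98	1.30e-04	8.31	-8.07	1
mir0014	gene000077	-0.98	1.31e-04	-16.18	6.59	1
mir0022	gene000049	-0.98	1.66e-04	8.71	-8.92	1
mir0023	gene000066	-0.98	1.79e-04	4.76	-13.39	1
mir0022	gene000102	-0.98	1.84e-04	8.71	-8.04	1
mir0021	gene000004	-0.98	2.12e-04	-10.27	9.87	2
mir0020	gene000049	-0.98	2.18e-04	7.09	-8.92	1
mir0014	gene000100	-0.97	2.22e-04	-16.18	6.91	2
mir0016	gene000115	-0.97	2.76e-04	-12.01	3.96	1
mir0010	gene000099	-0.97	2.99e-04	7.73	-14.51	1
mir0010	gene000095	-0.96	5.58e-04	7.73	-14.17	1
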